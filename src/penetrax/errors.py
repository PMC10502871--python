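"""Exception hierarchy shared across the pipeline stages."""


class PenetraxError(Exception):
    """Base class for all penetrax errors."""


class ConfigurationError(PenetraxError):
    """A run configuration or table schema problem (missing column, bad option)."""


class ValidationError(PenetraxError):
    """Input data violates an invariant (e.g. allele count exceeds allele number)."""


class DegeneracyError(PenetraxError):
    """A count of zero (or an otherwise empty stratum) precludes a defensible
    log-scale confidence interval; the caller must apply the degeneracy policy."""
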