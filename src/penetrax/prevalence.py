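"""Disease-prevalence handling: proportion meta-analysis and effective counts.

The penetrance estimator propagates uncertainty through three binomial-like
terms.  Prevalence usually arrives as a point estimate with a 95% CI rather
than raw counts, so this module converts any (p, CI) pair into pseudo-binomial
*effective counts* (x_eff, n_eff) whose log-scale variance reproduces the CI.
It also pools prevalence proportion studies (random-effects DerSimonian-Laird
on the logit scale by default) and packages the cardiomyopathy prevalence
constants used throughout: hypertrophic cardiomyopathy (HCM) ~1 in 543 adults
overall, dilated cardiomyopathy (DCM) ~1 in 220, each with sex-specific
values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.meta_analysis import combine_effects

from .errors import ConfigurationError, ValidationError

DEFAULT_LEVEL = 0.95


def z_from_level(level: float) -> float:
    """Two-sided normal quantile for a confidence level (1.959964 at 95%)."""
    if not 0.5 < level < 1:
        raise ConfigurationError(f"confidence level must be in (0.5, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2))


@dataclass(frozen=True)
class StudyProportion:
    """One prevalence study: ``affected`` of ``screened`` individuals."""

    label: str
    affected: int
    screened: int

    def __post_init__(self) -> None:
        if self.screened <= 0:
            raise ValidationError(f"{self.label}: screened must be positive")
        if not 0 <= self.affected <= self.screened:
            raise ValidationError(
                f"{self.label}: affected must be in [0, screened]"
            )

    @property
    def p(self) -> float:
        return self.affected / self.screened


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Baseline disease risk p_D with its CI and derived effective counts.

    ``x_eff``/``n_eff`` are the pseudo-binomial counts whose log-scale
    delta-method variance reproduces the CI width, allowing prevalence to
    enter the estimator exactly like an observed allele count.
    """

    p: float
    ci_low: float
    ci_high: float
    x_eff: float
    n_eff: float
    source: str = "configured"  # meta_analysis | configured | derived

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValidationError(f"prevalence must be in (0, 1), got {self.p}")
        if not 0 < self.ci_low <= self.p <= self.ci_high < 1:
            raise ValidationError(
                f"CI must satisfy 0 < low <= p <= high < 1, got "
                f"({self.ci_low}, {self.p}, {self.ci_high})"
            )
        if not math.isclose(self.x_eff / self.n_eff, self.p, rel_tol=1e-6):
            raise ValidationError("effective counts inconsistent: x_eff/n_eff != p")

    @classmethod
    def from_ci(cls, p: float, ci_low: float, ci_high: float,
                level: float = DEFAULT_LEVEL, source: str = "configured",
                ) -> "PrevalenceEstimate":
        x_eff, n_eff = effective_counts_from_ci(p, ci_low, ci_high, level)
        return cls(p=p, ci_low=ci_low, ci_high=ci_high,
                   x_eff=x_eff, n_eff=n_eff, source=source)

    @classmethod
    def from_counts(cls, x: float, n: float, level: float = DEFAULT_LEVEL,
                    source: str = "derived") -> "PrevalenceEstimate":
        """Build from (pseudo-)counts using the log-scale normal interval."""
        if x <= 0 or n <= x:
            raise ValidationError("need 0 < x < n for a log-scale interval")
        p = x / n
        z = z_from_level(level)
        half = z * math.sqrt(1 / x - 1 / n)
        return cls(p=p, ci_low=p * math.exp(-half), ci_high=p * math.exp(half),
                   x_eff=float(x), n_eff=float(n), source=source)

    def scaled(self, factor: float) -> "PrevalenceEstimate":
        """Multiply the estimate by a deterministic factor in (0, 1] (used for
        age-cumulative renormalisation); the relative CI width is preserved,
        so x_eff is unchanged."""
        if not 0 < factor <= 1:
            raise ConfigurationError(f"scale factor must be in (0, 1], got {factor}")
        return PrevalenceEstimate(
            p=self.p * factor, ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor, x_eff=self.x_eff,
            n_eff=self.n_eff / factor, source="derived",
        )


def effective_counts_from_ci(p: float, ci_low: float, ci_high: float,
                             level: float = DEFAULT_LEVEL) -> tuple[float, float]:
    """Invert a (p, CI) pair to effective counts (x_eff, n_eff).

    The CI is assumed normal on the log scale, so its standard error is
    SE = (ln ci_high - ln ci_low) / (2 z).  Matching the leading term of the
    delta-method variance of a log proportion (1/x - 1/n ~= 1/x for rare
    events) gives x_eff = 1/SE^2 and n_eff = x_eff / p.
    """
    if ci_low <= 0:
        raise ValidationError("ci_low must be positive (log-scale degeneracy at 0)")
    if not ci_low <= p <= ci_high < 1:
        raise ValidationError(
            f"need 0 < ci_low <= p <= ci_high < 1, got ({ci_low}, {p}, {ci_high})"
        )
    if ci_low == ci_high:
        raise ValidationError("degenerate CI of zero width")
    z = z_from_level(level)
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * z)
    x_eff = 1.0 / se**2
    return x_eff, x_eff / p


def meta_analyze_proportions(studies: list[StudyProportion],
                             model: str = "random",
                             level: float = DEFAULT_LEVEL,
                             continuity: bool = False) -> PrevalenceEstimate:
    """Pool prevalence studies on the logit scale.

    Random-effects (DerSimonian-Laird) is the default; ``model="fixed"``
    selects inverse-variance fixed effects.  Studies with zero affected
    individuals are rejected unless ``continuity`` is set, in which case a
    0.5 continuity correction is applied with a warning.
    """
    if len(studies) < 2:
        raise ConfigurationError("meta-analysis needs at least two studies")
    if model not in ("fixed", "random"):
        raise ConfigurationError(f"model must be 'fixed' or 'random', got {model!r}")
    x = np.array([s.affected for s in studies], dtype=float)
    n = np.array([s.screened for s in studies], dtype=float)
    zero = x == 0
    if zero.any():
        if not continuity:
            labels = ", ".join(s.label for s, z0 in zip(studies, zero) if z0)
            raise ValidationError(
                f"study with zero affected individuals ({labels}); pass "
                "continuity=True to apply a 0.5 continuity correction"
            )
        warnings.warn(
            "applying 0.5 continuity correction to zero-count studies",
            stacklevel=2,
        )
        x = np.where(zero, x + 0.5, x)
        n = np.where(zero, n + 1.0, n)

    eff = logit(x / n)
    var = 1.0 / x + 1.0 / (n - x)  # delta-method variance of a logit proportion
    with warnings.catch_warnings():
        # statsmodels leaves tau^2 unclipped and warns on sqrt(<0)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = combine_effects(eff, var, method_re="dl", use_t=False,
                              alpha=1 - level,
                              row_names=[s.label for s in studies])
        frame = res.summary_frame()
    # DerSimonian-Laird truncates tau^2 at 0; with no excess heterogeneity the
    # random-effects pool collapses to the fixed-effects one.
    if model == "random" and res.tau2 > 0:
        row = frame.loc["random effect"]
    else:
        row = frame.loc["fixed effect"]
    p = float(expit(row["eff"]))
    lo = float(expit(row["ci_low"]))
    hi = float(expit(row["ci_upp"]))
    return PrevalenceEstimate.from_ci(p, lo, hi, level=level, source="meta_analysis")


# Printed prevalence constants (fraction, CI low, CI high), overall and by sex.
# HCM pooled from four imaging-based population studies; DCM derived from the
# UK Biobank imaging cohort.
_PACKAGED = {
    ("HCM", "overall"): (0.0018, 0.0015, 0.0023),
    ("HCM", "F"): (0.0008, 0.0004, 0.0012),
    ("HCM", "M"): (0.0028, 0.0022, 0.0035),
    ("DCM", "overall"): (0.0045, 0.0039, 0.0053),
    ("DCM", "F"): (0.0030, 0.0023, 0.0038),
    ("DCM", "M"): (0.0063, 0.0052, 0.0075),
}


def packaged_prevalences(level: float = DEFAULT_LEVEL,
                         ) -> dict[tuple[str, str], PrevalenceEstimate]:
    """The packaged cardiomyopathy prevalence constants with effective counts
    derived on load.  Keys are (disease, "overall"|"F"|"M")."""
    return {
        key: PrevalenceEstimate.from_ci(p, lo, hi, level=level, source="configured")
        for key, (p, lo, hi) in _PACKAGED.items()
    }
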