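"""The core cross-sectional penetrance estimator.

Penetrance — the probability of disease given a risk allele, P(D|A) — is
estimated by Bayes' theorem from three binomial proportions:

    penetrance = prevalence x case allele frequency / population allele frequency

The point estimate is this ratio, clamped to 1.  The 95% CI treats the three
terms as independent and applies the delta method on the log scale,

    log P(D|A) = log P(D) + log P(A|D) - log P(A),

with a second-order mean correction and an adjustment for near-degenerate
counts; prevalence enters through its effective pseudo-counts.  Exact
Clopper-Pearson intervals are provided as the small-count building block and
independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .errors import DegeneracyError, ValidationError
from .prevalence import DEFAULT_LEVEL, PrevalenceEstimate, z_from_level
from .variant_table import CountPair, VariantRecord


@dataclass(frozen=True)
class PenetranceEstimate:
    """Point estimate and CI for penetrance, with reliability bookkeeping.

    ``clamped`` is set when the point or upper bound was truncated at 1;
    ``reliable`` is cleared when a contributing count is too sparse for a
    defensible CI (population allele count <= 1).  ``components`` records the
    three (x, n) pairs used: prevalence effective counts, case, population.
    """

    point: float
    ci_low: float
    ci_high: float
    clamped: bool = False
    reliable: bool = True
    components: tuple[tuple[float, float], ...] = ()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.point <= self.ci_high <= 1):
            raise ValidationError(
                f"require 0 <= ci_low <= point <= ci_high <= 1, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low

    def as_percent(self, decimals: int = 1) -> tuple[float, float, float]:
        """(point, low, high) as percentages, round-half-even."""
        scale = 100.0
        return tuple(  # type: ignore[return-value]
            float(np.round(v * scale, decimals))
            for v in (self.point, self.ci_low, self.ci_high)
        )


def binom_ci_exact(x: int, n: int, level: float = DEFAULT_LEVEL) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval for x successes out of n.

    The lower bound is 0 when x = 0 and the upper bound 1 when x = n.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValidationError(f"need 0 <= x <= n, got x={x}, n={n}")
    ci = binomtest(x, n).proportion_ci(confidence_level=level, method="exact")
    return float(ci.low), float(ci.high)


def degeneracy_adjust(x: float, n: float) -> tuple[float, float]:
    """Count adjustment applied inside CI computation for sparse counts.

    For an observed integer count of 1 or 2 the log-scale variance 1/x - 1/n
    is badly estimated, so an Anscombe-style shift (x + 0.5, n + 1) is used
    for the CI only; point estimates never pass through here.  Kept as a
    single swappable function so an alternative small-count policy can be
    substituted without touching the estimator.
    """
    if 1 <= x <= 2:
        return x + 0.5, n + 1
    return x, n


def log_prop_moments(x: float, n: float) -> tuple[float, float]:
    """Delta-method moments of the log of a binomial proportion.

    For p_hat = x/n:  var[ln p_hat] ~= 1/x - 1/n, and the second-order
    bias-corrected estimator of ln p is ln p_hat + (1 - p_hat)/(2x).
    ``x`` may be a real effective count.  A zero count is degenerate; the
    caller must apply the degeneracy policy first.
    """
    if x <= 0:
        raise DegeneracyError("log-scale moments undefined at x = 0")
    if n <= x:
        raise DegeneracyError("need x < n for a finite log-scale variance")
    p_hat = x / n
    return math.log(p_hat) + (1 - p_hat) / (2 * x), 1 / x - 1 / n


def estimate_penetrance(prev: PrevalenceEstimate, case: CountPair,
                        pop: CountPair, level: float = DEFAULT_LEVEL,
                        ) -> PenetranceEstimate:
    """Penetrance point estimate and CI from prevalence plus case and
    population allele counts.

    The point estimate is prev.p x (case AF / population AF), clamped at 1.
    On the log scale the mean is the sum of the three bias-corrected means
    (population entering negatively) and the variance the sum of the three
    variances, prevalence contributing via its effective counts.  Counts of
    1 or 2 are shifted by the degeneracy adjustment inside the CI only, and
    the estimate is flagged unreliable when the population count is 0 or 1.
    """
    if case.ac == 0:
        raise ValidationError("variant not observed in the case series (case ac = 0)")
    if pop.ac == 0:
        raise DegeneracyError(
            "population allele count of 0: population AF cannot be estimated; "
            "route the variant to groups G1/G4 as unreliable"
        )
    z = z_from_level(level)
    point_raw = prev.p * case.af / pop.af

    m_prev, v_prev = log_prop_moments(prev.x_eff, prev.n_eff)
    m_case, v_case = log_prop_moments(*degeneracy_adjust(case.ac, case.an))
    m_pop, v_pop = log_prop_moments(*degeneracy_adjust(pop.ac, pop.an))
    mean = m_prev + m_case - m_pop
    half = z * math.sqrt(v_prev + v_case + v_pop)

    lo = min(1.0, math.exp(mean - half))
    hi = math.exp(mean + half)
    clamped = point_raw > 1 or hi > 1
    point = min(1.0, point_raw)
    hi = min(1.0, hi)
    lo = min(lo, point)
    hi = max(hi, point)
    return PenetranceEstimate(
        point=point, ci_low=lo, ci_high=hi, clamped=clamped,
        reliable=pop.ac > 1,
        components=((prev.x_eff, prev.n_eff), (case.ac, case.an), (pop.ac, pop.an)),
    )


def aggregate_penetrance(prev: PrevalenceEstimate, variants: list[VariantRecord],
                         case_cohort_an: int, pop_cohort_an: int,
                         level: float = DEFAULT_LEVEL) -> PenetranceEstimate:
    """Aggregate penetrance of a variant set: allele counts are pooled over
    the set and divided by the cohort-level allele numbers.

    Subgroup selection (ACMG class, consequence class, rarity bin, gene) is
    expressed as a filter before aggregation.  All variants must share one
    disease.
    """
    if not variants:
        raise ValidationError("cannot aggregate an empty variant list")
    diseases = {v.disease for v in variants}
    if len(diseases) > 1:
        raise ValidationError(f"mixed diseases in one aggregate: {sorted(diseases)}")
    case = CountPair(sum(v.case_counts.ac for v in variants), case_cohort_an)
    pop = CountPair(sum(v.pop_counts.ac for v in variants), pop_cohort_an)
    return estimate_penetrance(prev, case, pop, level=level)


def penetrance_ci_array(prev: PrevalenceEstimate,
                        case_ac: np.ndarray, case_an: np.ndarray,
                        pop_ac: np.ndarray, pop_an: np.ndarray,
                        level: float = DEFAULT_LEVEL,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (point, ci_low, ci_high) over arrays of count pairs.

    Applies the same degeneracy policy as :func:`estimate_penetrance`; any
    entry with case ac = 0 or pop ac = 0 yields NaNs (the scalar path raises
    instead).  Used by the simulation machinery where millions of replicate
    estimates are needed.
    """
    case_ac = np.asarray(case_ac, dtype=float)
    case_an = np.asarray(case_an, dtype=float)
    pop_ac = np.asarray(pop_ac, dtype=float)
    pop_an = np.asarray(pop_an, dtype=float)
    z = z_from_level(level)

    with np.errstate(divide="ignore", invalid="ignore"):
        point = np.minimum(1.0, prev.p * (case_ac / case_an) / (pop_ac / pop_an))

        def moments(x, n):
            adj = (x >= 1) & (x <= 2)
            xs = np.where(adj, x + 0.5, x)
            ns = np.where(adj, n + 1, n)
            p_hat = xs / ns
            return np.log(p_hat) + (1 - p_hat) / (2 * xs), 1 / xs - 1 / ns

        m_prev, v_prev = log_prop_moments(prev.x_eff, prev.n_eff)
        m_case, v_case = moments(case_ac, case_an)
        m_pop, v_pop = moments(pop_ac, pop_an)
        mean = m_prev + m_case - m_pop
        half = z * np.sqrt(v_prev + v_case + v_pop)
        lo = np.minimum(1.0, np.exp(mean - half))
        hi = np.minimum(1.0, np.exp(mean + half))

    bad = (case_ac < 1) | (pop_ac < 1)
    for arr in (point, lo, hi):
        arr[bad] = np.nan
    return point, lo, hi
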