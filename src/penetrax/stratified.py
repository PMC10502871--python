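"""Sex-, ancestry- and age-stratified penetrance.

Three distinct recipes:

* by sex — every term of the penetrance equation is replaced by its
  sex-specific value (prevalence, case counts, population counts);
* by ancestry — prevalence is kept at the disease-level estimate (too few
  ancestry-specific prevalence studies exist) while case and population
  allele frequencies are proportioned by reported ancestry;
* by age — prevalence is renormalised by the cumulative fraction of the case
  cohort diagnosed by each age, the case allele frequency is taken
  cumulatively by age, and the population allele frequency stays fixed,
  yielding a cumulative penetrance-by-age curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .errors import ValidationError
from .estimator import PenetranceEstimate, estimate_penetrance
from .prevalence import DEFAULT_LEVEL, PrevalenceEstimate
from .variant_table import SEXES, CountPair, VariantRecord

logger = logging.getLogger(__name__)

#: Below this stratum allele count the estimate carries a sparse-data caveat.
SPARSE_AC = 5


@dataclass(frozen=True)
class AgeGrid:
    """Cumulative case-cohort observations by decade.

    ``ages`` are decade upper bounds in years ("20s" is evaluated at 30);
    ``cum_diagnosed`` counts case-cohort individuals diagnosed by each age;
    ``cum_case`` holds the cumulative variant carriers over cumulative
    alleles (2 x individuals with known age <= bound) by each age.  All
    cumulative quantities must be non-decreasing.
    """

    ages: tuple[int, ...]
    cum_diagnosed: tuple[int, ...]
    cum_case: tuple[CountPair, ...]

    def __post_init__(self) -> None:
        if not self.ages:
            raise ValidationError("age grid is empty")
        if not (len(self.ages) == len(self.cum_diagnosed) == len(self.cum_case)):
            raise ValidationError("age grid fields have mismatched lengths")
        for name, seq in (("ages", self.ages),
                          ("cum_diagnosed", self.cum_diagnosed),
                          ("cum_case ac", [c.ac for c in self.cum_case]),
                          ("cum_case an", [c.an for c in self.cum_case])):
            if any(b < a for a, b in zip(seq, seq[1:])):
                raise ValidationError(f"{name} must be non-decreasing")
        if self.cum_diagnosed[-1] <= 0:
            raise ValidationError("no diagnosed individuals in the final decade")


def penetrance_by_sex(prev_by_sex: dict[str, PrevalenceEstimate],
                      variant: VariantRecord, level: float = DEFAULT_LEVEL,
                      ) -> tuple[dict[str, PenetranceEstimate], bool]:
    """Sex-specific penetrance with all terms stratified by sex.

    Returns the per-sex estimates and a flag that is set when the female and
    male CIs do not overlap (a conservative screen for a sex difference).
    A missing sex stratum drops that sex from the output with a warning.
    """
    out: dict[str, PenetranceEstimate] = {}
    for sex in SEXES:
        case = variant.stratum("case", sex)
        pop = variant.stratum("pop", sex)
        if case is None or pop is None or sex not in prev_by_sex:
            logger.warning("%s: missing %s stratum, skipping", variant.variant_id, sex)
            continue
        out[sex] = estimate_penetrance(prev_by_sex[sex], case, pop, level=level)
    disjoint = False
    if set(out) == set(SEXES):
        f, m = out["F"], out["M"]
        disjoint = f.ci_high < m.ci_low or m.ci_high < f.ci_low
    return out, disjoint


def penetrance_by_ancestry(prev: PrevalenceEstimate, variant: VariantRecord,
                           ancestries: set[str] | tuple[str, ...],
                           level: float = DEFAULT_LEVEL,
                           ) -> dict[str, PenetranceEstimate]:
    """Per-ancestry penetrance with a shared disease-level prevalence.

    Estimates carry a ``sparse_stratum`` note when either side's stratum
    allele count is below 5; an ancestry whose population count is 0 is
    omitted (degeneracy policy) with a warning, as is one lacking strata.
    """
    out: dict[str, PenetranceEstimate] = {}
    for anc in ancestries:
        case = variant.stratum("case", anc)
        pop = variant.stratum("pop", anc)
        if case is None or pop is None:
            logger.warning("%s: no %s stratum data, omitting",
                           variant.variant_id, anc)
            continue
        if case.ac == 0 or pop.ac == 0:
            logger.warning("%s: zero %s allele count, unreliable — omitting",
                           variant.variant_id, anc)
            continue
        est = estimate_penetrance(prev, case, pop, level=level)
        if min(case.ac, pop.ac) < SPARSE_AC:
            est = replace(est, notes=est.notes + ("sparse_stratum",))
        out[anc] = est
    return out


def penetrance_by_age(prev: PrevalenceEstimate, grid: AgeGrid, pop: CountPair,
                      level: float = DEFAULT_LEVEL,
                      ) -> list[tuple[int, PenetranceEstimate]]:
    """Cumulative penetrance by age.

    At each decade bound *a*, prevalence is scaled by the cumulative fraction
    of the case cohort diagnosed by *a*, the case counts are the cumulative
    carriers/alleles by *a*, and the population AF is the fixed overall value.
    The final decade therefore reproduces the unstratified estimate.  Decades
    with no cumulative carriers yet return a point of 0 with an upper bound
    from a pseudo-count of one carrier, flagged unreliable — late-onset
    variants show a curve near 0 before their onset ages.
    """
    total = grid.cum_diagnosed[-1]
    out: list[tuple[int, PenetranceEstimate]] = []
    for age, diag, case in zip(grid.ages, grid.cum_diagnosed, grid.cum_case):
        if diag == 0 or case.ac == 0:
            upper = 0.0
            if case.an > 0 and diag > 0:
                shifted = estimate_penetrance(
                    prev.scaled(diag / total),
                    CountPair(1, case.an + 1), pop, level=level)
                upper = shifted.ci_high
            est = PenetranceEstimate(point=0.0, ci_low=0.0, ci_high=upper,
                                     reliable=False,
                                     notes=("no_carriers_by_age",))
        else:
            est = estimate_penetrance(prev.scaled(diag / total), case, pop,
                                      level=level)
        out.append((age, est))
    return out
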