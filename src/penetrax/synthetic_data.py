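"""Synthetic case/population cohorts with known ground truth.

The generator runs the penetrance identity forward: given a true penetrance,
a true population allele frequency and the disease prevalence, the implied
case allele frequency is ``penetrance x pop AF / prevalence`` and both cohorts
are sampled binomially at their allele numbers.  Because the generative model
is exactly the inferential model, parameter-recovery and CI-coverage tests on
these cohorts are directly interpretable.  Sex strata are drawn as primary
binomials (so they sum to the totals exactly), ancestry strata are a
multinomial split of the totals, and each case carrier receives an age at
diagnosis from a truncated normal to populate the cumulative age grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigurationError, ValidationError
from .prevalence import PrevalenceEstimate
from .variant_table import (CountPair, VariantRecord, to_frame)

#: Default decade upper bounds for the cumulative age grid ("20s" = by 30).
DEFAULT_AGE_BOUNDS = (30, 40, 50, 60, 70, 80)

#: Age-at-diagnosis of the cohort at large (used for the cumulative
#: denominator): mid-life onset typical of dominant cardiomyopathy.
COHORT_ONSET_MEAN, COHORT_ONSET_SD = 50.0, 13.0


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth parameters for one synthetic variant.

    ``sex_af_ratio`` is the male:female population AF ratio; ``ancestry_af``
    optionally gives per-ancestry population AFs (the cohort-level AF is then
    their composition-weighted mixture).  Onset ages are truncated-normal
    parameters in years, a fixture-modelling choice (no onset model is implied
    by the estimator itself).
    """

    variant_id: str
    gene: str
    disease: str
    true_pop_af: float
    true_penetrance: float
    acmg_class: str = "unclassified"
    consequence_class: str = "other_PAV"
    sex_af_ratio: float = 1.0
    ancestry_af: dict[str, float] | None = None
    onset_age_mean: float = 50.0
    onset_age_sd: float = 12.0

    def __post_init__(self) -> None:
        if not 0 < self.true_pop_af < 1:
            raise ValidationError(f"{self.variant_id}: pop AF must be in (0, 1)")
        if not 0 < self.true_penetrance <= 1:
            raise ValidationError(f"{self.variant_id}: penetrance must be in (0, 1]")
        if self.sex_af_ratio <= 0:
            raise ValidationError(f"{self.variant_id}: sex AF ratio must be positive")


def _truncnorm_ages(rng: np.random.Generator, n: int, mean: float, sd: float,
                    ) -> np.ndarray:
    a, b = (0 - mean) / sd, (100 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _split_by_weights(rng: np.random.Generator, total: int,
                      weights: np.ndarray, caps: np.ndarray) -> np.ndarray:
    """Multinomial split of ``total`` with per-bin caps (stratum ANs)."""
    w = weights / weights.sum()
    counts = rng.multinomial(total, w)
    # redistribute any overflow above a stratum's allele number
    for _ in range(10):
        over = counts - caps
        excess = int(np.clip(over, 0, None).sum())
        if excess == 0:
            break
        counts = np.minimum(counts, caps)
        room = caps - counts
        w2 = np.where(room > 0, w, 0.0)
        if w2.sum() == 0:
            raise ValidationError("stratum allele numbers too small for the total count")
        counts = counts + rng.multinomial(excess, w2 / w2.sum())
    return np.minimum(counts, caps)


def generate_cohorts(
    truths: list[TruthRecord],
    prev: PrevalenceEstimate,
    n_case: int,
    n_pop: int,
    seed: int,
    prev_by_sex: dict[str, PrevalenceEstimate] | None = None,
    case_female_fraction: float | None = None,
    pop_female_fraction: float = 0.5,
    case_ancestry_comp: dict[str, float] | None = None,
    pop_ancestry_comp: dict[str, float] | None = None,
    age_bounds: tuple[int, ...] = DEFAULT_AGE_BOUNDS,
    stratify: bool = True,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Draw one synthetic case cohort and population cohort.

    Returns the observable variant records and the truth table (one row per
    variant with its generating parameters).  Fully reproducible from
    ``seed``.  Raises if any variant's implied case allele frequency exceeds
    1 (true_penetrance x pop AF must not exceed the prevalence).
    """
    if n_case < 1 or n_pop < 1:
        raise ConfigurationError("cohort sizes must be at least 1")
    rng = np.random.default_rng(seed)
    prev_by_sex = prev_by_sex or {"F": prev, "M": prev}
    if case_female_fraction is None:
        # diagnosed cases follow the disease sex ratio (equal sexes at birth)
        p_f, p_m = prev_by_sex["F"].p, prev_by_sex["M"].p
        case_female_fraction = p_f / (p_f + p_m)

    n_case_sex = {"F": round(n_case * case_female_fraction)}
    n_case_sex["M"] = n_case - n_case_sex["F"]
    n_pop_sex = {"F": round(n_pop * pop_female_fraction)}
    n_pop_sex["M"] = n_pop - n_pop_sex["F"]

    # cohort-wide ages at diagnosis drive the cumulative AN denominator
    if stratify:
        cohort_ages = _truncnorm_ages(rng, n_case, COHORT_ONSET_MEAN,
                                      COHORT_ONSET_SD)
        cum_diag = {a: int((cohort_ages <= a).sum()) for a in age_bounds}

    records: list[VariantRecord] = []
    truth_rows = []
    for t in truths:
        if t.ancestry_af:
            comp_pop = pop_ancestry_comp or {k: 1 / len(t.ancestry_af)
                                             for k in t.ancestry_af}
            comp_case = case_ancestry_comp or comp_pop
            pop_af = sum(comp_pop[a] * t.ancestry_af[a] for a in t.ancestry_af)
            case_af = sum(comp_case[a] * t.true_penetrance * t.ancestry_af[a] / prev.p
                          for a in t.ancestry_af)
        else:
            pop_af = t.true_pop_af
            case_af = t.true_penetrance * pop_af / prev.p
        if case_af > 1:
            raise ValidationError(
                f"{t.variant_id}: implied case allele frequency {case_af:.3g} "
                "exceeds 1 (penetrance x pop AF > prevalence)"
            )

        r = t.sex_af_ratio
        af_sex = {"F": 2 * pop_af / (1 + r), "M": 2 * pop_af * r / (1 + r)}
        strata: dict[tuple[str, str], CountPair] = {}
        case_total = pop_total = 0
        if stratify:
            for sex in ("F", "M"):
                ca_sex = min(1.0, t.true_penetrance * af_sex[sex] / prev_by_sex[sex].p)
                c_an = 2 * n_case_sex[sex]
                p_an = 2 * n_pop_sex[sex]
                c_ac = int(rng.binomial(c_an, ca_sex))
                p_ac = int(rng.binomial(p_an, min(1.0, af_sex[sex])))
                strata[("case", sex)] = CountPair(c_ac, c_an)
                strata[("pop", sex)] = CountPair(p_ac, p_an)
                case_total += c_ac
                pop_total += p_ac
        else:
            case_total = int(rng.binomial(2 * n_case, case_af))
            pop_total = int(rng.binomial(2 * n_pop, pop_af))

        case_pair = CountPair(case_total, 2 * n_case)
        pop_pair = CountPair(pop_total, 2 * n_pop)

        if t.ancestry_af and stratify:
            ancs = sorted(t.ancestry_af)
            for side, total, comp, n_side in (
                    ("case", case_total, comp_case, n_case),
                    ("pop", pop_total, comp_pop, n_pop)):
                caps = np.array([2 * round(n_side * comp[a]) for a in ancs])
                weights = np.array([comp[a] * t.ancestry_af[a] for a in ancs])
                counts = _split_by_weights(rng, total, weights, caps)
                for a, ac, cap in zip(ancs, counts, caps):
                    if cap > 0:
                        strata[(side, a)] = CountPair(int(ac), int(cap))

        if stratify:
            carrier_ages = _truncnorm_ages(rng, case_total,
                                           t.onset_age_mean, t.onset_age_sd)
            for a in age_bounds:
                strata[("case", f"age{a}")] = CountPair(
                    int((carrier_ages <= a).sum()), 2 * cum_diag[a])

        records.append(VariantRecord(
            variant_id=t.variant_id, gene=t.gene, disease=t.disease,
            case_counts=case_pair, pop_counts=pop_pair,
            consequence_class=t.consequence_class, acmg_class=t.acmg_class,
            strata=strata))
        truth_rows.append({
            "variant_id": t.variant_id, "gene": t.gene, "disease": t.disease,
            "acmg_class": t.acmg_class,
            "consequence_class": t.consequence_class,
            "true_pop_af": pop_af, "true_penetrance": t.true_penetrance,
            "sex_af_ratio": t.sex_af_ratio,
            "onset_age_mean": t.onset_age_mean,
            "onset_age_sd": t.onset_age_sd})
    return records, pd.DataFrame(truth_rows)


def fixture_suite(seed: int) -> dict[str, pd.DataFrame]:
    """Deterministic mini-fixtures for unit tests.

    * ``groups`` — ten hand-specified variants spanning all four recurrence
      groups at realistic cohort allele numbers;
    * ``degenerate`` — variants absent or singleton in the reference set,
      including a ``.`` (missing) population count;
    * ``stratified`` — a generated table with both sexes, three ancestries
      and five age decades.
    """
    case_an, pop_an = 20_800, 586_452
    group_spec = [  # (case_ac, pop_ac) covering G1..G4
        ("v1", "MYH7", 2, 0), ("v2", "MYBPC3", 3, 1),        # G1
        ("v3", "MYBPC3", 5, 2), ("v4", "TNNT2", 4, 6),       # G2
        ("v5", "TPM1", 12, 20), ("v6", "TNNI3", 2, 3),       # G2
        ("v7", "MYL2", 1, 2), ("v8", "ACTC1", 1, 5),         # G3
        ("v9", "MYL3", 1, 0), ("v10", "MYH7", 1, 1),         # G4
    ]
    acmg = ["P", "LP", "P", "VUS", "LP", "VUS", "VUS", "LB", "LP", "VUS"]
    csq = ["missense", "PTC_NMDc", "splice", "inframe_deletion", "missense",
           "missense", "other_PAV", "missense", "PTC_NMDi", "missense"]
    groups = [VariantRecord(vid, gene, "HCM", CountPair(ca, case_an),
                            CountPair(pa, pop_an), consequence_class=c,
                            acmg_class=a)
              for (vid, gene, ca, pa), a, c in zip(group_spec, acmg, csq)]

    degen = [
        VariantRecord("d1", "MYH7", "HCM", CountPair(3, case_an),
                      CountPair(0, pop_an), acmg_class="P",
                      flags={"absent_from_reference"}),
        VariantRecord("d2", "MYBPC3", "HCM", CountPair(2, case_an),
                      CountPair(1, pop_an), acmg_class="LP"),
        VariantRecord("d3", "TNNT2", "HCM", CountPair(1, case_an),
                      CountPair(0, pop_an)),
    ]

    prev = PrevalenceEstimate.from_ci(0.0018, 0.0015, 0.0023)
    prev_sex = {"F": PrevalenceEstimate.from_ci(0.0008, 0.0004, 0.0012),
                "M": PrevalenceEstimate.from_ci(0.0028, 0.0022, 0.0035)}
    anc_af = {"AFR": 3e-4, "EUR": 2e-4, "SAS": 2.5e-4}
    truths = [
        TruthRecord("s1", "MYBPC3", "HCM", 2e-4, 0.25, acmg_class="LP",
                    sex_af_ratio=1.0, ancestry_af=anc_af, onset_age_mean=45),
        TruthRecord("s2", "MYH7", "HCM", 3e-4, 0.10, acmg_class="VUS",
                    sex_af_ratio=1.5, ancestry_af=anc_af, onset_age_mean=55),
        TruthRecord("s3", "TNNT2", "HCM", 1e-4, 0.40, acmg_class="P",
                    ancestry_af=anc_af, onset_age_mean=35, onset_age_sd=8),
    ]
    strat_records, _ = generate_cohorts(
        truths, prev, n_case=4000, n_pop=150_000, seed=seed,
        prev_by_sex=prev_sex,
        case_ancestry_comp={"AFR": 0.1, "EUR": 0.8, "SAS": 0.1},
        pop_ancestry_comp={"AFR": 0.1, "EUR": 0.8, "SAS": 0.1},
        age_bounds=(30, 40, 50, 60, 70))

    return {"groups": to_frame(groups), "degenerate": to_frame(degen),
            "stratified": to_frame(strat_records)}
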