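"""Variant count tables: reading, validation, rarity filtering and group assignment.

Every downstream stage consumes the records produced here.  A record carries
a case-cohort and a population-cohort binomial observation (allele count over
allele number) plus optional per-stratum observations keyed by sex, ancestry
group or age-decade upper bound.

The interchange format is a plain tab-separated table with a header row,
UTF-8, no quoting, and ``.`` marking a missing value.  Stratum columns follow
a suffix convention: ``case_ac_F``, ``pop_ac_AFR``, ``case_ac_age50`` and the
matching ``*_an_*`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Genes with strong/definitive evidence for each dominant cardiomyopathy.
#: Disease determines the admissible gene list.
HCM_GENES = frozenset(
    {"MYH7", "MYBPC3", "MYL2", "MYL3", "ACTC1", "TNNI3", "TNNT2", "TPM1"}
)
DCM_GENES = frozenset(
    {"BAG3", "DES", "DSP", "LMNA", "MYH7", "PLN", "RBM20", "SCN5A", "TNNC1",
     "TNNT2", "TTN"}
)
GENES_BY_DISEASE = {"HCM": HCM_GENES, "DCM": DCM_GENES}

CONSEQUENCE_CLASSES = frozenset(
    {"PTC_NMDc", "PTC_NMDi", "missense", "inframe_deletion", "splice",
     "other_PAV"}
)
ACMG_CLASSES = frozenset({"P", "LP", "VUS", "LB", "B", "unclassified"})
DISEASES = frozenset({"HCM", "DCM"})
SEXES = ("F", "M")
ANCESTRIES = ("AFR", "EAS", "EUR", "SAS", "other")

GROUPS = ("G1", "G2", "G3", "G4")

#: Default rarity threshold: inclusive population allele frequency < 0.1%.
DEFAULT_MAX_POP_AF = 0.001

REQUIRED_COLUMNS = (
    "variant_id", "gene", "disease", "case_ac", "case_an", "pop_ac", "pop_an",
)

MISSING = "."


@dataclass(frozen=True)
class CountPair:
    """A binomial allele observation: ``ac`` alternate alleles out of ``an``
    alleles genotyped (``an`` = 2 x individuals at autosomal diploid loci)."""

    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.an <= 0:
            raise ValidationError(f"allele number must be positive, got an={self.an}")
        if not 0 <= self.ac <= self.an:
            raise ValidationError(
                f"allele count must satisfy 0 <= ac <= an, got ac={self.ac}, an={self.an}"
            )

    @property
    def af(self) -> float:
        """Allele frequency ac/an."""
        return self.ac / self.an


@dataclass
class VariantRecord:
    """One variant's identity, annotations and count observations.

    ``strata`` maps ``(side, stratum)`` -> :class:`CountPair`, where *side* is
    ``"case"`` or ``"pop"`` and *stratum* is a sex (``F``/``M``), an ancestry
    group (``AFR``...) or an age-decade label (``age50`` = by 50 years old).
    """

    variant_id: str
    gene: str
    disease: str
    case_counts: CountPair
    pop_counts: CountPair
    consequence_class: str = "other_PAV"
    acmg_class: str = "unclassified"
    strata: dict[tuple[str, str], CountPair] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValidationError(
                f"{self.variant_id}: unknown disease {self.disease!r}"
            )
        if self.gene not in GENES_BY_DISEASE[self.disease]:
            raise ValidationError(
                f"{self.variant_id}: gene {self.gene!r} is not on the "
                f"{self.disease} panel"
            )
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValidationError(
                f"{self.variant_id}: unknown consequence class "
                f"{self.consequence_class!r}"
            )
        if self.acmg_class not in ACMG_CLASSES:
            raise ValidationError(
                f"{self.variant_id}: unknown ACMG class {self.acmg_class!r}"
            )

    def stratum(self, side: str, key: str) -> CountPair | None:
        return self.strata.get((side, key))

    @property
    def pop_af(self) -> float:
        return self.pop_counts.af

    @property
    def case_af(self) -> float:
        return self.case_counts.af


def classify_group(case_ac: int, pop_ac: int) -> str:
    """Assign a variant to one of the four recurrence groups.

    Group 1: recurrent in cases (AC >= 2), absent/singleton in the population;
    group 2: recurrent in both (the only group supporting per-variant
    penetrance estimation); group 3: case singleton, population recurrent;
    group 4: singleton in cases and absent/singleton in the population.
    The four groups partition all (case_ac >= 1, pop_ac >= 0) outcomes.
    """
    if case_ac < 0 or pop_ac < 0:
        raise ValidationError("allele counts must be non-negative")
    if case_ac == 0:
        raise ValidationError("variant not observed in the case series (case_ac = 0)")
    if case_ac >= 2:
        return "G1" if pop_ac <= 1 else "G2"
    return "G4" if pop_ac <= 1 else "G3"


def filter_variants(
    records: list[VariantRecord],
    max_pop_af: float = DEFAULT_MAX_POP_AF,
    genes: frozenset[str] | set[str] | None = None,
    classes: frozenset[str] | set[str] | None = None,
) -> list[VariantRecord]:
    """Retain rare variants (population AF strictly below ``max_pop_af``) in
    the requested genes and consequence classes.

    ``genes``/``classes`` of ``None`` apply no restriction on that axis.
    The output is a subset of the input and the operation is idempotent.
    """
    if not 0 < max_pop_af <= 1:
        raise ConfigurationError(f"max_pop_af must be in (0, 1], got {max_pop_af}")
    if genes is not None and len(genes) == 0:
        raise ConfigurationError("empty gene set would retain nothing")
    if classes is not None and len(classes) == 0:
        raise ConfigurationError("empty consequence-class set would retain nothing")
    out = []
    for rec in records:
        if rec.pop_counts.af >= max_pop_af:
            continue
        if genes is not None and rec.gene not in genes:
            continue
        if classes is not None and rec.consequence_class not in classes:
            continue
        out.append(rec)
    return out


def _parse_int(value: str, column: str, row_label: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row_label}: column {column!r} is not an integer ({value!r})"
        ) from None


def _stratum_columns(columns: list[str]) -> dict[tuple[str, str], tuple[str, str]]:
    """Map (side, stratum) -> (ac column, an column) from suffixed headers."""
    found: dict[tuple[str, str], tuple[str, str]] = {}
    for col in columns:
        for side in ("case", "pop"):
            prefix = f"{side}_ac_"
            if col.startswith(prefix):
                key = col[len(prefix):]
                an_col = f"{side}_an_{key}"
                if an_col not in columns:
                    raise ConfigurationError(
                        f"stratum column {col!r} has no matching {an_col!r}"
                    )
                found[(side, key)] = (col, an_col)
    return found


def read_variant_table(path, sep: str = "\t") -> list[VariantRecord]:
    """Read and validate a variant count table.

    Rows violating count invariants raise :class:`ValidationError` naming the
    row; a missing required column raises :class:`ConfigurationError`.  A
    population allele count of ``.`` is read as 0 and the record is flagged
    ``absent_from_reference`` (absence from the reference set is itself an
    analysis category, not an error).
    """
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                        quoting=3, encoding="utf-8")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    strata_cols = _stratum_columns(list(frame.columns))

    records: list[VariantRecord] = []
    for idx, row in frame.iterrows():
        label = f"{idx + 2} (variant_id={row['variant_id']})"  # 1-based + header
        flags: set[str] = set()
        pop_ac_raw = row["pop_ac"]
        if pop_ac_raw == MISSING:
            pop_ac = 0
            flags.add("absent_from_reference")
        else:
            pop_ac = _parse_int(pop_ac_raw, "pop_ac", label)
        try:
            case = CountPair(_parse_int(row["case_ac"], "case_ac", label),
                             _parse_int(row["case_an"], "case_an", label))
            pop = CountPair(pop_ac, _parse_int(row["pop_an"], "pop_an", label))
            strata: dict[tuple[str, str], CountPair] = {}
            for (side, key), (ac_col, an_col) in strata_cols.items():
                ac_raw, an_raw = row[ac_col], row[an_col]
                if ac_raw == MISSING or an_raw == MISSING:
                    continue
                strata[(side, key)] = CountPair(
                    _parse_int(ac_raw, ac_col, label),
                    _parse_int(an_raw, an_col, label),
                )
            rec = VariantRecord(
                variant_id=row["variant_id"],
                gene=row["gene"],
                disease=row["disease"],
                case_counts=case,
                pop_counts=pop,
                consequence_class=row.get("consequence_class", "other_PAV") or "other_PAV",
                acmg_class=row.get("acmg_class", "unclassified") or "unclassified",
                strata=strata,
                flags=flags,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {label}: {exc}") from None
        _check_stratum_sums(rec, label)
        records.append(rec)
    return records


def _check_stratum_sums(rec: VariantRecord, label: str) -> None:
    """Stratum allele counts on one axis must not exceed the unstratified
    total (missing stratum data is allowed, so <= not ==)."""
    for side, total in (("case", rec.case_counts), ("pop", rec.pop_counts)):
        for axis_keys in (SEXES, ANCESTRIES):
            acs = [rec.strata[(side, k)].ac for k in axis_keys
                   if (side, k) in rec.strata]
            if acs and sum(acs) > total.ac:
                raise ValidationError(
                    f"row {label}: {side} stratum allele counts "
                    f"({sum(acs)}) exceed the total ({total.ac})"
                )


def to_frame(records: list[VariantRecord]) -> pd.DataFrame:
    """Serialize records back to the tabular dialect (inverse of reading)."""
    stratum_keys = sorted({k for rec in records for k in rec.strata},
                          key=lambda sk: (sk[0], sk[1]))
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "variant_id": rec.variant_id,
            "gene": rec.gene,
            "disease": rec.disease,
            "consequence_class": rec.consequence_class,
            "acmg_class": rec.acmg_class,
            "case_ac": rec.case_counts.ac,
            "case_an": rec.case_counts.an,
            "pop_ac": MISSING if "absent_from_reference" in rec.flags
            else rec.pop_counts.ac,
            "pop_an": rec.pop_counts.an,
        }
        for side, key in stratum_keys:
            pair = rec.strata.get((side, key))
            row[f"{side}_ac_{key}"] = MISSING if pair is None else pair.ac
            row[f"{side}_an_{key}"] = MISSING if pair is None else pair.an
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_table(records: list[VariantRecord], path, sep: str = "\t") -> None:
    to_frame(records).to_csv(path, sep=sep, index=False, encoding="utf-8")


def restrict_to_stratum(rec: VariantRecord, key: str) -> VariantRecord | None:
    """Return a copy of ``rec`` whose totals are the given stratum's counts,
    or ``None`` when either side lacks that stratum."""
    case = rec.stratum("case", key)
    pop = rec.stratum("pop", key)
    if case is None or pop is None:
        return None
    return replace(rec, case_counts=case, pop_counts=pop, strata={})
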