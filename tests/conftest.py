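import pandas as pd
import pytest

from penetrax import (CountPair, PrevalenceEstimate, VariantRecord,
                      fixture_suite, packaged_prevalences)


@pytest.fixture(scope="session")
def prev_hcm() -> PrevalenceEstimate:
    return packaged_prevalences()[("HCM", "overall")]


@pytest.fixture(scope="session")
def prev_by_sex() -> dict[str, PrevalenceEstimate]:
    table = packaged_prevalences()
    return {"F": table[("HCM", "F")], "M": table[("HCM", "M")]}


@pytest.fixture(scope="session")
def fixtures() -> dict[str, pd.DataFrame]:
    return fixture_suite(seed=7)


@pytest.fixture()
def groups_table_path(fixtures, tmp_path):
    path = tmp_path / "groups.tsv"
    fixtures["groups"].to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def make_record():
    """Factory for a minimal valid HCM variant record."""

    def _make(case_ac=4, case_an=20_800, pop_ac=20, pop_an=586_452, **kw):
        defaults = dict(variant_id="vX", gene="MYBPC3", disease="HCM")
        defaults.update(kw)
        return VariantRecord(case_counts=CountPair(case_ac, case_an),
                             pop_counts=CountPair(pop_ac, pop_an), **defaults)

    return _make
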