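from pathlib import Path

import pytest

from thyrocv.records import (
    EffectEstimate,
    StudyRecord,
    read_extraction_table,
)

DATA = Path(__file__).parent / "data"


def make_screening_fixture() -> list[StudyRecord]:
    """Ten records with planted violations: 2 duplicates, 1 human
    cell-culture study, 1 non-thyroidal-illness study, 6 clean.

    Hand enumeration: s01-s06 included; s07, s08 excluded as
    "duplicate"; s09 as "animal/cell"; s10 as "NTI".
    """
    clean = dict(
        design="prospective", n_subjects=1000, followup_years=5.0, nos_score=8
    )
    records = [
        StudyRecord(f"s{i:02d}", f"Author{i}", 2010 + i, **clean)
        for i in range(1, 7)
    ]
    records.append(
        StudyRecord("s07", "Author7", 2017, duplicate_of="s01", **clean)
    )
    records.append(
        StudyRecord("s08", "Author8", 2018, duplicate_of="s02", **clean)
    )
    records.append(
        StudyRecord("s09", "Author9", 2019, is_animal_or_cell=True, **clean)
    )
    records.append(StudyRecord("s10", "Author10", 2020, is_nti_study=True, **clean))
    return records


@pytest.fixture
def screening_records() -> list[StudyRecord]:
    return make_screening_fixture()


@pytest.fixture(scope="session")
def extraction_table() -> tuple[list[StudyRecord], list[EffectEstimate]]:
    """The shipped 18-study / 31-estimate synthetic extraction table."""
    return read_extraction_table(
        DATA / "synthetic_studies.csv", DATA / "synthetic_estimates.csv"
    )


@pytest.fixture
def fixture_paths() -> tuple[Path, Path]:
    return DATA / "synthetic_studies.csv", DATA / "synthetic_estimates.csv"
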