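import pytest

from snpmeta import GenotypeCounts, StudyRecord, StudySet, load_table1


@pytest.fixture(scope="session")
def table1_all() -> StudySet:
    return load_table1()


@pytest.fixture(scope="session")
def rs1333049(table1_all) -> StudySet:
    return table1_all.filter(variant="rs1333049")


@pytest.fixture(scope="session")
def rs4977574(table1_all) -> StudySet:
    return table1_all.filter(variant="rs4977574")


@pytest.fixture
def suleiman() -> StudyRecord:
    """The smallest study of the panel: 50 cases / 50 controls from Iraq."""
    return StudyRecord(
        study_id="Suleiman2019_Iraq_rs1333049",
        author="Suleiman", year=2019, origin="Iraq", variant="rs1333049",
        phenotype="CAD", ethnicity="West Asian", control_source="HB",
        cases=GenotypeCounts(9, 22, 19),
        controls=GenotypeCounts(4, 23, 23),
        method="Primex PCR",
    )
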