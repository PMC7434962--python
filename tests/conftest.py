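from datetime import date

import pytest

from gestbegin.claims_model import AlgorithmConstants, BirthClass, CalendarQuarter, EddCoding, PregnancyRecord
from gestbegin.synthetic_cohort import GeneratorParams, adversarial_cohort, simulate_cohort


@pytest.fixture(scope="session")
def constants() -> AlgorithmConstants:
    return AlgorithmConstants()


@pytest.fixture(scope="session")
def adversarial_records():
    return adversarial_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort under default study conditions."""
    return simulate_cohort(GeneratorParams(n_pregnancies=800, seed=101))


@pytest.fixture(scope="session")
def large_cohort():
    """Simulated cohort at n = 10,000 for calibration checks."""
    return simulate_cohort(GeneratorParams(n_pregnancies=10_000, seed=202))


def make_concordant_record(
    pid: str,
    birth: date,
    birth_class: BirthClass,
    edd: date,
    n_codings: int = 2,
) -> PregnancyRecord:
    """A record whose codings are all the given EDD, stamped two quarters before birth."""
    coded_in = CalendarQuarter.from_index(CalendarQuarter.of(birth).index - 2)
    return PregnancyRecord(
        pid, 30, birth, birth_class, [EddCoding(edd, coded_in)] * n_codings
    )
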