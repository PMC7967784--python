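import pytest

from sinkcod import default_config, generate_cohort
from sinkcod.records import CauseCode, DeathRecord, Gender


def make_record(
    record_id="r1",
    age=70,
    gender=Gender.MALE,
    region="R0",
    chain=("I25.1",),
    history=(),
    underlying=None,
):
    return DeathRecord(
        record_id=record_id,
        age=age,
        gender=gender,
        region=region,
        chain=tuple(CauseCode(c) for c in chain),
        history=tuple(CauseCode(c) for c in history),
        underlying=CauseCode(underlying) if underlying else None,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2,000 labeled synthetic records, fixed seed, shared across tests."""
    return generate_cohort(default_config(n_records=2_000, n_causes=25, n_regions=3, seed=42))
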