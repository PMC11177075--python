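import pytest

from abcscore import (
    Cause,
    Cpc,
    FirstRhythm,
    Region,
    UtsteinRecord,
    all_published_tables,
)


def make_record(record_id="r1", **overrides) -> UtsteinRecord:
    """An eligible baseline record; override fields to break eligibility."""
    base = dict(
        record_id=record_id,
        age=65,
        cause=Cause.INTERNAL,
        witnessed=True,
        no_flow_time=3.0,
        first_rhythm=FirstRhythm.VF,
        pad_performed=False,
        prehospital_rosc=False,
        resuscitation_attempted=True,
        region=Region.OTHER,
        year=2008,
        cpc=Cpc.CPC5,
    )
    base.update(overrides)
    return UtsteinRecord(**base)


@pytest.fixture(scope="session")
def published_tables():
    """Per-score contingency tables of the three guideline groups,
    reconstructed from the published cumulative threshold counts."""
    return all_published_tables()
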