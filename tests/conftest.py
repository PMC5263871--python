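import pytest

from recoverydebt.records import OutcomeMeasure
from recoverydebt.simulate import SyntheticConfig, generate_dataset


def make_record(x_start, x_end, x_ref, t_years=10.0, metric="abundance", **kw):
    kw.setdefault("study_id", "S1")
    kw.setdefault("outcome_id", "O1")
    return OutcomeMeasure(
        metric=metric, x_start=x_start, x_end=x_end, x_ref=x_ref, t_years=t_years, **kw
    )


@pytest.fixture(scope="session")
def full_dataset():
    """Default-condition database: 348 studies, ~3,800 outcome measures."""
    return generate_dataset(SyntheticConfig(seed=20260928))


@pytest.fixture(scope="session")
def mid_dataset():
    """A 150-study database used for end-to-end recovery checks."""
    return generate_dataset(SyntheticConfig(n_studies=150, seed=42))
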