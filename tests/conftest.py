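import numpy as np
import pandas as pd
import pytest

from sdqnorm.instrument import SDQ_INSTRUMENT
from sdqnorm.scoring import ITEM_COLUMNS
from sdqnorm.tables import NormTable


@pytest.fixture(scope="session")
def age15_norm_table() -> NormTable:
    """The packaged transcription of the published age-15 parent-report
    percentile rows (percent-below convention)."""
    from importlib import resources

    path = resources.files("sdqnorm.data") / "dutch_parent_percentiles_age15.csv"
    return NormTable.from_csv(str(path))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A deterministic 12-subject item-level cohort with known raw values."""
    rng = np.random.default_rng(42)
    n = 12
    df = pd.DataFrame(
        rng.integers(0, 3, size=(n, 25)).astype(float), columns=list(ITEM_COLUMNS)
    )
    df.insert(0, "subject_id", [f"x{i}" for i in range(n)])
    df.insert(1, "version", "self")
    df["age"] = rng.choice(range(12, 18), n).astype(float)
    df["gender"] = np.where(rng.uniform(size=n) < 0.5, "female", "male")
    df["ethnic_background"] = "majority"
    df["maternal_education"] = "medium"
    return df


def make_items(values: dict[int, float], n: int = 1) -> pd.DataFrame:
    """Item-level frame from a {1-based item -> value} map (others 0)."""
    row = {c: 0.0 for c in ITEM_COLUMNS}
    for item, v in values.items():
        row[f"item{item:02d}"] = v
    df = pd.DataFrame([row] * n)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    return df


@pytest.fixture(scope="session")
def instrument():
    return SDQ_INSTRUMENT
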