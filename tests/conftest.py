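import numpy as np
import pandas as pd
import pytest

from linetrend.data_model import RepeatedMeasuresDataset


def make_dataset(rows):
    """Build a dataset from (subject, group, time, response) tuples."""
    return RepeatedMeasuresDataset(
        pd.DataFrame(rows, columns=["subject", "group", "time", "response"])
    )


@pytest.fixture
def growth_study():
    """27 subjects in two groups (11 + 16) measured at ages 8, 10, 12, 14,
    with group-specific linear growth plus a subject shift and noise."""
    rng = np.random.default_rng(42)
    rows = []
    ages = [8.0, 10.0, 12.0, 14.0]
    for i in range(27):
        group = "girl" if i < 11 else "boy"
        slope = 0.5 if group == "girl" else 0.8
        intercept = 17.0 + rng.normal(0, 1.5)
        for t in ages:
            rows.append(
                (f"c{i:02d}", group, t, intercept + slope * t + rng.normal(0, 0.6))
            )
    return make_dataset(rows)


@pytest.fixture
def two_by_three():
    """Two subjects, one group, three shared times."""
    return make_dataset(
        [
            ("a", "g", 1.0, 1.0), ("a", "g", 2.0, 2.0), ("a", "g", 3.0, 3.0),
            ("b", "g", 1.0, 2.0), ("b", "g", 2.0, 4.0), ("b", "g", 3.0, 6.0),
        ]
    )
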