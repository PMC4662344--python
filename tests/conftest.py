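import numpy as np
import pandas as pd
import pytest

from phenoplast.lmm import ModelSpec, RandomTerm, fit_lmm


@pytest.fixture
def rng():
    return np.random.default_rng(20230401)


@pytest.fixture
def crossed_slope_data():
    """Small dataset with two crossed factors and a random slope; the same
    draws back the frozen lme4 cross-check numbers."""
    r = np.random.default_rng(42)
    n = 200
    df = pd.DataFrame(
        {
            "f1": r.integers(0, 8, n),
            "f2": r.integers(0, 12, n),
            "x": r.normal(size=n),
        }
    )
    df["y"] = (
        1
        + 0.5 * df.x
        + r.normal(0, 1, 8)[df.f1]
        + r.normal(0, 0.7, 12)[df.f2]
        + r.normal(0, 0.5, 12)[df.f2] * df.x
        + r.normal(0, 1, n)
    )
    return df


@pytest.fixture
def crossed_slope_spec():
    return ModelSpec("y", ["x"], [RandomTerm("f1"), RandomTerm("f2", "x")])


@pytest.fixture
def balanced_oneway():
    """Balanced one-way layout (q=8 groups, m=5 replicates) with its
    closed-form ANOVA variance-component estimators."""
    r = np.random.default_rng(7)
    q, m = 8, 5
    g = np.repeat(np.arange(q), m)
    y = 10 + np.repeat(r.normal(0, 2, q), m) + r.normal(0, 1, q * m)
    df = pd.DataFrame({"y": y, "g": g})
    gm = df.groupby("g")["y"].mean()
    msb = m * ((gm - gm.mean()) ** 2).sum() / (q - 1)
    msw = ((y - gm[g].to_numpy()) ** 2).sum() / (q * m - q)
    return df, q, m, (msb - msw) / m, msw


@pytest.fixture
def tiny_records():
    """Eight breeding records including one second clutch and one same-year
    duplicate female; seven survive the first-clutch filter, six of which are
    clutch_order 1 rows of distinct (female, year)."""
    return pd.DataFrame(
        {
            "farm_id": ["F0", "F0", "F0", "F1", "F1", "F1", "F2", "F2"],
            "nestbox_id": ["F0-0", "F0-1", "F0-0", "F1-0", "F1-1", "F1-0", "F2-0", "F2-1"],
            "year": [2005, 2005, 2005, 2005, 2005, 2006, 2006, 2006],
            "female_id": ["A", "B", "A", "C", None, "C", "D", "E"],
            "age_class": ["SY", "ASY", "SY", "ASY", "unknown", "ASY", "SY", "ASY"],
            "lay_date": [140, 145, 175, 138, 150, 139, 142, 148],
            "clutch_order": [1, 1, 2, 1, 1, 1, 1, 1],
        }
    )
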