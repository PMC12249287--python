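import numpy as np
import pandas as pd
import pytest


def make_occurrences(rows):
    """Build an occurrence frame from (record_id, date, x, y, scalp) tuples."""
    df = pd.DataFrame(rows, columns=["record_id", "date", "x", "y", "scalp"])
    df["date"] = pd.to_datetime(df["date"])
    df["source"] = "observation"
    df["area_id"] = "A"
    df["is_reproduction"] = False
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def taxonomy():
    return {
        "sheep": "livestock",
        "goat": "livestock",
        "dog": "pet",
        "red fox": "wild prey",
        "bird": "other",
        "olive": "fruit",
    }


@pytest.fixture
def scats(taxonomy):
    """Nine scats with a known composition over the fixture taxonomy."""
    rows = []
    contents = {
        "s1": ["sheep"],
        "s2": ["sheep", "goat"],
        "s3": ["dog"],
        "s4": ["red fox", "bird"],
        "s5": ["sheep", "dog"],
        "s6": ["bird"],
        "s7": ["olive", "sheep"],
        "s8": ["goat"],
        "s9": ["red fox"],
    }
    for i, (sid, items) in enumerate(contents.items()):
        for it in items:
            rows.append({"scat_id": sid, "date": pd.Timestamp("2024-07-01") + pd.Timedelta(days=i), "item": it})
    return pd.DataFrame(rows)
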