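import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from addgwas.sumstats import CANONICAL_COLUMNS, StudySumstats


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Canonical summary-statistics frame from sparse row dicts."""
    defaults = {
        "CHR": "1", "POS": 1000, "REF": "A", "ALT": "G", "EA": "G",
        "BETA": 0.0, "SE": 0.1, "P": 1.0, "EAF": 0.3, "INFO": 0.99,
        "N_CASES": 5000, "N_CONTROLS": 10000,
    }
    df = pd.DataFrame([{**defaults, **r} for r in rows])
    return df[CANONICAL_COLUMNS]


@pytest.fixture
def small_study() -> StudySumstats:
    records = make_records([
        {"POS": 1000, "BETA": 0.10, "SE": 0.02, "P": 5.7e-7},
        {"POS": 2000, "BETA": -0.05, "SE": 0.02, "P": 0.012},
        {"POS": 3000, "BETA": 0.01, "SE": 0.02, "P": 0.62},
    ])
    return StudySumstats("STUDY1", "case_control", records, total_cases=5000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)
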