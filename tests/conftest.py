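import numpy as np
import pandas as pd
import pytest

from timeuse_coda import pipeline, simulate

TABLE2_GEOMETRIC = np.array([682.0, 278.0, 8.0, 471.0])
TABLE2_ARITHMETIC = np.array([659.0, 291.0, 21.0, 453.0])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (60 participants) with its ground truth."""
    cfg = simulate.GeneratorConfig(n_participants=60, seed=42)
    tables, truth = simulate.generate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Preprocessed analysis table for the reduced cohort."""
    _, tables, _ = small_cohort
    return pipeline.preprocess_tables(tables)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (211 participants, 7 days) at the default settings."""
    cfg = simulate.GeneratorConfig(seed=7)
    tables, truth = simulate.generate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_compositions(rng, n, total=1440.0):
    """Strictly positive random compositions closed to `total`."""
    logs = rng.normal(size=(n, 4)) * np.array([0.3, 0.3, 1.0, 0.3]) + np.log(
        [600, 300, 20, 450]
    )
    x = np.exp(logs)
    return x * (total / x.sum(axis=1, keepdims=True))


@pytest.fixture()
def toy_days():
    """5 participants with valid-day counts (1, 2, 3, 0, 7) after the
    non-wear filter, including values straddling the 120-min boundary."""
    rows = []
    counts = {"A": 1, "B": 2, "C": 3, "D": 0, "E": 7}
    rng = np.random.default_rng(5)
    for pid, n_valid in counts.items():
        for d in range(7):
            valid = d < n_valid
            nonwear = float(rng.uniform(0, 120)) if valid else float(rng.uniform(121, 400))
            if pid == "B" and d == 0:
                nonwear = 120.0  # boundary: retained
            if pid == "D" and d == 0:
                nonwear = 121.0  # boundary: excluded
            comp = random_compositions(rng, 1)[0]
            rows.append(
                {
                    "participant_id": pid,
                    "date": pd.Timestamp("2023-06-05") + pd.Timedelta(days=d),
                    "sb": comp[0],
                    "lpa": comp[1],
                    "mvpa": comp[2],
                    "sleep": comp[3],
                    "nonwear": nonwear,
                }
            )
    return pd.DataFrame(rows)
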