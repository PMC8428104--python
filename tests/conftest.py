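import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from heterosiskit import TriadSimConfig, simulate_triad_counts


@pytest.fixture(scope="session")
def small_triad():
    """A small simulated triad shared by read-only tests."""
    cfg = TriadSimConfig(n_genes=300, seed=42)
    counts, samples, truth = simulate_triad_counts(cfg)
    return cfg, counts, samples, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_counts():
    """Hand-sized count matrix with a matching sample sheet."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(50)]
    cols = [
        f"{pop}_{cond}_{r}"
        for pop in ("P1", "P2", "F1")
        for cond in ("control", "heat")
        for r in (1, 2, 3)
    ]
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, len(cols))), index=genes, columns=cols
    )
    samples = pd.DataFrame(
        [(c, *c.rsplit("_", 2)) for c in cols],
        columns=["sample", "population", "condition", "replicate"],
    )
    samples["replicate"] = samples["replicate"].astype(int)
    return counts, samples
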