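import warnings

import numpy as np
import pandas as pd
import pytest

import wheatgs as w

# constant-marker warnings from small random panels are expected noise here
warnings.filterwarnings("ignore", message="dropped .* constant markers")


@pytest.fixture(scope="session")
def small_panel():
    """166-line panel at reduced marker count, with missingness."""
    cfg = w.SimulationConfig(seed=101, n_markers=1200)
    return w.simulate_panel(cfg) + (w.SimulationConfig(seed=101, n_markers=1200),)


@pytest.fixture(scope="session")
def clean_panel():
    """Fully observed panel with a single known-architecture trait."""
    cfg = w.SimulationConfig(
        seed=202, n_lines=120, n_markers=400, missing_rate_max=0.0,
        monomorphic_fraction=0.0, n_qtl=20,
        variance_targets={"T": (1.0, 0.5, 0.5, 0.5)},
    )
    g, p, t = w.simulate_panel(cfg)
    return g, p, t, cfg


@pytest.fixture(scope="session")
def clean_blues(clean_panel):
    g, p, _, _ = clean_panel
    return w.compute_blue(p, "T")


def toy_matrix(calls, chrom=None, pos=None):
    """GenotypeMatrix from a literal 2-D list (None -> missing)."""
    arr = np.array(
        [[np.nan if c is None else float(c) for c in row] for row in calls]
    )
    n, m = arr.shape
    marker_ids = [f"m{j}" for j in range(m)]
    mp = pd.DataFrame(
        {
            "marker": marker_ids,
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos_mb": pos if pos is not None else np.arange(m, dtype=float),
            "position_known": [True] * m,
        }
    )
    return w.GenotypeMatrix(
        [f"l{i}" for i in range(n)], marker_ids, arr, mp
    )
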