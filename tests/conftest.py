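import sys
from pathlib import Path

import numpy as np
import pytest

from devconn.core import Connectome

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


def random_connectome(seed, n=12, density=0.5, weighted=True, w_lo=0.1, w_hi=0.9):
    """Small random symmetric connectome for oracle comparisons."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(iu.size) < density
    m = np.zeros((n, n))
    w = rng.uniform(w_lo, w_hi, int(present.sum())) if weighted else 1.0
    m[iu[present], ju[present]] = w
    m = m + m.T
    variant = "fa_weighted" if weighted else "binary"
    return Connectome([f"R{i}" for i in range(n)], m, variant)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 1-year cohort with scores, small graphs for speed."""
    from devconn.synth import default_design, simulate_cohort

    design = default_design(ages=(1,), n_control=12, n_iugr=12, n_nodes=30,
                            seed=77)
    # 30-node graphs cannot hold a degree-60 target: rescale cell targets.
    for cell in design.cells:
        cell.degree_mean *= 30 / 93
        cell.degree_sd *= 30 / 93
    return simulate_cohort(design)
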