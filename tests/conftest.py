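import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from samgep.io_data import LabelSeries
from samgep.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small 'correct'-mode cohort shared by the slower integration tests."""
    cfg = SimConfig(
        N_unlabeled=150, n_labeled=50, p=40, m=8, mean_T=12,
        n_informative=8, seed=42,
    )
    panel, labels, V, truth = simulate_cohort(cfg)
    labeled = LabelSeries(y={pid: labels.y[pid] for pid in truth["labeled_ids"]})
    return {
        "config": cfg, "panel": panel, "labels_all": labels,
        "labels": labeled, "V": V, "truth": truth,
        "anchor": truth["informative_ids"][0],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
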