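import numpy as np
import pytest

from targetfish.curation import ACTIVE, INACTIVE, InteractionRecord
from targetfish.synth import PanelSpec, generate_panel


@pytest.fixture(scope="session")
def tiny_panel():
    """Small two-target panel: fast, passes the 10+10 gate after curation."""
    spec = PanelSpec(
        n_targets=2,
        actives_per_target=14,
        inactives_per_target=20,
        seed=11,
    )
    return generate_panel(spec)


@pytest.fixture
def raw_records():
    """A handful of hand-written assay rows covering all curation rules."""
    return [
        InteractionRecord("c1", "CCO", "t1", "IC50", 5000.0, "nM", "a1"),
        InteractionRecord("c1", "CCO", "t1", "IC50", 6.0, "uM", "a2"),
        InteractionRecord("c1", "CCO", "t1", "Ki", 1.0, "uM", "a3"),
        InteractionRecord("c2", "CCN", "t1", "IC50", 0.05, "mM", "a4"),
        InteractionRecord("c3", "CCC", "t2", "IC50", 2.0, "uM", "a5"),
    ]


@pytest.fixture
def blob_data():
    """Two well-separated Gaussian blobs: 20 actives, 20 inactives, d=5."""
    rng = np.random.default_rng(42)
    sep = 8.0  # inter-centroid distance in units of the within-blob SD (1.0)
    X_act = rng.normal(0.0, 1.0, size=(20, 5))
    X_inact = rng.normal(sep / np.sqrt(5), 1.0, size=(20, 5))
    X = np.vstack([X_act, X_inact])
    y = np.array([ACTIVE] * 20 + [INACTIVE] * 20)
    return X, y
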