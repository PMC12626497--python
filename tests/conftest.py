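import numpy as np
import pandas as pd
import pytest

from iscn import SyntheticConfig, simulate_study, synthetic_atlas
from iscn.data_model import Atlas


@pytest.fixture(scope="session")
def toy_atlas() -> Atlas:
    """Six regions, three homotopic pairs; pair 0 (ids 1, 2) is resected."""
    rows = [
        (1, "L_hip", "L", 2, "temporal", "limbic", 1),
        (2, "R_hip", "R", 1, "temporal", "limbic", 0),
        (3, "L_ins", "L", 4, "insular", "ventral-attention", 0),
        (4, "R_ins", "R", 3, "insular", "ventral-attention", 0),
        (5, "L_occ", "L", 6, "occipital", "visual", 0),
        (6, "R_occ", "R", 5, "occipital", "visual", 0),
    ]
    t = pd.DataFrame(
        rows,
        columns=[
            "region_id",
            "name",
            "hemisphere",
            "homotopic_partner",
            "module",
            "yeo",
            "resected",
        ],
    )
    t["resected"] = t["resected"].astype(bool)
    return Atlas(t).validate()


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic cohort with injected deviations (fixed seed)."""
    cfg = SyntheticConfig(
        n_regions=20,
        n_controls=40,
        n_sf=12,
        n_nsf=10,
        edges_per_sf=3,
        edges_per_nsf=8,
        delta=4.0,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_atlas_12():
    return synthetic_atlas(12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
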