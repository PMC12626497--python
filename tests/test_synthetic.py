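import numpy as np
import pytest

from iscn import (
    SyntheticConfig,
    build_rscn,
    make_reference_covariance,
    patient_deviation,
    simulate_controls,
    simulate_patient,
    simulate_study,
    synthetic_atlas,
    write_study,
    read_cohort,
    read_atlas,
)
from iscn.data_model import ValidationError, covariate_frame
from iscn.normative import residualize
from iscn.synthetic import build_study_model


def test_reference_covariance_is_spd_and_deterministic():
    cfg = SyntheticConfig(n_regions=16, n_controls=30, seed=9)
    s1 = make_reference_covariance(cfg)
    s2 = make_reference_covariance(cfg)
    assert np.array_equal(s1, s2)
    assert np.allclose(s1, s1.T)
    assert np.linalg.eigvalsh(s1).min() > 0


def test_reference_covariance_homotopic_structure():
    cfg = SyntheticConfig(n_regions=40, n_controls=30, homotopic_rho=0.9, seed=2)
    s = make_reference_covariance(cfg)
    d = np.sqrt(np.diag(s))
    c = s / np.outer(d, d)
    homotopic = [c[2 * k, 2 * k + 1] for k in range(20)]
    off = c[np.triu_indices_from(c, 1)]
    assert np.mean(homotopic) > np.mean(np.abs(off))


def test_large_unique_variance_kills_correlations():
    cfg = SyntheticConfig(n_regions=12, n_controls=30, psi=500.0, seed=4)
    s = make_reference_covariance(cfg)
    d = np.sqrt(np.diag(s))
    c = s / np.outer(d, d)
    assert np.max(np.abs(c[np.triu_indices_from(c, 1)])) < 0.05


def test_controls_reproduce_reference_correlation():
    """Empirical residual correlations track the generating covariance."""
    cfg = SyntheticConfig(
        n_regions=8, n_controls=500, n_latent=2, homotopic_rho=0.95, seed=6
    )
    atlas = synthetic_atlas(8)
    vm, metas = simulate_controls(cfg, atlas)
    sigma = make_reference_covariance(cfg)
    d = np.sqrt(np.diag(sigma))
    true_corr = sigma / np.outer(d, d)
    resid = residualize(vm.values, covariate_frame(metas))
    emp = np.corrcoef(resid, rowvar=False)
    tol = 3 / np.sqrt(cfg.n_controls) + 0.02
    assert np.max(np.abs(emp - true_corr)) < tol


def test_controls_deterministic():
    cfg = SyntheticConfig(n_regions=10, n_controls=20, seed=3)
    atlas = synthetic_atlas(10)
    v1, m1 = simulate_controls(cfg, atlas)
    v2, m2 = simulate_controls(cfg, atlas)
    assert np.array_equal(v1.values, v2.values)
    assert [a.subject_id for a in m1] == [b.subject_id for b in m2]


def test_patient_same_seed_identical():
    cfg = SyntheticConfig(n_regions=12, n_controls=20, edges_per_nsf=2, seed=5)
    atlas = synthetic_atlas(12)
    model = build_study_model(cfg)
    r1, m1, e1 = simulate_patient(
        cfg, "NSF", "L", atlas, model, np.random.default_rng(42)
    )
    r2, m2, e2 = simulate_patient(
        cfg, "NSF", "L", atlas, model, np.random.default_rng(42)
    )
    assert np.array_equal(r1, r2)
    assert e1 == e2 and m1 == m2


def test_injected_edge_detected_downstream():
    """delta=6 on a single edge with 78 controls drives that edge's |Z| over 2."""
    cfg = SyntheticConfig(
        n_regions=12,
        n_controls=78,
        delta=6.0,
        edges_per_nsf=1,
        contra_fraction_nsf=1.0,
        seed=8,
    )
    atlas = synthetic_atlas(12)
    model = build_study_model(cfg)
    rng = np.random.default_rng(1)
    vm, metas = simulate_controls(cfg, atlas, model, rng)
    row, meta, injected = simulate_patient(cfg, "NSF", "L", atlas, model, rng, "p0")
    assert len(injected) == 1
    covs = covariate_frame(metas)
    rscn = build_rscn(vm, covs)
    dev = patient_deviation(
        vm, covs, rscn, "p0", row, {"age": meta.age, "sex": meta.sex_code, "tiv": meta.tiv}
    )
    (a, b), = injected
    ia, ib = atlas.index_of([a, b])
    assert abs(dev.z[ia, ib]) > 2.0


def test_edge_budget_exceeding_pool_is_config_error():
    cfg = SyntheticConfig(
        n_regions=6, n_controls=20, edges_per_nsf=500, contra_fraction_nsf=1.0, seed=0
    )
    atlas = synthetic_atlas(6)
    model = build_study_model(cfg)
    with pytest.raises(ValidationError, match="pools"):
        simulate_patient(cfg, "NSF", "L", atlas, model, np.random.default_rng(0))


def test_study_determinism_and_files(tmp_path):
    cfg = SyntheticConfig(
        n_regions=10, n_controls=15, n_sf=4, n_nsf=3,
        edges_per_sf=1, edges_per_nsf=2, seed=12,
    )
    s1 = simulate_study(cfg)
    s2 = simulate_study(cfg)
    assert np.array_equal(s1.volumes.values, s2.volumes.values)
    assert s1.ground_truth == s2.ground_truth
    paths = write_study(s1, tmp_path)
    atlas = read_atlas(paths["atlas"])
    volumes, metas = read_cohort(paths["volumes"], paths["metadata"], atlas)
    assert len(metas) == 15 + 4 + 3
    assert sum(m.group == "patient" for m in metas) == 7
    # injected ground-truth pairs reference valid regions, i < j
    ids = set(int(r) for r in atlas.region_ids)
    for edges in s1.ground_truth.values():
        for i, j in edges:
            assert i < j and i in ids and j in ids


def test_odd_region_count_rejected():
    with pytest.raises(ValidationError, match="even"):
        SyntheticConfig(n_regions=9).validate()


def test_small_control_cohort_warns():
    with pytest.warns(UserWarning, match="noisy"):
        SyntheticConfig(n_regions=40, n_controls=10).validate()
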