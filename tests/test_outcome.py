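import numpy as np
import pytest

from iscn import (
    ModelConfig,
    aggregate_weights_yeo,
    apply_frozen,
    confusion_metrics,
    cross_validate,
    f_score,
    freeze,
    permutation_test,
    select_top_k,
)
from iscn.data_model import ValidationError


def test_f_score_hand_computation():
    """Six-patient toy: class means 8 vs 2, overall 5, within-class var 1+1."""
    X = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    assert f_score(X, y)[0] == pytest.approx(((8 - 5) ** 2 + (2 - 5) ** 2) / 2.0)


def test_f_score_degenerate_features():
    y = np.array([0, 0, 1, 1])
    X = np.column_stack(
        [
            np.ones(4),  # constant everywhere -> 0
            np.array([0.0, 0.0, 1.0, 1.0]),  # perfectly separated -> +inf
        ]
    )
    s = f_score(X, y)
    assert s[0] == 0.0
    assert np.isinf(s[1])
    with pytest.raises(ValidationError):
        f_score(X, np.ones(4))


def test_select_top_k_ties_and_bounds(rng):
    scores = np.zeros(6)
    assert select_top_k(scores, 3).tolist() == [0, 1, 2]
    s = rng.normal(size=10)
    assert select_top_k(s, 20).tolist() == np.argsort(-s, kind="stable").tolist()
    s = rng.normal(size=10)
    assert select_top_k(s, 4).tolist() == np.argsort(-s, kind="stable")[:4].tolist()


def test_confusion_metrics_identities():
    sens, spec, acc = confusion_metrics(tp=21, fp=6, tn=37, fn=7)
    assert sens == pytest.approx(21 / 28)
    assert spec == pytest.approx(37 / 43)
    assert acc == pytest.approx(58 / 71)
    with pytest.raises(ValidationError):
        confusion_metrics(0, 0, 0, 0)


def test_cross_validate_separable_cohort(rng):
    n, p = 60, 25
    y = np.array(["SF"] * 30 + ["NSF"] * 30)
    X = rng.normal(0, 1, (n, p))
    X[:, 7] = (y == "NSF") * 10.0 + rng.normal(0, 0.1, n)
    cfg = ModelConfig(k_grid=(20,), n_folds=5, seed=0)
    rep = cross_validate(X, y, cfg)
    assert rep.accuracy == 1.0
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.auc == 1.0
    assert sum(c["tp"] + c["fp"] + c["tn"] + c["fn"] for c in rep.per_fold) == n
    assert all(7 in sel for sel in rep.selected_features)


def test_cross_validate_null_cohort_near_chance(rng):
    n, p = 40, 10
    X = rng.normal(0, 1, (n, p))
    y = np.array(["SF", "NSF"] * (n // 2))
    rep = cross_validate(X, y, ModelConfig(k_grid=(5,), n_folds=5, seed=3))
    p0 = 0.5
    assert rep.accuracy <= p0 + 1.96 * np.sqrt(p0 * (1 - p0) / n)


def test_cross_validate_reports_pooled_confusion(rng):
    n, p = 24, 8
    X = rng.normal(0, 1, (n, p))
    y = np.array(["SF"] * 14 + ["NSF"] * 10)
    rep = cross_validate(X, y, ModelConfig(k_grid=(4,), n_folds=4, seed=1))
    tp = sum(c["tp"] for c in rep.per_fold)
    tn = sum(c["tn"] for c in rep.per_fold)
    fp = sum(c["fp"] for c in rep.per_fold)
    fn = sum(c["fn"] for c in rep.per_fold)
    sens, spec, acc = confusion_metrics(tp, fp, tn, fn)
    assert rep.accuracy == pytest.approx(acc)
    assert rep.sensitivity == pytest.approx(sens)
    assert rep.specificity == pytest.approx(spec)


def test_permutation_p_extremes(rng):
    n, p = 20, 5
    X = rng.normal(0, 1, (n, p))
    y = np.array(["SF", "NSF"] * 10)
    cfg = ModelConfig(k_grid=(3,), n_folds=4, n_permutations=5, seed=0)
    p_hi, _ = permutation_test(X, y, cfg, observed_accuracy=2.0)  # above everything
    assert p_hi == pytest.approx(1 / 6)
    p_lo, _ = permutation_test(X, y, cfg, observed_accuracy=-1.0)  # below everything
    assert p_lo == pytest.approx(1.0)


def test_aggregate_weights_yeo(toy_atlas):
    weights = {1: 1.0, 2: 3.0, 3: 2.0, 5: 10.0}
    means, excluded = aggregate_weights_yeo(weights, toy_atlas)
    assert means["limbic"] == pytest.approx(2.0)
    assert means["ventral-attention"] == pytest.approx(2.0)
    assert means["visual"] == pytest.approx(10.0)
    assert means.index[0] == "visual"  # ranked by mean weight
    assert excluded == []


def test_aggregate_weights_excludes_unmapped():
    from iscn import synthetic_atlas

    atlas = synthetic_atlas(28)  # includes subcortical pairs mapped to yeo 'none'
    sub = [int(r) for r, y in zip(atlas.region_ids, atlas.yeo) if y == "none"]
    means, excluded = aggregate_weights_yeo({sub[0]: 5.0, 1: 1.0}, atlas)
    assert excluded == [sub[0]]
    assert sub[0] not in means.index


def test_freeze_apply_roundtrip(rng):
    n, p = 30, 12
    y = np.array(["SF"] * 16 + ["NSF"] * 14)
    X = rng.normal(0, 1, (n, p))
    X[:, 2] += (y == "NSF") * 3.0
    cfg = ModelConfig(k_grid=(4,), n_folds=5, seed=0)
    rep = cross_validate(X, y, cfg)
    frozen = freeze(X, y, cfg, k=rep.k_chosen)
    resub = apply_frozen(frozen, X, y, list(range(p)))
    assert resub["accuracy"] >= rep.accuracy  # resubstitution optimism
    # relabeling symmetry: negate the decision rule and flip the labels
    flipped = np.where(y == "SF", "NSF", "SF")
    frozen.weights = -frozen.weights
    frozen.intercept = -frozen.intercept
    swapped = apply_frozen(frozen, X, flipped, list(range(p)))
    assert swapped["sensitivity"] == pytest.approx(resub["specificity"])
    assert swapped["specificity"] == pytest.approx(resub["sensitivity"])


def test_apply_frozen_missing_region(rng):
    n, p = 20, 6
    y = np.array(["SF", "NSF"] * 10)
    X = rng.normal(0, 1, (n, p))
    frozen = freeze(X, y, ModelConfig(k_grid=(3,), n_folds=4, seed=0), k=3)
    with pytest.raises(ValidationError, match="missing"):
        apply_frozen(frozen, X[:, :2], y, [100, 101])
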