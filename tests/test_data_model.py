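import numpy as np
import pandas as pd
import pytest

from iscn import (
    SubjectMeta,
    VolumeMatrix,
    read_atlas,
    read_cohort,
    read_metadata,
    read_volumes,
    synthetic_atlas,
    write_atlas,
    write_metadata,
    write_volumes,
)
from iscn.data_model import FormatError, ValidationError, covariate_frame


def _atlas_file(tmp_path, rows=None, name="atlas.tsv"):
    header = "region_id\tname\themisphere\thomotopic_partner\tmodule\tyeo\tresected\n"
    if rows is None:
        rows = [
            "1\tL_a\tL\t2\ttemporal\tlimbic\t1",
            "2\tR_a\tR\t1\ttemporal\tlimbic\t0",
            "3\tL_b\tL\t4\tfrontal\tdefault\t0",
            "4\tR_b\tR\t3\tfrontal\tdefault\t0",
            "5\tL_c\tL\t6\toccipital\tvisual\t0",
            "6\tR_c\tR\t5\toccipital\tvisual\t0",
        ]
    path = tmp_path / name
    path.write_text(header + "\n".join(rows) + "\n")
    return path


def test_read_atlas_toy(tmp_path):
    atlas = read_atlas(_atlas_file(tmp_path))
    assert atlas.n_regions == 6
    assert (atlas.hemispheres == "L").sum() == 3
    assert (atlas.hemispheres == "R").sum() == 3
    assert atlas.resected_ids == frozenset({1})


def test_read_atlas_broken_involution(tmp_path):
    rows = [
        "1\tL_a\tL\t2\ttemporal\tlimbic\t0",
        "2\tR_a\tR\t3\ttemporal\tlimbic\t0",  # partner(2)=3 but partner(1)=2
        "3\tL_b\tL\t2\tfrontal\tdefault\t0",
    ]
    with pytest.raises(ValidationError, match="involution"):
        read_atlas(_atlas_file(tmp_path, rows))


def test_read_atlas_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("region_id\tname\n1\tx\n")
    with pytest.raises(FormatError, match="missing columns"):
        read_atlas(path)


def test_study_scale_atlas_round_trip(tmp_path):
    atlas = synthetic_atlas(246)
    assert atlas.n_regions == 246
    assert set(atlas.modules) == {
        "frontal", "temporal", "parietal", "insular", "limbic",
        "occipital", "subcortical",
    }
    assert len(atlas.resected_ids) == 21
    hemi = dict(zip(atlas.region_ids, atlas.hemispheres))
    assert all(hemi[r] == "L" for r in atlas.resected_ids)
    # canonical-dialect round trip is byte-stable
    p1, p2 = tmp_path / "a1.tsv", tmp_path / "a2.tsv"
    write_atlas(atlas, p1)
    write_atlas(read_atlas(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_duplicate_region_ids_rejected(tmp_path):
    rows = [
        "1\tL_a\tL\t2\ttemporal\tlimbic\t0",
        "2\tR_a\tR\t1\ttemporal\tlimbic\t0",
        "1\tL_b\tL\t2\tfrontal\tdefault\t0",
    ]
    with pytest.raises(ValidationError, match="duplicate"):
        read_atlas(_atlas_file(tmp_path, rows))


def _cohort_files(tmp_path, atlas, n_ctrl=10, n_pat=4):
    rng = np.random.default_rng(1)
    metas, rows = [], []
    for i in range(n_ctrl + n_pat):
        patient = i >= n_ctrl
        metas.append(
            SubjectMeta(
                subject_id=f"s{i:02d}",
                group="patient" if patient else "control",
                age=30 + i,
                sex="F" if i % 2 else "M",
                tiv=1400 + 5 * i,
                focus_laterality="R" if patient else "none",
                outcome="SF" if patient else "none",
                site="toy",
            )
        )
        rows.append(rng.uniform(5, 10, atlas.n_regions))
    vm = VolumeMatrix(
        subjects=[m.subject_id for m in metas],
        region_ids=atlas.region_ids,
        values=np.array(rows),
    )
    vp, mp = tmp_path / "vol.tsv", tmp_path / "meta.tsv"
    write_volumes(vm, vp)
    write_metadata(metas, mp)
    return vp, mp


def test_read_cohort_aligned(tmp_path, toy_atlas):
    vp, mp = _cohort_files(tmp_path, toy_atlas)
    volumes, metas = read_cohort(vp, mp, toy_atlas)
    assert len(metas) == 14
    assert volumes.values.shape == (14, 6)
    assert [m.subject_id for m in metas] == volumes.subjects
    # patient with outcome=SF, focus=R is accepted
    assert metas[-1].outcome == "SF" and metas[-1].focus_laterality == "R"


def test_read_cohort_id_mismatch(tmp_path, toy_atlas):
    vp, mp = _cohort_files(tmp_path, toy_atlas)
    meta = pd.read_csv(mp, sep="\t")
    meta.loc[0, "subject_id"] = "ghost"
    meta.to_csv(mp, sep="\t", index=False)
    with pytest.raises(ValidationError, match="mismatch"):
        read_cohort(vp, mp, toy_atlas)


def test_control_with_outcome_rejected(tmp_path, toy_atlas):
    vp, mp = _cohort_files(tmp_path, toy_atlas)
    meta = pd.read_csv(mp, sep="\t")
    meta.loc[0, "outcome"] = "SF"
    meta.to_csv(mp, sep="\t", index=False)
    with pytest.raises(ValidationError, match="control"):
        read_metadata(mp)


def test_volume_positivity_enforced(tmp_path, toy_atlas):
    vp, mp = _cohort_files(tmp_path, toy_atlas)
    t = pd.read_csv(vp, sep="\t")
    t.iloc[0, 1] = -1.0
    t.to_csv(vp, sep="\t", index=False)
    with pytest.raises(ValidationError, match="positive"):
        read_volumes(vp, toy_atlas)


def test_sex_coding_in_covariate_frame():
    metas = [
        SubjectMeta("a", "control", 30, "F", 1400),
        SubjectMeta("b", "control", 40, "M", 1500),
    ]
    cf = covariate_frame(metas)
    assert cf.loc["a", "sex"] == 0 and cf.loc["b", "sex"] == 1
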