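"""End-to-end orchestration: cohort in, deviation networks, features,
group statistics and outcome models out.

``analyze_cohort`` is the in-memory pipeline used by the CLI, the tests and
the acceptance script; ``run_pipeline`` wraps it with file I/O and a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    Atlas,
    SubjectMeta,
    ValidationError,
    VolumeMatrix,
    covariate_frame,
    read_atlas,
    read_cohort,
)
from .deviation import DEFAULT_THRESHOLD, DeviationNetwork, patient_deviation
from .features import (
    LEVELS,
    build_feature_table,
    feature_matrix,
    global_abnormality,
    modular_abnormality,
    regional_abnormality,
)
from .group_stats import compare_groups
from .normative import ReferenceNetwork, build_rscn
from .outcome import CVReport, ModelConfig, cross_validate, permutation_test
from .resection import ResectionMask, partition_network


@dataclass
class RunConfig:
    atlas_path: str
    volumes_path: str
    metadata_path: str
    out_dir: str
    tau: float = DEFAULT_THRESHOLD
    seed: int = 0
    levels: tuple[str, ...] = LEVELS
    svm_cost: float = 1.0
    n_folds: int = 10
    k_grid: tuple[int, ...] | None = None
    n_permutations: int = 5000
    run_permutation: bool = False
    fixed_covariate_fit: bool = False
    log_level: str = "INFO"


@dataclass
class CohortResults:
    rscn: ReferenceNetwork
    deviations: dict[str, DeviationNetwork]
    feature_table: pd.DataFrame
    global_table: pd.DataFrame
    modular_tables: dict[str, pd.DataFrame]
    outcomes: pd.Series  # patient -> SF/NSF/none
    stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    cv_reports: dict[str, CVReport] = field(default_factory=dict)
    permutation: dict[str, float] = field(default_factory=dict)


def split_cohort(
    volumes: VolumeMatrix, metas: list[SubjectMeta]
) -> tuple[VolumeMatrix, list[SubjectMeta], VolumeMatrix, list[SubjectMeta]]:
    ctrl_ids = [m.subject_id for m in metas if m.group == "control"]
    pat_ids = [m.subject_id for m in metas if m.group == "patient"]
    if not ctrl_ids:
        raise ValidationError("cohort has no controls")
    meta_by_id = {m.subject_id: m for m in metas}
    return (
        volumes.subset(ctrl_ids),
        [meta_by_id[s] for s in ctrl_ids],
        volumes.subset(pat_ids) if pat_ids else None,
        [meta_by_id[s] for s in pat_ids],
    )


def compute_deviations(
    volumes: VolumeMatrix,
    metas: list[SubjectMeta],
    atlas: Atlas,
    tau: float = DEFAULT_THRESHOLD,
    fixed_covariate_fit: bool = False,
) -> tuple[ReferenceNetwork, dict[str, DeviationNetwork]]:
    """Reference network from controls plus one deviation network per patient."""
    ctrl_vm, ctrl_meta, pat_vm, pat_meta = split_cohort(volumes, metas)
    ctrl_cov = covariate_frame(ctrl_meta)
    rscn = build_rscn(ctrl_vm, ctrl_cov)
    devs: dict[str, DeviationNetwork] = {}
    if pat_vm is not None:
        pat_cov = covariate_frame(pat_meta)
        for k, m in enumerate(pat_meta):
            devs[m.subject_id] = patient_deviation(
                ctrl_vm,
                ctrl_cov,
                rscn,
                m.subject_id,
                pat_vm.values[k],
                pat_cov.iloc[k],
                threshold=tau,
                fixed_covariate_fit=fixed_covariate_fit,
            )
    return rscn, devs


def compute_features(
    devs: dict[str, DeviationNetwork],
    metas: list[SubjectMeta],
    atlas: Atlas,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Regional feature table, global table and per-level modular tables."""
    mask = ResectionMask(atlas.resected_ids).validate(atlas)
    meta_by_id = {m.subject_id: m for m in metas}
    regionals: dict[str, pd.DataFrame] = {}
    global_rows = []
    modular_acc: dict[str, dict[str, pd.Series]] = {lvl: {} for lvl in LEVELS}
    for pid, dev in devs.items():
        m = meta_by_id[pid]
        part = partition_network(atlas, mask, m.focus_laterality)
        reg = regional_abnormality(dev, part, atlas, m.focus_laterality)
        regionals[pid] = reg
        g = global_abnormality(dev, part, atlas)
        global_rows.append(
            {
                "patient_id": pid,
                "surgery_strength": g.surgery_strength,
                "spared_strength": g.spared_strength,
                "surgery_count": g.surgery_count,
                "spared_count": g.spared_count,
            }
        )
        mod = modular_abnormality(reg, atlas)
        for lvl in LEVELS:
            modular_acc[lvl][pid] = mod[lvl]
    table = build_feature_table(regionals, atlas)
    global_table = pd.DataFrame(global_rows).set_index("patient_id").sort_index()
    modular_tables = {
        lvl: pd.DataFrame(modular_acc[lvl]).T.sort_index() for lvl in LEVELS
    }
    return table, global_table, modular_tables


def analyze_cohort(
    volumes: VolumeMatrix,
    metas: list[SubjectMeta],
    atlas: Atlas,
    tau: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    levels: tuple[str, ...] = LEVELS,
    svm_cost: float = 1.0,
    n_folds: int = 10,
    k_grid: tuple[int, ...] | None = None,
    n_permutations: int = 0,
    fixed_covariate_fit: bool = False,
) -> CohortResults:
    """Run the full pipeline in memory.

    ``n_permutations > 0`` additionally runs the label-permutation test for
    every requested level (expensive: each permutation repeats the whole
    cross-validation).
    """
    rscn, devs = compute_deviations(
        volumes, metas, atlas, tau, fixed_covariate_fit=fixed_covariate_fit
    )
    if not devs:
        raise ValidationError("cohort has no patients to analyze")
    table, global_table, modular_tables = compute_features(devs, metas, atlas)
    outcomes = pd.Series(
        {m.subject_id: m.outcome for m in metas if m.group == "patient"}
    ).sort_index()

    res = CohortResults(
        rscn=rscn,
        deviations=devs,
        feature_table=table,
        global_table=global_table,
        modular_tables=modular_tables,
        outcomes=outcomes,
    )

    labelled = outcomes[outcomes.isin(["SF", "NSF"])]
    if labelled.nunique() == 2:
        lab = labelled.to_numpy()
        res.stats["global"] = compare_groups(
            global_table.loc[labelled.index, ["surgery_strength", "spared_strength"]],
            lab,
            correct=False,
        )
        for lvl in LEVELS:
            res.stats[f"modular_{lvl}"] = compare_groups(
                modular_tables[lvl].loc[labelled.index], lab, correct=True
            )
        for lvl in levels:
            X, fids = feature_matrix(table.loc[labelled.index], lvl)
            cfg = ModelConfig(
                level=lvl,
                k_grid=k_grid,
                svm_cost=svm_cost,
                n_folds=n_folds,
                n_permutations=n_permutations,
                seed=seed,
            )
            res.cv_reports[lvl] = cross_validate(X, lab, cfg, fids)
            if n_permutations > 0:
                p, _ = permutation_test(
                    X, lab, cfg, observed_accuracy=res.cv_reports[lvl].accuracy
                )
                res.permutation[lvl] = p
    return res


def _manifest(config: RunConfig) -> dict:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "iscn_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }


def run_pipeline(config: RunConfig) -> Path:
    """File-based pipeline: read cohort, analyze, write a run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = read_atlas(config.atlas_path)
    volumes, metas = read_cohort(config.volumes_path, config.metadata_path, atlas)
    res = analyze_cohort(
        volumes,
        metas,
        atlas,
        tau=config.tau,
        seed=config.seed,
        levels=config.levels,
        svm_cost=config.svm_cost,
        n_folds=config.n_folds,
        k_grid=config.k_grid,
        n_permutations=config.n_permutations if config.run_permutation else 0,
        fixed_covariate_fit=config.fixed_covariate_fit,
    )
    # reference network
    pd.DataFrame(
        res.rscn.r, index=atlas.region_ids, columns=atlas.region_ids
    ).to_csv(out / "rscn.tsv", sep="\t")
    (out / "rscn.json").write_text(
        json.dumps({"n": res.rscn.n, "covariates": res.rscn.covariates_used})
    )
    # abnormal edges, long format
    rows = []
    for pid in sorted(res.deviations):
        dev = res.deviations[pid]
        for i, j in sorted(dev.abnormal_edges):
            rows.append(
                {
                    "patient_id": pid,
                    "region_i": int(atlas.region_ids[i]),
                    "region_j": int(atlas.region_ids[j]),
                    "z": dev.z[i, j],
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "region_i", "region_j", "z"]).to_csv(
        out / "abnormal_edges.tsv", sep="\t", index=False
    )
    flat = res.feature_table.copy()
    flat.columns = [f"{lvl}:{rid}" for lvl, rid in flat.columns]
    flat.to_csv(out / "features.tsv", sep="\t")
    res.global_table.to_csv(out / "global_abnormality.tsv", sep="\t")
    for lvl, t in res.modular_tables.items():
        t.to_csv(out / f"modular_{lvl}.tsv", sep="\t")
    for name, t in res.stats.items():
        t.to_csv(out / f"stats_{name}.tsv", sep="\t", index=False)
    cv_payload = {}
    for lvl, rep in res.cv_reports.items():
        cv_payload[lvl] = {
            "accuracy": rep.accuracy,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "auc": rep.auc,
            "k_chosen": rep.k_chosen,
            "accuracy_by_k": {str(k): v for k, v in rep.accuracy_by_k.items()},
            "per_fold": rep.per_fold,
            "selected_features": rep.selected_features,
            "mean_weights": {str(k): v for k, v in rep.mean_weights.items()},
            "permutation_p": res.permutation.get(lvl),
        }
    (out / "cv_reports.json").write_text(json.dumps(cv_payload, indent=2))
    (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))
    return out
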