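"""Synthetic cohorts with known covariance structure and injected deviations.

The generator emulates the statistical skeleton of a structural-covariance
study: control grey-matter volumes follow a latent-factor covariance with
homotopically correlated loadings plus linear age/sex/TIV effects, and
patients are controls whose residual vectors are displaced on chosen region
pairs so that specific reference covariances break.  For a targeted edge
(i, j) with positive reference correlation the residuals are set to
e_i = +delta*sigma_i, e_j = -delta*sigma_j — opposite-signed displacement
along the pair's minor axis, which attenuates the pair's correlation once
the patient is appended to the controls.  Non-seizure-free (NSF) patients
receive more edges, preferentially among contralateral spared-spared
pairs, mirroring the group contrast the deviation statistic must detect.
Every quantity is reproducible from the single config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ANATOMICAL_MODULES,
    YEO_NETWORKS,
    Atlas,
    SubjectMeta,
    ValidationError,
    VolumeMatrix,
    write_atlas,
    write_metadata,
    write_volumes,
)
from .resection import ResectionMask, partition_network

# study-scale defaults: 246-region lateralized parcellation, 78 controls,
# 43 seizure-free / 28 non-seizure-free patients
STUDY_RESECTED = 21
STUDY_REGIONS = 246


@dataclass
class SyntheticConfig:
    """Cohort-generator settings; defaults match the study-scale conditions."""

    n_regions: int = STUDY_REGIONS
    n_controls: int = 78
    n_sf: int = 43
    n_nsf: int = 28
    n_latent: int = 10
    homotopic_rho: float = 0.7  # loading correlation of homotopic pairs
    psi: float = 0.5  # unique-variance share before rescaling
    residual_sd: float = 0.5  # residual SD in volume units (ml)
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.2, "tiv": 0.003}
    )
    delta: float = 4.0  # displacement magnitude in residual-SD units
    edges_per_sf: int = 15
    edges_per_nsf: int = 40
    contra_fraction_sf: float = 0.3
    contra_fraction_nsf: float = 0.8
    site: str = "synthetic"
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_regions % 2:
            raise ValidationError("n_regions must be even (fully lateralized atlas)")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        for f in (self.contra_fraction_sf, self.contra_fraction_nsf):
            if not 0 <= f <= 1:
                raise ValidationError("contra fractions must lie in [0, 1]")
        if self.n_latent < 1:
            raise ValidationError("n_latent must be >= 1")
        if self.n_controls < self.n_regions / 2:
            warnings.warn(
                f"n_controls={self.n_controls} < n_regions/2={self.n_regions // 2}: "
                "reference correlations will be noisy",
                stacklevel=2,
            )
        return self


@dataclass
class StudyModel:
    """Population parameters shared by controls and patients."""

    sigma: np.ndarray  # residual covariance, regions x regions
    base: np.ndarray
    beta_age: np.ndarray
    beta_sex: np.ndarray
    beta_tiv: np.ndarray


@dataclass
class SyntheticStudy:
    atlas: Atlas
    volumes: VolumeMatrix
    metas: list[SubjectMeta]
    ground_truth: dict[str, frozenset[tuple[int, int]]]  # pid -> region-id pairs
    sigma: np.ndarray


def synthetic_atlas(n_regions: int = STUDY_REGIONS, n_resected: int | None = None) -> Atlas:
    """Deterministic fully-lateralized toy parcellation.

    Homotopic pair k gets left id 2k+1 and right id 2k+2; anatomical modules
    and Yeo networks cycle over the pairs, subcortical pairs map to Yeo
    ``none``, and the canonical resection mask takes left members of
    temporal/limbic pairs first (scaled from 21 of 246 by default).
    """
    if n_regions % 2:
        raise ValidationError("n_regions must be even")
    n_pairs = n_regions // 2
    if n_resected is None:
        n_resected = max(1, round(n_regions * STUDY_RESECTED / STUDY_REGIONS))
    if n_resected > n_pairs:
        raise ValidationError("more resected regions than homotopic pairs")
    rows = []
    modules = [ANATOMICAL_MODULES[k % 7] for k in range(n_pairs)]
    preferred = [k for k in range(n_pairs) if modules[k] in ("temporal", "limbic")]
    others = [k for k in range(n_pairs) if modules[k] not in ("temporal", "limbic")]
    resected_pairs = set((preferred + others)[:n_resected])
    for k in range(n_pairs):
        module = modules[k]
        yeo = "none" if module == "subcortical" else YEO_NETWORKS[k % 7]
        lid, rid = 2 * k + 1, 2 * k + 2
        rows.append(
            dict(region_id=lid, name=f"L_{k:03d}", hemisphere="L",
                 homotopic_partner=rid, module=module, yeo=yeo,
                 resected=k in resected_pairs)
        )
        rows.append(
            dict(region_id=rid, name=f"R_{k:03d}", hemisphere="R",
                 homotopic_partner=lid, module=module, yeo=yeo, resected=False)
        )
    return Atlas(pd.DataFrame(rows)).validate()


def make_reference_covariance(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Symmetric positive-definite residual covariance Sigma = LL' + psi*I.

    Factor loadings of homotopic pairs are correlated (``homotopic_rho``)
    so left/right structure resembles real covariance networks; the result
    is rescaled to unit-free correlation times ``residual_sd**2``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p, q = config.n_regions, config.n_latent
    L = np.empty((p, q))
    rho = config.homotopic_rho
    for k in range(p // 2):
        a = rng.normal(size=q)
        b = rng.normal(size=q)
        L[2 * k] = a
        L[2 * k + 1] = rho * a + np.sqrt(1 - rho**2) * b
    L /= np.sqrt(q)
    sigma = L @ L.T + config.psi * np.eye(p)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    return config.residual_sd**2 * corr


def build_study_model(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> StudyModel:
    """Draw the population parameters (one deterministic draw per seed)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sigma = make_reference_covariance(config, rng)
    p = config.n_regions
    eff = config.covariate_effects
    return StudyModel(
        sigma=sigma,
        base=rng.uniform(5.0, 10.0, p),
        beta_age=rng.normal(0.0, eff.get("age", 0.0), p),
        beta_sex=rng.normal(0.0, eff.get("sex", 0.0), p),
        beta_tiv=rng.normal(eff.get("tiv", 0.0), eff.get("tiv", 0.0) / 3 or 0.0, p),
    )


def _draw_covariates(rng: np.random.Generator) -> dict:
    return {
        "age": float(rng.uniform(20.0, 50.0)),
        "sex": int(rng.integers(0, 2)),  # F=0, M=1
        "tiv": float(rng.normal(1400.0, 120.0)),
    }


def _volume_row(model: StudyModel, cov: dict, resid: np.ndarray) -> np.ndarray:
    return (
        model.base
        + model.beta_age * cov["age"]
        + model.beta_sex * cov["sex"]
        + model.beta_tiv * cov["tiv"]
        + resid
    )


def simulate_controls(
    config: SyntheticConfig,
    atlas: Atlas | None = None,
    model: StudyModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[VolumeMatrix, list[SubjectMeta]]:
    """Simulate the control cohort from the shared population model."""
    config.validate()
    atlas = synthetic_atlas(config.n_regions) if atlas is None else atlas
    rng = np.random.default_rng(config.seed) if rng is None else rng
    model = build_study_model(config, rng) if model is None else model
    chol = np.linalg.cholesky(model.sigma)
    rows, metas = [], []
    for s in range(config.n_controls):
        cov = _draw_covariates(rng)
        resid = chol @ rng.standard_normal(config.n_regions)
        rows.append(_volume_row(model, cov, resid))
        metas.append(
            SubjectMeta(
                subject_id=f"ctrl{s:03d}",
                group="control",
                age=cov["age"],
                sex="M" if cov["sex"] else "F",
                tiv=cov["tiv"],
                site=config.site,
            ).validate()
        )
    vm = VolumeMatrix(
        subjects=[m.subject_id for m in metas],
        region_ids=atlas.region_ids,
        values=np.array(rows),
    ).validate(atlas)
    return vm, metas


def _injection_pools(
    config: SyntheticConfig, atlas: Atlas, sigma: np.ndarray, laterality: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(contralateral, other) spared-spared index pairs with reference r > 0."""
    mask = ResectionMask(atlas.resected_ids)
    part = partition_network(atlas, mask, laterality)
    spared = np.sort(atlas.index_of(sorted(part.spared_nodes)))
    hemi = atlas.hemispheres
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    contra_side = "R" if laterality == "L" else "L"
    contra, other = [], []
    for a in range(len(spared)):
        for b in range(a + 1, len(spared)):
            i, j = int(spared[a]), int(spared[b])
            if corr[i, j] <= 0:
                continue
            if hemi[i] == contra_side and hemi[j] == contra_side:
                contra.append((i, j))
            else:
                other.append((i, j))
    return contra, other


def simulate_patient(
    config: SyntheticConfig,
    outcome: str,
    laterality: str,
    atlas: Atlas,
    model: StudyModel,
    rng: np.random.Generator,
    patient_id: str = "pat000",
) -> tuple[np.ndarray, SubjectMeta, frozenset[tuple[int, int]]]:
    """One patient row with injected edge-level deviations.

    Returns (volume row, metadata, injected region-id pairs).  With
    ``delta=0`` the patient is statistically exchangeable with controls.
    """
    if outcome not in ("SF", "NSF"):
        raise ValidationError(f"outcome must be SF or NSF, got {outcome!r}")
    if laterality not in ("L", "R"):
        raise ValidationError("laterality must be L or R")
    cov = _draw_covariates(rng)
    chol = np.linalg.cholesky(model.sigma)
    resid = chol @ rng.standard_normal(config.n_regions)
    n_edges = config.edges_per_nsf if outcome == "NSF" else config.edges_per_sf
    frac = (
        config.contra_fraction_nsf if outcome == "NSF" else config.contra_fraction_sf
    )
    injected: set[tuple[int, int]] = set()
    if config.delta > 0 and n_edges > 0:
        contra_pool, other_pool = _injection_pools(
            config, atlas, model.sigma, laterality
        )
        n_contra = int(round(frac * n_edges))
        n_other = n_edges - n_contra
        if n_contra > len(contra_pool) or n_other > len(other_pool):
            raise ValidationError(
                f"requested {n_contra}+{n_other} injection edges but pools hold "
                f"{len(contra_pool)}/{len(other_pool)} eligible pairs"
            )
        sd = np.sqrt(np.diag(model.sigma))
        picks = []
        if n_contra:
            picks += [
                contra_pool[k]
                for k in rng.choice(len(contra_pool), size=n_contra, replace=False)
            ]
        if n_other:
            picks += [
                other_pool[k]
                for k in rng.choice(len(other_pool), size=n_other, replace=False)
            ]
        for i, j in picks:
            resid[i] = +config.delta * sd[i]
            resid[j] = -config.delta * sd[j]
            a, b = int(atlas.region_ids[i]), int(atlas.region_ids[j])
            injected.add((min(a, b), max(a, b)))
    row = _volume_row(model, cov, resid)
    meta = SubjectMeta(
        subject_id=patient_id,
        group="patient",
        age=cov["age"],
        sex="M" if cov["sex"] else "F",
        tiv=cov["tiv"],
        focus_laterality=laterality,
        outcome=outcome,
        site=config.site,
    ).validate()
    return row, meta, frozenset(injected)


def simulate_study(
    config: SyntheticConfig, atlas: Atlas | None = None
) -> SyntheticStudy:
    """Full cohort (controls + SF + NSF patients) with ground truth.

    All randomness flows from ``config.seed``; identical configs reproduce
    identical studies.
    """
    config.validate()
    atlas = synthetic_atlas(config.n_regions) if atlas is None else atlas
    rng = np.random.default_rng(config.seed)
    model = build_study_model(config, rng)
    ctrl_vm, ctrl_meta = simulate_controls(config, atlas, model, rng)
    rows = [ctrl_vm.values]
    metas = list(ctrl_meta)
    truth: dict[str, frozenset[tuple[int, int]]] = {}
    counter = 0
    for outcome, n in (("SF", config.n_sf), ("NSF", config.n_nsf)):
        for _ in range(n):
            lat = "L" if rng.random() < 0.5 else "R"
            pid = f"pat{counter:03d}"
            row, meta, injected = simulate_patient(
                config, outcome, lat, atlas, model, rng, pid
            )
            rows.append(row.reshape(1, -1))
            metas.append(meta)
            truth[pid] = injected
            counter += 1
    vm = VolumeMatrix(
        subjects=[m.subject_id for m in metas],
        region_ids=atlas.region_ids,
        values=np.vstack(rows),
    ).validate(atlas)
    return SyntheticStudy(
        atlas=atlas, volumes=vm, metas=metas, ground_truth=truth, sigma=model.sigma
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write atlas/volumes/metadata plus the ground-truth sidecar as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "atlas": outdir / "atlas.tsv",
        "volumes": outdir / "volumes.tsv",
        "metadata": outdir / "metadata.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    write_atlas(study.atlas, paths["atlas"])
    write_volumes(study.volumes, paths["volumes"])
    write_metadata(study.metas, paths["metadata"])
    rows = [
        {"patient_id": pid, "region_i": i, "region_j": j}
        for pid in sorted(study.ground_truth)
        for i, j in sorted(study.ground_truth[pid])
    ]
    pd.DataFrame(rows, columns=["patient_id", "region_i", "region_j"]).to_csv(
        paths["ground_truth"], sep="\t", index=False
    )
    return paths


def node_disjoint_null_edges(
    injected: frozenset[tuple[int, int]],
    candidate_edges,
) -> list[tuple[int, int]]:
    """Candidate edges sharing no node with any injected edge.

    Both arguments use region ids; this is the comparison set for
    ground-truth detection checks (avoids ambiguity from edges that merely
    touch an injected node).
    """
    hot = {n for e in injected for n in e}
    return [e for e in candidate_edges if e[0] not in hot and e[1] not in hot]


def detection_auc(
    dev_z: np.ndarray,
    atlas: Atlas,
    injected: frozenset[tuple[int, int]],
    candidate_edges,
) -> float:
    """Mann-Whitney AUC of |Z| for injected vs node-disjoint null edges."""
    if not injected:
        raise ValidationError("no injected edges to score")
    idx = {int(r): i for i, r in enumerate(atlas.region_ids)}
    null = node_disjoint_null_edges(injected, candidate_edges)
    if not null:
        raise ValidationError("no node-disjoint null edges available")
    zi = np.array([abs(dev_z[idx[a], idx[b]]) for a, b in injected])
    zn = np.array([abs(dev_z[idx[a], idx[b]]) for a, b in null])
    wins = (zi[:, None] > zn[None, :]).sum() + 0.5 * (zi[:, None] == zn[None, :]).sum()
    return float(wins / (len(zi) * len(zn)))
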