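"""Domain types and tabular I/O for atlas, cohort metadata and volume tables.

The atlas is a fully lateralized parcellation: every region has a homotopic
partner in the opposite hemisphere, belongs to one of seven anatomical
modules, and may carry a flag marking membership in the canonical
(left-lateralized) group-level resection mask.  Internally regions are
indexed 0-based in atlas-file row order; file-facing identifiers are the
atlas's 1-based integer labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ANATOMICAL_MODULES = (
    "frontal",
    "temporal",
    "parietal",
    "insular",
    "limbic",
    "occipital",
    "subcortical",
)

YEO_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal-attention",
    "ventral-attention",
    "limbic",
    "frontoparietal",
    "default",
    "none",
)

ATLAS_COLUMNS = (
    "region_id",
    "name",
    "hemisphere",
    "homotopic_partner",
    "module",
    "yeo",
    "resected",
)

META_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "tiv",
    "laterality",
    "outcome",
    "site",
)


class FormatError(ValueError):
    """A table is missing required columns or cannot be parsed."""


class ValidationError(ValueError):
    """A table parses but violates a domain invariant."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass(frozen=True)
class Atlas:
    """Validated brain parcellation table.

    Attributes
    ----------
    table
        One row per region in atlas order, with the canonical columns
        ``region_id, name, hemisphere, homotopic_partner, module, yeo,
        resected``.
    """

    table: pd.DataFrame

    # -- derived arrays -------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def modules(self) -> np.ndarray:
        return self.table["module"].to_numpy()

    @property
    def yeo(self) -> np.ndarray:
        return self.table["yeo"].to_numpy()

    @property
    def partner_index(self) -> np.ndarray:
        """0-based index of each region's homotopic partner."""
        id_to_idx = {rid: i for i, rid in enumerate(self.region_ids)}
        return np.array(
            [id_to_idx[p] for p in self.table["homotopic_partner"]], dtype=int
        )

    @property
    def resected_ids(self) -> frozenset[int]:
        """Region ids in the canonical (left-lateralized) resection mask."""
        mask = self.table["resected"].astype(bool).to_numpy()
        return frozenset(int(r) for r in self.region_ids[mask])

    def index_of(self, region_ids: Sequence[int]) -> np.ndarray:
        id_to_idx = {rid: i for i, rid in enumerate(self.region_ids)}
        return np.array([id_to_idx[r] for r in region_ids], dtype=int)

    def partner_of(self, region_id: int) -> int:
        row = self.table.loc[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return int(row["homotopic_partner"].iloc[0])

    def validate(self) -> "Atlas":
        t = self.table
        missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"atlas missing columns: {missing}")
        ids = t["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate region ids in atlas")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_mod = set(t["module"]) - set(ANATOMICAL_MODULES)
        if bad_mod:
            raise ValidationError(f"unknown module labels: {sorted(bad_mod)}")
        bad_yeo = set(t["yeo"]) - set(YEO_NETWORKS)
        if bad_yeo:
            raise ValidationError(f"unknown yeo labels: {sorted(bad_yeo)}")
        id_set = set(int(i) for i in ids)
        hemi = dict(zip((int(i) for i in ids), t["hemisphere"]))
        partner = dict(
            zip((int(i) for i in ids), (int(p) for p in t["homotopic_partner"]))
        )
        for rid, p in partner.items():
            if p not in id_set:
                raise ValidationError(f"region {rid}: partner {p} not in atlas")
            if p == rid:
                raise ValidationError(f"region {rid} is its own homotopic partner")
            if partner[p] != rid:
                raise ValidationError(
                    f"homotopic pairing is not an involution: partner({rid})={p} "
                    f"but partner({p})={partner[p]}"
                )
            if hemi[p] == hemi[rid]:
                raise ValidationError(
                    f"homotopic pair ({rid}, {p}) does not cross hemispheres"
                )
        for rid in self.resected_ids:
            if hemi[rid] != "L":
                raise ValidationError(
                    f"resection-mask region {rid} is not in hemisphere L "
                    "(mask must be canonical)"
                )
        return self


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject metadata: demographics, nuisance covariates and labels."""

    subject_id: str
    group: str  # control | patient
    age: float
    sex: str  # F | M
    tiv: float
    focus_laterality: str = "none"  # L | R | none
    outcome: str = "none"  # SF | NSF | none
    site: str = ""

    def validate(self) -> "SubjectMeta":
        if self.group not in ("control", "patient"):
            raise ValidationError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.subject_id}: unknown sex {self.sex!r}")
        if self.group == "control":
            if self.focus_laterality != "none" or self.outcome != "none":
                raise ValidationError(
                    f"control {self.subject_id} must have laterality=none and "
                    f"outcome=none (got {self.focus_laterality}, {self.outcome})"
                )
        else:
            if self.focus_laterality not in ("L", "R"):
                raise ValidationError(
                    f"patient {self.subject_id}: focus laterality must be L or R"
                )
            if self.outcome not in ("SF", "NSF", "none"):
                raise ValidationError(
                    f"patient {self.subject_id}: unknown outcome {self.outcome!r}"
                )
        return self

    @property
    def sex_code(self) -> int:
        # F=0, M=1; any consistent binary coding is equivalent after centering
        return 0 if self.sex == "F" else 1


@dataclass
class VolumeMatrix:
    """Subjects x regions grey-matter volume matrix aligned to an atlas."""

    subjects: list[str]
    region_ids: np.ndarray
    values: np.ndarray  # shape (n_subjects, n_regions)

    def validate(self, atlas: Atlas | None = None) -> "VolumeMatrix":
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subjects), len(self.region_ids)):
            raise ValidationError("volume matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise ValidationError("volume matrix contains missing/non-finite values")
        if not np.all(v > 0):
            raise ValidationError("grey-matter volumes must be strictly positive")
        if atlas is not None and not np.array_equal(self.region_ids, atlas.region_ids):
            raise ValidationError("volume columns do not match atlas region order")
        return self

    def subset(self, subject_ids: Sequence[str]) -> "VolumeMatrix":
        idx = [self.subjects.index(s) for s in subject_ids]
        return VolumeMatrix(
            subjects=list(subject_ids),
            region_ids=self.region_ids,
            values=self.values[idx],
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_atlas(path: str | Path) -> Atlas:
    """Read and validate an atlas table (TSV/CSV)."""
    t = _read_table(path)
    missing = [c for c in ATLAS_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"atlas file {path}: missing columns {missing}")
    t = t[list(ATLAS_COLUMNS)].copy()
    t["region_id"] = t["region_id"].astype(int)
    t["homotopic_partner"] = t["homotopic_partner"].astype(int)
    t["resected"] = t["resected"].astype(int).astype(bool)
    return Atlas(table=t.reset_index(drop=True)).validate()


def write_atlas(atlas: Atlas, path: str | Path) -> None:
    path = Path(path)
    t = atlas.table.copy()
    t["resected"] = t["resected"].astype(int)
    t.to_csv(path, sep=_sep_for(path), index=False)


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    t = _read_table(path)
    missing = [c for c in META_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"metadata file {path}: missing columns {missing}")
    metas = []
    for _, row in t.iterrows():
        metas.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                tiv=float(row["tiv"]),
                focus_laterality=str(row["laterality"]),
                outcome=str(row["outcome"]),
                site=str(row["site"]),
            ).validate()
        )
    return metas


def write_metadata(metas: Sequence[SubjectMeta], path: str | Path) -> None:
    path = Path(path)
    rows = [
        {
            "subject_id": m.subject_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "tiv": m.tiv,
            "laterality": m.focus_laterality,
            "outcome": m.outcome,
            "site": m.site,
        }
        for m in metas
    ]
    pd.DataFrame(rows, columns=list(META_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_volumes(path: str | Path, atlas: Atlas | None = None) -> VolumeMatrix:
    t = _read_table(path)
    if t.columns[0] != "subject_id":
        raise FormatError(f"volume file {path}: first column must be subject_id")
    subjects = [str(s) for s in t["subject_id"]]
    region_ids = np.array([int(c) for c in t.columns[1:]])
    values = t.iloc[:, 1:].to_numpy(dtype=float)
    vm = VolumeMatrix(subjects=subjects, region_ids=region_ids, values=values)
    return vm.validate(atlas)


def write_volumes(vm: VolumeMatrix, path: str | Path) -> None:
    path = Path(path)
    t = pd.DataFrame(vm.values, columns=[str(r) for r in vm.region_ids])
    t.insert(0, "subject_id", vm.subjects)
    t.to_csv(path, sep=_sep_for(path), index=False)


def read_cohort(
    volumes_path: str | Path, meta_path: str | Path, atlas: Atlas
) -> tuple[VolumeMatrix, list[SubjectMeta]]:
    """Read volumes + metadata, align subjects and validate against the atlas."""
    volumes = read_volumes(volumes_path, atlas)
    metas = read_metadata(meta_path)
    meta_ids = [m.subject_id for m in metas]
    if set(volumes.subjects) != set(meta_ids):
        only_v = sorted(set(volumes.subjects) - set(meta_ids))[:5]
        only_m = sorted(set(meta_ids) - set(volumes.subjects))[:5]
        raise ValidationError(
            f"subject id mismatch between volumes and metadata "
            f"(volumes-only: {only_v}, metadata-only: {only_m})"
        )
    # align volume rows to metadata order
    volumes = volumes.subset(meta_ids)
    return volumes, metas


def covariate_frame(metas: Sequence[SubjectMeta]) -> pd.DataFrame:
    """Nuisance-covariate table (age, sex code, TIV) indexed by subject."""
    return pd.DataFrame(
        {
            "age": [m.age for m in metas],
            "sex": [m.sex_code for m in metas],
            "tiv": [m.tiv for m in metas],
        },
        index=[m.subject_id for m in metas],
    )
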