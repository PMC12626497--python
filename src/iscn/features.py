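"""Abnormality-strength aggregation over supra-threshold deviation edges.

Each patient's abnormal edges (|Z| above threshold) are summarized as sums
of |Z|:

* globally, within the surgery and spared subnetworks;
* regionally, for every spared region, at three levels — bilateral (all
  spared partners), ipsilateral (partners on the seizure-focus side) and
  contralateral (partners opposite the focus);
* modularly, by summing regional values over the seven anatomical modules.

Features from right-focus patients are mapped through the homotopic
involution so that every patient lives in a focus-relative canonical space
(ipsilateral = left hemisphere); this makes regional features comparable
across patients with different focus sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import Atlas, ValidationError
from .deviation import DeviationNetwork
from .resection import NetworkPartition

LEVELS = ("bilateral", "ipsilateral", "contralateral")


@dataclass(frozen=True)
class GlobalAbnormality:
    surgery_strength: float
    spared_strength: float
    surgery_count: int
    spared_count: int


def regional_abnormality(
    dev: DeviationNetwork,
    partition: NetworkPartition,
    atlas: Atlas,
    focus_laterality: str,
    canonicalize: bool = True,
    seed_laterality: bool = False,
) -> pd.DataFrame:
    """Per-spared-region abnormality strengths (bilateral, ipsi, contra).

    For spared region u, bilateral(u) sums |z| over abnormal spared-spared
    edges incident to u; the ipsilateral/contralateral components restrict
    the sum to partners on the focus side / the opposite side.  With
    ``seed_laterality=True`` the split is instead by the seed region's own
    hemisphere (documented alternative reading).  With ``canonicalize=True``
    (default) right-focus patients' regions are relabeled through the
    homotopic map so the returned index is the canonical spared set.
    """
    if focus_laterality not in ("L", "R"):
        raise ValidationError(f"focus laterality must be L or R, got {focus_laterality!r}")
    hemi = atlas.hemispheres
    spared_idx = np.sort(atlas.index_of(sorted(partition.spared_nodes)))
    spared_set = set(spared_idx.tolist())
    bilateral = dict.fromkeys(spared_idx.tolist(), 0.0)
    ipsi = dict.fromkeys(spared_idx.tolist(), 0.0)
    contra = dict.fromkeys(spared_idx.tolist(), 0.0)
    absz = np.abs(dev.z)
    for i, j in dev.abnormal_edges:
        if i not in spared_set or j not in spared_set:
            continue
        w = absz[i, j]
        for u, v in ((i, j), (j, i)):
            bilateral[u] += w
            side = hemi[u] if seed_laterality else hemi[v]
            if side == focus_laterality:
                ipsi[u] += w
            else:
                contra[u] += w
    idx = spared_idx
    out = pd.DataFrame(
        {
            "bilateral": [bilateral[u] for u in idx],
            "ipsilateral": [ipsi[u] for u in idx],
            "contralateral": [contra[u] for u in idx],
        },
        index=pd.Index(atlas.region_ids[idx], name="region_id"),
    )
    if canonicalize and focus_laterality == "R":
        partner = atlas.partner_index
        canon_ids = atlas.region_ids[partner[idx]]
        out.index = pd.Index(canon_ids, name="region_id")
        out = out.sort_index()
    return out


def global_abnormality(
    dev: DeviationNetwork, partition: NetworkPartition, atlas: Atlas
) -> GlobalAbnormality:
    """Sum of |z| (and edge counts) over abnormal edges in each subnetwork."""
    surg_idx = set(atlas.index_of(sorted(partition.surgical_nodes)).tolist())
    absz = np.abs(dev.z)
    surgery = spared = 0.0
    n_surg = n_spared = 0
    for i, j in dev.abnormal_edges:
        if i in surg_idx or j in surg_idx:
            surgery += absz[i, j]
            n_surg += 1
        else:
            spared += absz[i, j]
            n_spared += 1
    return GlobalAbnormality(surgery, spared, n_surg, n_spared)


def modular_abnormality(regional: pd.DataFrame, atlas: Atlas) -> pd.DataFrame:
    """Sum regional abnormality strengths within each anatomical module.

    The bilateral cell sums every spared region in the module; the
    ipsilateral/contralateral cells sum the corresponding regional component
    over the module's regions in the respective (canonical) hemisphere —
    ipsilateral = L, contralateral = R in canonical space.
    """
    module_of = dict(zip((int(i) for i in atlas.region_ids), atlas.modules))
    hemi_of = dict(zip((int(i) for i in atlas.region_ids), atlas.hemispheres))
    modules = sorted(set(atlas.modules))
    rows = []
    for m in modules:
        in_m = [int(r) for r in regional.index if module_of[int(r)] == m]
        bi = float(regional.loc[in_m, "bilateral"].sum()) if in_m else 0.0
        ip = float(
            regional.loc[[r for r in in_m if hemi_of[r] == "L"], "ipsilateral"].sum()
        )
        co = float(
            regional.loc[[r for r in in_m if hemi_of[r] == "R"], "contralateral"].sum()
        )
        rows.append({"module": m, "bilateral": bi, "ipsilateral": ip, "contralateral": co})
    return pd.DataFrame(rows).set_index("module")


def build_feature_table(
    regionals: dict[str, pd.DataFrame], atlas: Atlas
) -> pd.DataFrame:
    """Stack per-patient regional tables into a patients x (level, region) table.

    All patients must share the canonical spared-region index (guaranteed
    when ``regional_abnormality`` ran with ``canonicalize=True`` against one
    group mask).
    """
    if not regionals:
        raise ValidationError("no patients to tabulate")
    ids = sorted(regionals)
    ref_index = regionals[ids[0]].index
    cols = pd.MultiIndex.from_product(
        [LEVELS, ref_index.tolist()], names=["level", "region_id"]
    )
    data = np.zeros((len(ids), len(cols)))
    for k, pid in enumerate(ids):
        tab = regionals[pid]
        if not tab.index.equals(ref_index):
            raise ValidationError(
                f"patient {pid}: spared-region index differs from cohort index"
            )
        data[k] = np.concatenate([tab[lvl].to_numpy() for lvl in LEVELS])
    return pd.DataFrame(data, index=pd.Index(ids, name="patient_id"), columns=cols)


def feature_matrix(table: pd.DataFrame, level: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract one level's patients x regions matrix plus its region ids."""
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level!r}")
    sub = table[level]
    return sub.to_numpy(dtype=float), np.asarray(sub.columns, dtype=int)
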