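"""Virtual resection: surgical-node definition and network partition.

Surgical nodes are atlas regions whose volume overlaps an individual
resection area by at least 50%.  Nodes from right-sided patients are
flipped to their left homotopic partners, individual node sets are merged
into a canonical left-lateralized group mask, and each patient's network is
partitioned into a surgery subnetwork (surgical nodes and every edge
incident to them) and a spared subnetwork (the remaining nodes and their
mutual edges).  For right-focus patients the canonical mask is mirrored
back to the right hemisphere before partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import Atlas, ValidationError

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class ResectionMask:
    """Canonical (left-lateralized) group-level set of surgical regions."""

    surgical_regions: frozenset[int]

    def validate(self, atlas: Atlas) -> "ResectionMask":
        ids = set(int(i) for i in atlas.region_ids)
        hemi = dict(zip((int(i) for i in atlas.region_ids), atlas.hemispheres))
        for r in self.surgical_regions:
            if r not in ids:
                raise ValidationError(f"mask region {r} not in atlas")
            if hemi[r] != "L":
                raise ValidationError(f"mask region {r} is not left-hemisphere")
        return self


@dataclass(frozen=True)
class NetworkPartition:
    """Disjoint surgical/spared node sets (region ids) for one laterality."""

    surgical_nodes: frozenset[int]
    spared_nodes: frozenset[int]

    def surgery_edges(self, atlas: Atlas) -> frozenset[tuple[int, int]]:
        """Index pairs (i<j) with at least one surgical endpoint."""
        surg = set(atlas.index_of(sorted(self.surgical_nodes)).tolist())
        p = atlas.n_regions
        edges = set()
        for i in range(p):
            for j in range(i + 1, p):
                if i in surg or j in surg:
                    edges.add((i, j))
        return frozenset(edges)

    def spared_edges(self, atlas: Atlas) -> frozenset[tuple[int, int]]:
        """Index pairs (i<j) with both endpoints spared."""
        spared = sorted(atlas.index_of(sorted(self.spared_nodes)).tolist())
        return frozenset(
            (spared[a], spared[b])
            for a in range(len(spared))
            for b in range(a + 1, len(spared))
        )


def region_overlap_fraction(
    region_voxels: Iterable, resection_voxels: Iterable
) -> float:
    """|region ∩ resection| / |region| for voxel index sets on one grid."""
    region = set(region_voxels)
    if not region:
        raise ValidationError("region mask is empty")
    return len(region & set(resection_voxels)) / len(region)


def surgical_nodes_from_overlaps(
    overlaps: Mapping[int, float], threshold: float = DEFAULT_OVERLAP_THRESHOLD
) -> frozenset[int]:
    """Regions whose overlap proportion meets the threshold (inclusive)."""
    return frozenset(int(r) for r, f in overlaps.items() if f >= threshold)


def surgical_nodes_from_mask_arrays(
    region_labels: np.ndarray,
    resection_mask: np.ndarray,
    atlas: Atlas,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> frozenset[int]:
    """Overlap rule applied to a voxelwise label image and a binary mask.

    ``region_labels`` holds atlas region ids per voxel (0 = background);
    both arrays must share one grid (e.g. loaded from co-registered NIfTI
    images via nibabel).
    """
    labels = np.asarray(region_labels)
    mask = np.asarray(resection_mask).astype(bool)
    if labels.shape != mask.shape:
        raise ValidationError("label image and resection mask shapes differ")
    overlaps = {}
    for rid in atlas.region_ids:
        region = labels == rid
        size = int(region.sum())
        if size == 0:
            continue
        overlaps[int(rid)] = int((region & mask).sum()) / size
    return surgical_nodes_from_overlaps(overlaps, threshold)


def flip_to_left(nodes: Iterable[int], atlas: Atlas) -> frozenset[int]:
    """Replace right-hemisphere nodes by their left homotopic partners."""
    hemi = dict(zip((int(i) for i in atlas.region_ids), atlas.hemispheres))
    partner = dict(
        zip(
            (int(i) for i in atlas.region_ids),
            (int(p) for p in atlas.table["homotopic_partner"]),
        )
    )
    out = set()
    for n in nodes:
        n = int(n)
        if n not in hemi:
            raise ValidationError(f"node {n} not in atlas")
        out.add(partner[n] if hemi[n] == "R" else n)
    return frozenset(out)


def mirror_mask(nodes: Iterable[int], atlas: Atlas) -> frozenset[int]:
    """Map every node to its homotopic partner (hemisphere mirror)."""
    partner = dict(
        zip(
            (int(i) for i in atlas.region_ids),
            (int(p) for p in atlas.table["homotopic_partner"]),
        )
    )
    return frozenset(partner[int(n)] for n in nodes)


def merge_group_mask(
    individual_node_sets: Sequence[Iterable[int]], atlas: Atlas
) -> ResectionMask:
    """Union of canonicalized individual surgical-node sets."""
    if len(individual_node_sets) == 0:
        raise ValidationError("no individual node sets to merge")
    merged: set[int] = set()
    for nodes in individual_node_sets:
        merged |= flip_to_left(nodes, atlas)
    return ResectionMask(frozenset(merged)).validate(atlas)


def partition_network(
    atlas: Atlas, mask: ResectionMask, focus_laterality: str
) -> NetworkPartition:
    """Split the atlas into surgery/spared node sets for one patient.

    The canonical mask is left-lateralized; for a right-focus patient it is
    mirrored to the right hemisphere first.
    """
    if focus_laterality not in ("L", "R"):
        raise ValidationError(f"unknown focus laterality {focus_laterality!r}")
    mask.validate(atlas)
    nodes = (
        mirror_mask(mask.surgical_regions, atlas)
        if focus_laterality == "R"
        else frozenset(mask.surgical_regions)
    )
    all_ids = frozenset(int(i) for i in atlas.region_ids)
    return NetworkPartition(surgical_nodes=nodes, spared_nodes=all_ids - nodes)
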