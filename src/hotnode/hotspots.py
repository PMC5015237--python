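"""SPECT hot-spot detection and segmentation.

Seeds are the local maxima of the background-suppressed SPECT under a moving
3x3x3 mask.  From every seed an independent region is grown over the
26-neighbourhood: a neighbour of an accepted voxel is absorbed iff its value is
positive and does not exceed the accepted voxel's value (descent-only growth;
an increase is never crossed).  Voxels claimed by two or more seeds — "common
voxels", typically saddle regions between touching foci — are deleted from all
regions afterwards, so the final hot spots are pairwise disjoint and no focus
is absorbed by a hotter neighbour.

Growth is realised iteratively (an explicit stack) rather than by recursion,
to avoid depth limits on large regions; the contract is identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import Modality, Volume

log = logging.getLogger(__name__)

__all__ = ["Seed", "HotSpot", "find_seeds", "grow_region", "segment_hotspots",
           "adjacent_pair_count", "hotspots_to_json", "label_map"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Seed:
    index: tuple[int, int, int]
    value: float


@dataclass(frozen=True)
class HotSpot:
    """One segmented SPECT focus (after common-voxel deletion)."""

    label: int
    seed: Seed
    voxels: frozenset[tuple[int, int, int]]
    peak_value: float
    total_counts: float
    centroid_mm: tuple[float, float, float]
    common_voxels_removed: int = 0

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def find_seeds(v: Volume) -> list[Seed]:
    """All voxels whose value is >= every in-bounds 26-neighbour and > 0.

    A connected plateau of equal maximal values yields exactly one seed, at the
    lexicographically smallest index.  Result is sorted by descending value,
    ties broken lexicographically.  Border voxels use truncated
    neighbourhoods.
    """
    if v.modality is not Modality.SPECT:
        raise ValueError("seeds are detected on SPECT volumes")
    if any(n < 3 for n in v.shape):
        raise ValueError(f"need >= 3 voxels per axis for the 3x3x3 mask, got {v.shape}")
    vals = v.values
    # -inf padding == truncated neighbourhood at the border
    neigh_max = ndimage.maximum_filter(vals, size=3, mode="constant", cval=-np.inf)
    candidate = (vals >= neigh_max) & (vals > 0)
    if not candidate.any():
        return []
    # adjacent candidates are necessarily equal-valued (each >= the other),
    # so each 26-connected candidate component is one plateau -> one seed
    lab, n = ndimage.label(candidate, structure=_STRUCT26)
    seeds = []
    for k in range(1, n + 1):
        idxs = np.argwhere(lab == k)  # argwhere is C-ordered == lexicographic
        i = tuple(int(x) for x in idxs[0])
        seeds.append(Seed(index=i, value=float(vals[i])))
    seeds.sort(key=lambda s: (-s.value, s.index))
    return seeds


def _grow_flat(padded: np.ndarray, offsets: np.ndarray, start: int) -> list[int]:
    """Stack-based monotone growth on a zero-padded flattened volume.

    Accept neighbour n of accepted voxel c iff 0 < value(n) <= value(c).  The
    zero padding ring can never be accepted, so no bounds checks are needed.
    Returns flat indices (into the padded array) of the claimed voxels.
    """
    flat = padded.ravel()
    accepted = np.zeros(flat.shape[0], dtype=bool)
    accepted[start] = True
    stack = [start]
    members = [start]
    while stack:
        c = stack.pop()
        vc = flat[c]
        for off in offsets:
            nb = c + off
            if accepted[nb]:
                continue
            vn = flat[nb]
            if 0.0 < vn <= vc:
                accepted[nb] = True
                stack.append(nb)
                members.append(nb)
    return members


def _pad_geometry(shape: tuple[int, int, int], values: np.ndarray):
    padded = np.pad(values, 1, mode="constant", constant_values=0.0)
    ps = padded.shape
    offs = [dx * ps[1] * ps[2] + dy * ps[2] + dz
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]
    return padded, np.asarray(offs, dtype=np.int64)


def _flat_to_index(flat: int, padded_shape) -> tuple[int, int, int]:
    x, r = divmod(flat, padded_shape[1] * padded_shape[2])
    y, z = divmod(r, padded_shape[2])
    return (x - 1, y - 1, z - 1)


def grow_region(v: Volume, seed: Seed) -> set[tuple[int, int, int]]:
    """Claim-set of one seed: all voxels reachable by non-increasing positive descent.

    Equivalent to: voxel q is claimed iff a 26-connected path seed -> q exists
    along which values are positive and never increase.
    """
    if seed.value <= 0:
        raise ValueError("seed value must be positive")
    padded, offsets = _pad_geometry(v.shape, v.values)
    start = int(np.ravel_multi_index(tuple(i + 1 for i in seed.index), padded.shape))
    members = _grow_flat(padded, offsets, start)
    return {_flat_to_index(m, padded.shape) for m in members}


def segment_hotspots(v: Volume) -> list[HotSpot]:
    """Full segmentation: seeds, independent growth, common-voxel deletion.

    Hot spots whose claim-set becomes empty or loses its own seed are
    discarded (logged).  Labels are assigned in descending peak order from 1.
    """
    seeds = find_seeds(v)
    if not seeds:
        return []
    padded, offsets = _pad_geometry(v.shape, v.values)
    claims: list[list[int]] = []
    claim_count = np.zeros(padded.size, dtype=np.int32)
    for s in seeds:
        start = int(np.ravel_multi_index(tuple(i + 1 for i in s.index), padded.shape))
        members = _grow_flat(padded, offsets, start)
        claims.append(members)
        claim_count[members] += 1

    spacing = np.asarray(v.spacing_mm)
    origin = np.asarray(v.origin_mm)
    flat_vals = padded.ravel()
    spots: list[HotSpot] = []
    label = 1
    for s, members in zip(seeds, claims):
        kept = [m for m in members if claim_count[m] == 1]
        removed = len(members) - len(kept)
        seed_flat = int(np.ravel_multi_index(tuple(i + 1 for i in s.index), padded.shape))
        if not kept or claim_count[seed_flat] > 1:
            log.info("discarding hot spot seeded at %s: %s", s.index,
                     "seed was a common voxel" if kept else "claim-set emptied")
            continue
        idx = np.asarray([_flat_to_index(m, padded.shape) for m in kept], dtype=float)
        w = flat_vals[kept]
        centroid = origin + (idx * spacing).T @ w / w.sum()
        spots.append(HotSpot(
            label=label,
            seed=s,
            voxels=frozenset(_flat_to_index(m, padded.shape) for m in kept),
            peak_value=s.value,
            total_counts=float(w.sum()),
            centroid_mm=tuple(float(c) for c in centroid),
            common_voxels_removed=removed,
        ))
        label += 1
    n_adj = adjacent_pair_count(spots)
    log.info("segmented %d hot spots from %d seeds; residual adjacent voxel pairs: %d",
             len(spots), len(seeds), n_adj)
    return spots


def adjacent_pair_count(spots: list[HotSpot]) -> int:
    """Number of 26-adjacent voxel pairs belonging to two different hot spots.

    Shared voxels are deleted by construction, but remaining voxels of distinct
    regions may still touch; this reports that residual adjacency instead of
    eroding further.
    """
    owner: dict[tuple[int, int, int], int] = {}
    for sp in spots:
        for vx in sp.voxels:
            owner[vx] = sp.label
    n = 0
    for (x, y, z), lab in owner.items():
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if (dx, dy, dz) <= (0, 0, 0):
                        continue  # count each unordered pair once
                    other = owner.get((x + dx, y + dy, z + dz))
                    if other is not None and other != lab:
                        n += 1
    return n


def hotspots_to_json(spots: list[HotSpot], path: str | Path | None = None) -> str:
    """Serialise hot spots as JSON records (deterministic ordering)."""
    records = [{
        "label": sp.label,
        "seed_index": list(sp.seed.index),
        "peak_value": sp.peak_value,
        "total_counts": sp.total_counts,
        "centroid_mm": list(sp.centroid_mm),
        "n_voxels": sp.n_voxels,
        "common_voxels_removed": sp.common_voxels_removed,
    } for sp in spots]
    text = json.dumps(records, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def label_map(spots: list[HotSpot], like: Volume) -> Volume:
    """Integer label image of the segmentation, aligned with ``like``."""
    lab = np.zeros(like.shape, dtype=np.float64)
    for sp in spots:
        for vx in sp.voxels:
            lab[vx] = sp.label
    return Volume(values=lab, spacing_mm=like.spacing_mm,
                  modality=like.modality, origin_mm=like.origin_mm)
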