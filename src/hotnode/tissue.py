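"""CT tissue segmentation by Hounsfield-unit thresholds.

Every voxel of the resampled CT is assigned one of four labels — 0 air,
1 fat, 2 muscle, 3 bone — by a total partition of the HU axis into
lower-inclusive half-open intervals:

    air    HU < -200
    fat    -200 <= HU < -20
    muscle  -20 <= HU < 150
    bone          HU >= 150

Bone has no homogeneous structure on low-dose CT (trabecular gaps, marrow),
so the bone mask is regularised by a morphological closing with a ball
element; closing is extensive, so no bone voxel is ever lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import Modality, Volume

log = logging.getLogger(__name__)

__all__ = ["AIR", "FAT", "MUSCLE", "BONE", "HUThresholds", "TissueMap",
           "classify_tissue", "close_bone", "body_mask", "ball_element"]

AIR, FAT, MUSCLE, BONE = 0, 1, 2, 3
TISSUE_NAMES = {AIR: "air", FAT: "fat", MUSCLE: "muscle", BONE: "bone"}

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class HUThresholds:
    air_max: float = -200.0
    fat_max: float = -20.0
    muscle_max: float = 150.0

    def __post_init__(self) -> None:
        if not self.air_max < self.fat_max < self.muscle_max:
            raise ValueError("thresholds must be strictly increasing: air_max < fat_max < muscle_max")

    @property
    def edges(self) -> tuple[float, float, float]:
        return (self.air_max, self.fat_max, self.muscle_max)


@dataclass
class TissueMap:
    """Integer label grid {0 air, 1 fat, 2 muscle, 3 bone} on the resampled CT geometry."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    thresholds: HUThresholds
    closing_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("tissue map must be 3-D")
        if not np.isin(self.labels, (AIR, FAT, MUSCLE, BONE)).all():
            raise ValueError("labels must be in {0,1,2,3}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def counts(self) -> dict[str, int]:
        return {TISSUE_NAMES[k]: int((self.labels == k).sum()) for k in TISSUE_NAMES}


def classify_tissue(ct: Volume, t: HUThresholds = HUThresholds()) -> TissueMap:
    """Total HU partition: every real value maps to exactly one tissue label."""
    if ct.modality is not Modality.CT:
        raise ValueError("tissue classification applies to CT volumes")
    labels = np.digitize(ct.values, t.edges, right=False).astype(np.uint8)
    m = TissueMap(labels=labels, spacing_mm=ct.spacing_mm, origin_mm=ct.origin_mm,
                  thresholds=t)
    log.info("tissue composition: %s", m.counts())
    return m


def ball_element(radius_mm: float, spacing_mm) -> np.ndarray:
    """Binary ball (ellipsoid in voxel units) of the given physical radius."""
    r_vox = [max(int(np.floor(radius_mm / s)), 0) for s in spacing_mm]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in r_vox)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing_mm))
    return dist2 <= radius_mm ** 2


def close_bone(m: TissueMap, radius_mm: float = 3.0) -> TissueMap:
    """Morphological closing of the bone mask; gained voxels are relabelled bone.

    Idempotent at fixed radius and never removes bone.  A radius below the
    voxel size cannot move anything: the map is returned unchanged with a
    warning.
    """
    if radius_mm < min(m.spacing_mm):
        log.warning("closing radius %.3g mm below voxel size %s; map unchanged",
                    radius_mm, m.spacing_mm)
        return TissueMap(labels=m.labels.copy(), spacing_mm=m.spacing_mm,
                         origin_mm=m.origin_mm, thresholds=m.thresholds,
                         closing_radius_mm=radius_mm)
    bone = m.labels == BONE
    st = ball_element(radius_mm, m.spacing_mm)
    pad = [s // 2 for s in st.shape]
    padded = np.pad(bone, [(p, p) for p in pad], mode="constant")
    closed = ndimage.binary_closing(padded, structure=st)
    closed = closed[tuple(slice(p, p + n) for p, n in zip(pad, bone.shape))]
    closed |= bone  # extensivity guaranteed even in pathological border cases
    gained = int(closed.sum() - bone.sum())
    labels = m.labels.copy()
    labels[closed] = BONE
    log.info("bone closing (r=%.3g mm): +%d voxels", radius_mm, gained)
    return TissueMap(labels=labels, spacing_mm=m.spacing_mm, origin_mm=m.origin_mm,
                     thresholds=m.thresholds, closing_radius_mm=radius_mm)


def body_mask(m: TissueMap) -> np.ndarray:
    """Largest 26-connected non-air component with per-axial-slice hole filling.

    Interior air pockets (bowel gas and the like) are part of the body; lymph
    nodes cannot be extracorporal, so everything outside this mask is rejected
    downstream.
    """
    nonair = m.labels != AIR
    if not nonair.any():
        raise ValueError("no body found: tissue map is all air")
    lab, n = ndimage.label(nonair, structure=_STRUCT26)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    filled = np.empty_like(body)
    for z in range(body.shape[2]):  # axial slice = fixed z (inferior-superior axis)
        filled[:, :, z] = ndimage.binary_fill_holes(body[:, :, z])
    return filled
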