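"""Rule-based classification of hot spots into "true"/"false" lymph-node candidates.

A segmented SPECT focus is a plausible sentinel-node candidate only if its
anatomical context allows it: lymph nodes cannot lie outside the body, inside
bone, or in air, and they are embedded in fatty/connective soft tissue.  The
CT voxel values *inside* a hot spot are deliberately not used — on low-dose CT
the nodal tissue itself is not resolvable — only the tissue composition of a
thin shell around the focus is.

Each hot spot receives:

* a hard verdict: ``true`` iff ALL criteria hold (not the injection site,
  inside the body, soft-tissue shell, limited bone and air contact, minimum
  volume);
* an ordinal probability score in [0, 1] combining a SPECT index (peak value
  normalised by the global maximum) and a CT index (shell soft-tissue
  fraction) with configurable weights;
* a side (left/right of the body midline) and a drainage region (inguinal
  below a configurable axial landmark plane, secondary above it).

The dominant tracer depot at the injection site is eliminated: in ``auto``
mode the spot with maximal total counts is flagged, with a coordinate
override for operators who know the injection location.  Expert corrections
move findings between the two ranked lists and are tallied as false-positive
(true -> false) or false-negative (false -> true) corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .hotspots import HotSpot
from .imaging import Volume
from .tissue import AIR, BONE, FAT, MUSCLE, TissueMap, ball_element

log = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "Finding", "extract_features", "detect_injection_site",
           "classify", "assign_side_region", "rank_findings", "apply_expert_corrections"]

TRUE_FINDING = "true_finding"
FALSE_FINDING = "false_finding"


@dataclass(frozen=True)
class ClassifierConfig:
    shell_thickness_mm: float = 2.0
    min_soft_tissue_fraction: float = 0.5
    max_bone_fraction: float = 0.3
    max_air_fraction: float = 0.3
    injection_site_mode: str = "auto_max_activity"  # or "given_coordinate"
    injection_coordinate_mm: tuple[float, float, float] | None = None
    injection_exclusion_radius_mm: float = 30.0
    min_volume_mm3: float = 8.0
    weight_spect: float = 0.5
    weight_ct: float = 0.5
    landmark_plane_z_mm: float = 0.0
    midline_x_mm: float | str = "auto"

    def __post_init__(self) -> None:
        if self.weight_spect < 0 or self.weight_ct < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.weight_spect + self.weight_ct - 1.0) > 1e-9:
            raise ValueError("weight_spect + weight_ct must equal 1")
        for name in ("min_soft_tissue_fraction", "max_bone_fraction", "max_air_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.injection_site_mode not in ("auto_max_activity", "given_coordinate"):
            raise ValueError(f"unknown injection_site_mode {self.injection_site_mode!r}")


@dataclass
class Finding:
    hotspot: HotSpot
    verdict: str = FALSE_FINDING
    probability: float = 0.0
    side: str = ""
    region: str = ""
    features: dict[str, float] = field(default_factory=dict)
    reasons: list[str] = field(default_factory=list)

    @property
    def label(self) -> int:
        return self.hotspot.label


def _bbox_slices(voxels, shape, margin):
    arr = np.asarray(list(voxels))
    lo = np.maximum(arr.min(axis=0) - margin, 0)
    hi = np.minimum(arr.max(axis=0) + margin + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi)), lo


def extract_features(h: HotSpot, m: TissueMap, body: np.ndarray,
                     cfg: ClassifierConfig, *, spect_max: float,
                     spect_total: float) -> dict[str, float]:
    """Context features of one hot spot on the common 1 mm grid.

    The shell is the dilation of the member voxels by ``shell_thickness_mm``
    minus the members themselves, clipped to the grid; its four tissue
    fractions sum to 1.
    """
    st = ball_element(cfg.shell_thickness_mm, m.spacing_mm)
    margin = max(s // 2 for s in st.shape)
    sl, lo = _bbox_slices(h.voxels, m.shape, margin)
    mask = np.zeros(tuple(s.stop - s.start for s in sl), dtype=bool)
    for vx in h.voxels:
        mask[vx[0] - sl[0].start, vx[1] - sl[1].start, vx[2] - sl[2].start] = True
    shell = ndimage.binary_dilation(mask, structure=st) & ~mask
    n_shell = int(shell.sum())
    if n_shell == 0:
        raise ValueError(f"hot spot {h.label} fills the grid: empty shell")
    sub_labels = m.labels[sl][shell]
    frac = {name: float((sub_labels == k).sum()) / n_shell
            for k, name in ((AIR, "shell_air"), (FAT, "shell_fat"),
                            (MUSCLE, "shell_muscle"), (BONE, "shell_bone"))}
    inside = float(body[sl][mask].sum()) / mask.sum()
    voxel_vol = float(np.prod(m.spacing_mm))
    return {
        **frac,
        "inside_body_fraction": inside,
        "normalized_peak": float(h.peak_value / spect_max) if spect_max > 0 else 0.0,
        "counts_fraction": float(h.total_counts / spect_total) if spect_total > 0 else 0.0,
        "volume_mm3": len(h.voxels) * voxel_vol,
    }


def detect_injection_site(spots: list[HotSpot], cfg: ClassifierConfig) -> set[int]:
    """Labels of hot spots attributed to the tracer application site.

    auto mode: the single spot with maximal total counts (the depot dominates
    every node's uptake).  given_coordinate mode: every spot whose centroid
    lies within the exclusion radius of the supplied coordinate.
    """
    if not spots:
        return set()
    if cfg.injection_site_mode == "auto_max_activity":
        best = max(spots, key=lambda s: (s.total_counts, -s.label))
        ties = [s.label for s in spots
                if s.total_counts == best.total_counts and s.label != best.label]
        if ties:
            log.info("injection-site tie on total counts; choosing label %d over %s",
                     best.label, ties)
        return {best.label}
    if cfg.injection_coordinate_mm is None:
        raise ValueError("injection_site_mode=given_coordinate requires injection_coordinate_mm")
    c = np.asarray(cfg.injection_coordinate_mm)
    return {s.label for s in spots
            if np.linalg.norm(np.asarray(s.centroid_mm) - c) <= cfg.injection_exclusion_radius_mm}


def classify(spots: list[HotSpot], m: TissueMap, body: np.ndarray,
             cfg: ClassifierConfig, spect: Volume) -> list[Finding]:
    """Verdict + probability for every hot spot; no spot is dropped.

    Hard criteria for a true finding (all must hold): not the injection site;
    inside-body fraction >= 0.5; shell fat+muscle >= min_soft_tissue_fraction;
    shell bone <= max_bone_fraction; shell air <= max_air_fraction;
    volume >= min_volume_mm3.
    """
    injection = detect_injection_site(spots, cfg)
    spect_max = float(spect.values.max())
    spect_total = float(spect.values.sum())
    findings = []
    for h in spots:
        feats = extract_features(h, m, body, cfg, spect_max=spect_max,
                                 spect_total=spect_total)
        soft = feats["shell_fat"] + feats["shell_muscle"]
        reasons = []
        if h.label in injection:
            reasons.append("injection_site")
        if feats["inside_body_fraction"] < 0.5:
            reasons.append("extracorporal")
        if soft < cfg.min_soft_tissue_fraction:
            reasons.append("low_soft_tissue")
        if feats["shell_bone"] > cfg.max_bone_fraction:
            reasons.append("bone_context")
        if feats["shell_air"] > cfg.max_air_fraction:
            reasons.append("air_context")
        if feats["volume_mm3"] < cfg.min_volume_mm3:
            reasons.append("below_min_volume")
        feats["injection_site_flag"] = float(h.label in injection)
        prob = cfg.weight_spect * feats["normalized_peak"] + cfg.weight_ct * soft
        findings.append(Finding(
            hotspot=h,
            verdict=TRUE_FINDING if not reasons else FALSE_FINDING,
            probability=float(np.clip(prob, 0.0, 1.0)),
            features=feats,
            reasons=reasons,
        ))
    return findings


def assign_side_region(f: Finding, body: np.ndarray, cfg: ClassifierConfig,
                       spacing_mm=None, origin_mm=None) -> Finding:
    """Left/right of the midline and inguinal/secondary territory of one finding.

    Auto midline = body-mask centroid x (needs ``spacing_mm``/``origin_mm`` of
    the grid); patient-left is increasing x, so side is left iff centroid
    x > midline (exact tie -> right, logged).  Region is inguinal iff the
    centroid lies below (smaller z than) the landmark plane.
    """
    if cfg.midline_x_mm == "auto":
        if spacing_mm is None or origin_mm is None:
            raise ValueError("auto midline requires the grid geometry")
        xs = np.nonzero(body)[0]
        midline = float(origin_mm[0] + xs.mean() * spacing_mm[0])
    else:
        midline = float(cfg.midline_x_mm)
    cx, _, cz = f.hotspot.centroid_mm
    if cx == midline:
        log.info("finding %d centred exactly on the midline; assigning right", f.label)
    side = "left" if cx > midline else "right"
    region = "inguinal" if cz < cfg.landmark_plane_z_mm else "secondary"
    return replace(f, side=side, region=region)


def rank_findings(findings: list[Finding]) -> tuple[list[Finding], list[Finding]]:
    """The two probability-ordered lists offered for expert perusal.

    True findings descend by probability (best candidate first); false
    findings ascend (most confidently false first).  Ties break by descending
    peak, then label.  Every finding lands in exactly one list.
    """
    true_list = [f for f in findings if f.verdict == TRUE_FINDING]
    false_list = [f for f in findings if f.verdict == FALSE_FINDING]
    true_list.sort(key=lambda f: (-f.probability, -f.hotspot.peak_value, f.label))
    false_list.sort(key=lambda f: (f.probability, -f.hotspot.peak_value, f.label))
    return true_list, false_list


def apply_expert_corrections(lists: tuple[list[Finding], list[Finding]],
                             moves: list[tuple[int, str]],
                             ) -> tuple[tuple[list[Finding], list[Finding]], dict[str, int]]:
    """Move findings between the lists as directed by the expert.

    A true -> false move is a false-positive correction of the program, a
    false -> true move a false-negative correction.  Unknown labels raise;
    moving a finding to the list it is already in is a logged no-op.
    Returns the corrected lists (re-ranked) and the move tallies.
    """
    true_list, false_list = (list(lists[0]), list(lists[1]))
    by_label = {f.label: f for f in true_list + false_list}
    if len(by_label) != len(true_list) + len(false_list):
        raise ValueError("finding labels are not unique across the lists")
    tally = {"fp_corrections": 0, "fn_corrections": 0, "noop": 0}
    for label, target in moves:
        if target not in ("true", "false"):
            raise ValueError(f"move target must be 'true' or 'false', got {target!r}")
        if label not in by_label:
            raise KeyError(f"unknown finding label {label}")
        f = by_label[label]
        in_true = any(g.label == label for g in true_list)
        if (target == "true") == in_true:
            log.warning("move of finding %d to %r is a no-op", label, target)
            tally["noop"] += 1
            continue
        if in_true:
            true_list = [g for g in true_list if g.label != label]
            false_list.append(replace(f, verdict=FALSE_FINDING))
            tally["fp_corrections"] += 1
        else:
            false_list = [g for g in false_list if g.label != label]
            true_list.append(replace(f, verdict=TRUE_FINDING))
            tally["fn_corrections"] += 1
        by_label[label] = replace(f, verdict=TRUE_FINDING if target == "true" else FALSE_FINDING)
    return rank_findings([*true_list, *false_list]), tally
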