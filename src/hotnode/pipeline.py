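"""End-to-end detection pipeline: paired volumes in, ranked finding lists out.

Stage order: resample both modalities to the common 1 mm grid, suppress the
SPECT background, segment hot spots, classify CT tissue, close the bone mask,
build the body mask, classify and localise every hot spot, rank the two
lists.  The background threshold may optionally be applied before resampling
instead (``suppress_before_resample``); both orders are supported because the
native-resolution counts and the interpolated counts give slightly different
noise floors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .classify import (Finding, assign_side_region, classify, rank_findings)
from .config import RunConfig
from .hotspots import HotSpot, label_map, segment_hotspots
from .imaging import Modality, Volume, resample, save_volume, suppress_background
from .tissue import TissueMap, body_mask, classify_tissue, close_bone

log = logging.getLogger(__name__)

__all__ = ["DetectResult", "run_detect", "findings_to_json", "lists_from_json"]


@dataclass
class DetectResult:
    spect: Volume           # resampled, background-suppressed
    tissue: TissueMap       # after bone closing
    body: np.ndarray
    hotspots: list[HotSpot]
    findings: list[Finding]
    true_list: list[Finding]
    false_list: list[Finding]
    config_sha256: str


def _crop_to_common(a: Volume, b: Volume) -> tuple[Volume, Volume]:
    """Crop two co-registered grids to their shared shape (origins must agree)."""
    if not np.allclose(a.origin_mm, b.origin_mm, atol=1e-6):
        log.warning("resampled origins differ: %s vs %s", a.origin_mm, b.origin_mm)
    shape = tuple(min(x, y) for x, y in zip(a.shape, b.shape))
    if shape != a.shape or shape != b.shape:
        log.info("cropping to common grid %s (had %s and %s)", shape, a.shape, b.shape)
    sl = tuple(slice(0, n) for n in shape)

    def crop(v: Volume) -> Volume:
        return Volume(values=v.values[sl], spacing_mm=v.spacing_mm,
                      modality=v.modality, origin_mm=v.origin_mm)

    return crop(a), crop(b)


def run_detect(ct: Volume, spect: Volume, cfg: RunConfig) -> DetectResult:
    """Execute the full assessment workflow on an in-memory volume pair."""
    if ct.modality is not Modality.CT or spect.modality is not Modality.SPECT:
        raise ValueError("run_detect needs one CT and one SPECT volume")
    if cfg.suppress_before_resample:
        spect = suppress_background(spect, cfg.background)
    spect_r = resample(spect, cfg.resample)
    ct_r = resample(ct, cfg.resample)
    spect_r, ct_r = _crop_to_common(spect_r, ct_r)
    if not cfg.suppress_before_resample:
        spect_r = suppress_background(spect_r, cfg.background)
    spots = segment_hotspots(spect_r)
    tmap = classify_tissue(ct_r, cfg.hu_thresholds)
    tmap = close_bone(tmap, cfg.closing_radius_mm)
    body = body_mask(tmap)
    findings = classify(spots, tmap, body, cfg.classifier, spect_r)
    findings = [assign_side_region(f, body, cfg.classifier,
                                   spacing_mm=tmap.spacing_mm, origin_mm=tmap.origin_mm)
                for f in findings]
    true_list, false_list = rank_findings(findings)
    return DetectResult(spect=spect_r, tissue=tmap, body=body, hotspots=spots,
                        findings=findings, true_list=true_list, false_list=false_list,
                        config_sha256=cfg.sha256())


def _finding_record(f: Finding) -> dict:
    return {
        "label": f.label,
        "verdict": f.verdict,
        "probability": f.probability,
        "side": f.side,
        "region": f.region,
        "centroid_mm": list(f.hotspot.centroid_mm),
        "seed_index": list(f.hotspot.seed.index),
        "peak_value": f.hotspot.peak_value,
        "total_counts": f.hotspot.total_counts,
        "n_voxels": f.hotspot.n_voxels,
        "features": {k: float(v) for k, v in sorted(f.features.items())},
        "reasons": list(f.reasons),
    }


def findings_to_json(result: DetectResult, path: str | Path | None = None,
                     seed: int | None = None) -> str:
    """Deterministic JSON of the two ranked lists plus a provenance block."""
    doc = {
        "provenance": {
            "package": "hotnode",
            "version": __version__,
            "config_sha256": result.config_sha256,
            "seed": seed,
        },
        "n_hotspots": len(result.hotspots),
        "true_findings": [_finding_record(f) for f in result.true_list],
        "false_findings": [_finding_record(f) for f in result.false_list],
    }
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def lists_from_json(path: str | Path) -> tuple[list[int], list[int]]:
    """Label lists (true, false) from a findings JSON file."""
    doc = json.loads(Path(path).read_text())
    return ([f["label"] for f in doc["true_findings"]],
            [f["label"] for f in doc["false_findings"]])


def write_label_map(result: DetectResult, path: str | Path) -> None:
    save_volume(label_map(result.hotspots, result.spect), path)
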