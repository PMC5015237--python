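"""Seeded synthetic SPECT/CT phantom pairs with ground truth.

The phantom emulates the statistical structure the detector assumes, not
anatomy: an ellipsoidal body (fat shell over a muscle core) in air, a pelvis
surrogate of bone cylinders, an interior air pocket (bowel gas), one dominant
tracer depot at the injection site, and a handful of small tracer-avid nodes
at known positions in soft tissue.  Decoy activity foci can be planted inside
bone, outside the body, or against the air pocket to exercise the anatomical
exclusion rules.

SPECT formation: point activities are placed on the 1 mm grid and convolved
with a Gaussian point-spread function (system FWHM, default 8 mm).  The
injection site is additionally spread by a depot sigma — a peritumoral
intradermal depot is physically extended, not a point — which sets the ratio
between the global maximum and the node peaks and hence what survives the
1 %-of-maximum background threshold.  Optional Poisson sampling adds counting
noise.  CT formation: tissue-class HU centres (air -1000, fat -100, muscle
40, bone 700) plus Gaussian HU noise.

A single integer seed fixes all randomness.  Sub-streams are spawned per
purpose (node placement jitter, activity fractions, CT noise, Poisson) in a
documented order, so switching one stochastic element off does not perturb
the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging import Modality, Volume

log = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "TruthNode", "PhantomTruth", "generate", "degrade_to_native"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

HU_AIR, HU_FAT, HU_MUSCLE, HU_BONE = -1000.0, -100.0, 40.0, 700.0

# Canonical node sites (mm, 1 mm grid of shape 96x96x128, body centre (48,48,64)):
# right/left inguinal, left iliac, para-aortic, right iliac.  Pairwise
# separations exceed 24 mm even after +/-2 mm placement jitter, and every site
# lies >= 30 mm from the injection depot: the depot's above-threshold footprint
# (~22 mm radius at the default activity ratio) plus one PSF FWHM.  A node on
# the depot's flank closer than that has no local maximum of its own and is
# absorbed into the depot spot — the method's stated resolution limit.
_CANONICAL_SITES = (
    (30.0, 48.0, 38.0),
    (66.0, 48.0, 38.0),
    (58.0, 44.0, 80.0),
    (44.0, 48.0, 100.0),
    (34.0, 40.0, 74.0),
)

_DEFAULT_DECOYS = (
    {"kind": "bone_embedded", "position_mm": (48.0, 62.0, 80.0), "activity_fraction": 0.004},
    {"kind": "extracorporal", "position_mm": (12.0, 14.0, 64.0), "activity_fraction": 0.004},
    {"kind": "air_adjacent", "position_mm": (48.0, 40.0, 63.0), "activity_fraction": 0.004},
)


@dataclass(frozen=True)
class PhantomSpec:
    """All dials of the generator; defaults are the study conditions of the tests."""

    grid_shape: tuple[int, int, int] = (96, 96, 128)  # at 1 mm
    body_semiaxes_mm: tuple[float, float, float] = (42.0, 34.0, 62.0)
    fat_shell_mm: float = 10.0
    n_nodes: int = 4
    node_positions: tuple | str | None = None  # None -> canonical sites + jitter
    node_activity_fractions: tuple | None = None  # None -> uniform in [0.003, 0.02]
    injection_position_mm: tuple[float, float, float] = (48.0, 42.0, 14.0)
    injection_activity: float = 1.0e6
    injection_sigma_mm: float = 6.0  # depot extent before PSF blur
    psf_fwhm_mm: float = 8.0
    poisson_noise: bool = True
    ct_noise_sd_hu: float = 20.0
    decoys: tuple = _DEFAULT_DECOYS
    air_pocket: tuple[float, float, float, float] | None = (48.0, 40.0, 70.0, 8.0)  # (x,y,z,r)
    bone_cylinders: tuple = (  # (cx, cy, r, z0, z1): spine + two femur surrogates
        (48.0, 62.0, 8.0, 70.0, 112.0),
        (20.0, 48.0, 6.0, 8.0, 44.0),
        (76.0, 48.0, 6.0, 8.0, 44.0),
    )
    landmark_plane_z_mm: float = 56.0
    jitter_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("phantom grid must be at least 16 voxels per axis")
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        if self.node_activity_fractions is not None:
            fr = self.node_activity_fractions
            if len(fr) != self.n_nodes:
                raise ValueError("need one activity fraction per node")
            if any(not 0.001 <= f <= 0.02 for f in fr):
                raise ValueError("node activity fractions must lie in [0.001, 0.02]")

    @property
    def body_center_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) / 2.0 for n in self.grid_shape)

    @property
    def midline_x_mm(self) -> float:
        return self.body_center_mm[0]


@dataclass(frozen=True)
class TruthNode:
    position_mm: tuple[float, float, float]
    activity_fraction: float
    side: str
    region: str
    is_decoy: bool = False
    kind: str = "node"


@dataclass(frozen=True)
class PhantomTruth:
    nodes: tuple[TruthNode, ...]
    decoys: tuple[TruthNode, ...]
    injection_position_mm: tuple[float, float, float]
    landmark_plane_z_mm: float
    midline_x_mm: float

    def to_json(self, path: str | Path | None = None) -> str:
        rec = {
            "nodes": [n.__dict__ for n in self.nodes],
            "decoys": [n.__dict__ for n in self.decoys],
            "injection_position_mm": list(self.injection_position_mm),
            "landmark_plane_z_mm": self.landmark_plane_z_mm,
            "midline_x_mm": self.midline_x_mm,
        }
        text = json.dumps(rec, indent=2, sort_keys=True, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        rec = json.loads(Path(path).read_text())
        return cls(
            nodes=tuple(TruthNode(**{**n, "position_mm": tuple(n["position_mm"])})
                        for n in rec["nodes"]),
            decoys=tuple(TruthNode(**{**n, "position_mm": tuple(n["position_mm"])})
                         for n in rec["decoys"]),
            injection_position_mm=tuple(rec["injection_position_mm"]),
            landmark_plane_z_mm=rec["landmark_plane_z_mm"],
            midline_x_mm=rec["midline_x_mm"],
        )


def _ellipsoid(shape, center, semiaxes):
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    return sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes)) <= 1.0


def _inside_body(pos, spec: PhantomSpec) -> bool:
    return sum(((p - c) / a) ** 2 for p, c, a in
               zip(pos, spec.body_center_mm, spec.body_semiaxes_mm)) <= 1.0


def _truth_side_region(pos, spec: PhantomSpec) -> tuple[str, str]:
    side = "left" if pos[0] > spec.midline_x_mm else "right"
    region = "inguinal" if pos[2] < spec.landmark_plane_z_mm else "secondary"
    return side, region


def _node_positions(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    if spec.node_positions is not None and spec.node_positions != "random":
        pos = [tuple(float(x) for x in p) for p in spec.node_positions]
        if len(pos) != spec.n_nodes:
            raise ValueError("need one position per node")
        return pos
    if spec.node_positions == "random":
        return _sample_positions(spec, rng)
    if spec.n_nodes > len(_CANONICAL_SITES):
        raise ValueError(
            f"only {len(_CANONICAL_SITES)} canonical sites; pass explicit "
            f"node_positions or 'random' for n_nodes={spec.n_nodes}")
    out = []
    for site in _CANONICAL_SITES[:spec.n_nodes]:
        jit = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
        out.append(tuple(float(s + j) for s, j in zip(site, jit)))
    return out


def _sample_positions(spec: PhantomSpec, rng: np.random.Generator,
                      min_separation_mm: float = 25.0,
                      max_tries: int = 5000) -> list[tuple[float, float, float]]:
    """Rejection-sample node sites in the muscle core, well separated."""
    center = np.asarray(spec.body_center_mm)
    inner = np.asarray(spec.body_semiaxes_mm) - spec.fat_shell_mm - 4.0
    placed: list[np.ndarray] = []
    inj = np.asarray(spec.injection_position_mm)
    for _ in range(max_tries):
        if len(placed) == spec.n_nodes:
            break
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u ** 2).sum() > 1.0:
            continue
        p = center + u * inner
        if np.linalg.norm(p - inj) < 30.0:
            continue
        if any(np.linalg.norm(p - q) < min_separation_mm for q in placed):
            continue
        if _near_bone_or_air(p, spec, margin_mm=10.0):
            continue
        placed.append(p)
    if len(placed) < spec.n_nodes:
        raise ValueError("could not place all nodes with the separation constraints")
    return [tuple(float(x) for x in p) for p in placed]


def _near_bone_or_air(p, spec: PhantomSpec, margin_mm: float) -> bool:
    for cx, cy, r, z0, z1 in spec.bone_cylinders:
        if z0 - margin_mm <= p[2] <= z1 + margin_mm and \
                np.hypot(p[0] - cx, p[1] - cy) <= r + margin_mm:
            return True
    if spec.air_pocket is not None:
        ax, ay, az, ar = spec.air_pocket
        if np.linalg.norm(np.asarray(p) - (ax, ay, az)) <= ar + margin_mm:
            return True
    return False


def _build_ct(spec: PhantomSpec, rng: np.random.Generator) -> Volume:
    shape = spec.grid_shape
    center = spec.body_center_mm
    hu = np.full(shape, HU_AIR, dtype=np.float64)
    body = _ellipsoid(shape, center, spec.body_semiaxes_mm)
    inner_axes = tuple(max(a - spec.fat_shell_mm, 1.0) for a in spec.body_semiaxes_mm)
    inner = _ellipsoid(shape, center, inner_axes)
    hu[body] = HU_FAT
    hu[inner] = HU_MUSCLE
    xg, yg, zg = np.ogrid[tuple(slice(0, n) for n in shape)]
    for cx, cy, r, z0, z1 in spec.bone_cylinders:
        cyl = (((xg - cx) ** 2 + (yg - cy) ** 2) <= r ** 2) & (zg >= z0) & (zg <= z1)
        hu[cyl & body] = HU_BONE
    if spec.air_pocket is not None:
        ax, ay, az, ar = spec.air_pocket
        pocket = _ellipsoid(shape, (ax, ay, az), (ar, ar, ar))
        hu[pocket & body] = HU_AIR
    if spec.ct_noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.ct_noise_sd_hu, size=shape)
    return Volume(values=hu, spacing_mm=(1.0, 1.0, 1.0), modality=Modality.CT)


def _place_delta(grid: np.ndarray, pos, activity: float) -> None:
    idx = tuple(int(np.clip(round(p), 0, n - 1)) for p, n in zip(pos, grid.shape))
    grid[idx] += activity


def generate(spec: PhantomSpec) -> tuple[Volume, Volume, PhantomTruth]:
    """Build the (CT, SPECT, truth) triple on the 1 mm grid.

    Stream order of the spawned RNG children: 0 node placement, 1 activity
    fractions, 2 CT noise, 3 Poisson sampling.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_frac, rng_ct, rng_poisson = (np.random.default_rng(c)
                                                for c in ss.spawn(4))
    positions = _node_positions(spec, rng_place)
    for p in positions:
        if not _inside_body(p, spec):
            raise ValueError(f"node at {p} lies outside the phantom body")
    if not _inside_body(spec.injection_position_mm, spec):
        raise ValueError("injection position lies outside the phantom body")

    if spec.node_activity_fractions is not None:
        fractions = [float(f) for f in spec.node_activity_fractions]
    else:
        fractions = [float(f) for f in rng_frac.uniform(0.003, 0.02, size=spec.n_nodes)]
    if fractions and max(fractions) > 0.2:
        raise ValueError("injection must dominate every node's activity by >= 5x")

    sigma_psf = spec.psf_fwhm_mm * _FWHM_TO_SIGMA  # voxels == mm on this grid
    shape = spec.grid_shape
    A = spec.injection_activity

    focal = np.zeros(shape, dtype=np.float64)
    for p, f in zip(positions, fractions):
        _place_delta(focal, p, f * A)
    for d in spec.decoys:
        _place_delta(focal, d["position_mm"], float(d["activity_fraction"]) * A)
    spect = ndimage.gaussian_filter(focal, sigma_psf, mode="reflect", truncate=5.0)

    depot = np.zeros(shape, dtype=np.float64)
    _place_delta(depot, spec.injection_position_mm, A)
    sigma_inj = float(np.hypot(sigma_psf, spec.injection_sigma_mm))
    spect += ndimage.gaussian_filter(depot, sigma_inj, mode="reflect", truncate=5.0)

    if spec.poisson_noise:
        spect = rng_poisson.poisson(spect).astype(np.float64)

    ct = _build_ct(spec, rng_ct)
    spect_vol = Volume(values=spect, spacing_mm=(1.0, 1.0, 1.0), modality=Modality.SPECT)

    nodes = []
    for p, f in zip(positions, fractions):
        side, region = _truth_side_region(p, spec)
        nodes.append(TruthNode(position_mm=p, activity_fraction=f, side=side, region=region))
    nodes = tuple(nodes)
    decoys = tuple(TruthNode(position_mm=tuple(float(x) for x in d["position_mm"]),
                             activity_fraction=float(d["activity_fraction"]),
                             side=_truth_side_region(d["position_mm"], spec)[0],
                             region=_truth_side_region(d["position_mm"], spec)[1],
                             is_decoy=True, kind=str(d["kind"]))
                   for d in spec.decoys)
    truth = PhantomTruth(nodes=nodes, decoys=decoys,
                         injection_position_mm=tuple(float(x) for x in spec.injection_position_mm),
                         landmark_plane_z_mm=spec.landmark_plane_z_mm,
                         midline_x_mm=spec.midline_x_mm)
    log.info("phantom seed=%d: %d nodes, %d decoys, total counts %.4g",
             spec.seed, len(nodes), len(decoys), float(spect.sum()))
    return ct, spect_vol, truth


def _block_mean(a: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Mean over non-overlapping blocks; trailing partial blocks average what exists."""
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        n = a.shape[ax]
        idx = np.arange(0, n, f)
        sums = np.add.reduceat(a, idx, axis=ax)
        counts = np.diff(np.append(idx, n)).astype(np.float64)
        shape = [1] * a.ndim
        shape[ax] = -1
        a = sums / counts.reshape(shape)
    return a


def degrade_to_native(ct: Volume, spect: Volume,
                      spect_block: tuple[int, int, int] = (4, 4, 4),
                      ct_block: tuple[int, int, int] = (1, 1, 5),
                      ) -> tuple[Volume, Volume]:
    """Block-average the 1 mm phantoms down to the native scanner lattices.

    Default blocks reproduce the acquisition geometry: SPECT 4x4x4 mm, CT
    1x1x5 mm.  Block means times block volume conserve the grid integral, so
    the pipeline's resampling step is exercised end to end.
    """
    def down(v: Volume, block) -> Volume:
        vals = _block_mean(v.values, block)
        spacing = tuple(s * b for s, b in zip(v.spacing_mm, block))
        origin = tuple(o + (b - 1) / 2.0 * s
                       for o, s, b in zip(v.origin_mm, v.spacing_mm, block))
        return Volume(values=vals, spacing_mm=spacing, modality=v.modality,
                      origin_mm=origin)

    return down(ct, ct_block), down(spect, spect_block)
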