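"""Independent brute-force oracles for the segmentation contracts.

These deliberately avoid the implementation's mechanics: seeds by exhaustive
neighbourhood comparison, claim-sets by a monotone-path fixpoint closure, and
segmentation by claim overlap deletion.  Only usable on small grids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def brute_seeds(vals: np.ndarray) -> list[tuple[tuple[int, int, int], float]]:
    """Exhaustive scan: every voxel >= all in-bounds 26-neighbours and > 0,
    reduced to one representative (lexicographically smallest) per connected
    equal-valued plateau."""
    nx, ny, nz = vals.shape
    cands = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = vals[x, y, z]
                if v <= 0:
                    continue
                ok = True
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            p, q, r = x + dx, y + dy, z + dz
                            if 0 <= p < nx and 0 <= q < ny and 0 <= r < nz \
                                    and vals[p, q, r] > v:
                                ok = False
                if ok:
                    cands.append((x, y, z))
    # plateau reduction: adjacent candidates are equal-valued by construction
    cand_set = set(cands)
    seen, reps = set(), []
    for c in sorted(cands):
        if c in seen:
            continue
        comp, stack = [], [c]
        seen.add(c)
        while stack:
            u = stack.pop()
            comp.append(u)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        n = (u[0] + dx, u[1] + dy, u[2] + dz)
                        if n in cand_set and n not in seen and vals[n] == vals[u]:
                            seen.add(n)
                            stack.append(n)
        reps.append(min(comp))
    reps.sort(key=lambda i: (-vals[i], i))
    return [(i, float(vals[i])) for i in reps]


def claim_closure(vals: np.ndarray, seed: tuple[int, int, int]) -> frozenset:
    """Fixpoint of: add voxel n if some already-claimed neighbour c has
    value(c) >= value(n) > 0.  Equals monotone-path reachability from the seed."""
    mask = np.zeros(vals.shape, dtype=bool)
    mask[seed] = True
    while True:
        masked = np.where(mask, vals, -np.inf)
        nbr_max = ndimage.maximum_filter(masked, size=3, mode="constant", cval=-np.inf)
        add = (vals > 0) & (vals <= nbr_max) & ~mask
        if not add.any():
            break
        mask |= add
    return frozenset(map(tuple, np.argwhere(mask)))


def segment_closure(vals: np.ndarray) -> list[frozenset]:
    """Brute-force segmentation: per-seed closures, then shared-voxel deletion.

    Returns the surviving regions (seed kept, non-empty) in the same
    descending-peak order the implementation uses.
    """
    seeds = brute_seeds(vals)
    claims = [claim_closure(vals, s) for s, _ in seeds]
    counts: dict[tuple, int] = {}
    for cl in claims:
        for vx in cl:
            counts[vx] = counts.get(vx, 0) + 1
    out = []
    for (s, _), cl in zip(seeds, claims):
        kept = frozenset(vx for vx in cl if counts[vx] == 1)
        if kept and s in kept:
            out.append(kept)
    return out
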