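"""Brute-force re-implementations used as independent oracles.

Everything here works voxel-by-voxel from the definitions, with explicit
neighbor loops and set algebra — deliberately naive and independent of the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

FACE = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
ALL26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
EDGE18 = [o for o in ALL26 if sum(abs(v) for v in o) <= 2]


def offsets(connectivity: int):
    return {6: FACE, 18: EDGE18, 26: ALL26}[connectivity]


def _inside(v, shape):
    return all(0 <= c < n for c, n in zip(v, shape))


def bf_surface_voxels(mask: np.ndarray) -> set[tuple[int, int, int]]:
    """Mask voxels with a face neighbor outside the mask (or off-grid)."""
    out = set()
    for v in map(tuple, np.argwhere(mask)):
        for d in FACE:
            n = tuple(a + b for a, b in zip(v, d))
            if not _inside(n, mask.shape) or not mask[n]:
                out.add(v)
                break
    return out


def bf_shell(mask: np.ndarray, connectivity: int = 6) -> set:
    """Background voxels adjacent (given connectivity) to a surface voxel,
    clipped at the grid boundary."""
    out = set()
    for v in bf_surface_voxels(mask):
        for d in offsets(connectivity):
            n = tuple(a + b for a, b in zip(v, d))
            if _inside(n, mask.shape) and not mask[n]:
                out.add(n)
    return out


def bf_overlap(primary: np.ndarray, secondary: np.ndarray,
               connectivity: int = 6) -> set:
    return bf_shell(primary, connectivity) & bf_surface_voxels(secondary)


def bf_sites(overlap: set) -> list[set]:
    """26-connected components of an overlap voxel set (BFS)."""
    remaining = set(overlap)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for d in ALL26:
                n = tuple(a + b for a, b in zip(v, d))
                if n in remaining:
                    remaining.remove(n)
                    comp.add(n)
                    frontier.append(n)
        comps.append(comp)
    return comps


def mask_to_set(mask: np.ndarray) -> set:
    return set(map(tuple, np.argwhere(mask)))


def random_blob(rng: np.random.Generator, shape=(24, 24, 24),
                n_seeds: int = 3, radius_range=(2, 5)) -> np.ndarray:
    """Random union of digitized balls — an irregular connected-ish blob."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    mask = np.zeros(shape, dtype=bool)
    c0 = rng.integers(6, np.array(shape) - 6)
    for _ in range(n_seeds):
        c = c0 + rng.integers(-3, 4, size=3)
        r = int(rng.integers(*radius_range))
        mask |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r * r
    return mask


def adjacent_blob_pair(rng: np.random.Generator, shape=(26, 26, 26)):
    """Two disjoint blobs, the second slid along +y until face-adjacent
    (brute-force scan entirely within this module)."""
    for _ in range(100):
        a = random_blob(rng, shape)
        b0 = random_blob(rng, shape)
        if not a.any() or not b0.any():
            continue
        for shift in range(shape[1]):
            b = np.zeros_like(b0)
            if shift:
                b[:, shift:, :] = b0[:, :-shift, :]
            else:
                b = b0.copy()
            if not b.any():
                break
            if (a & b).any():
                continue
            # face adjacency?
            adjacent = False
            for v in map(tuple, np.argwhere(b)):
                for d in FACE:
                    n = tuple(p + q for p, q in zip(v, d))
                    if _inside(n, a.shape) and a[n]:
                        adjacent = True
                        break
                if adjacent:
                    break
            if adjacent:
                return a, b
            if shift > 0:
                break  # separated without touching: try new blobs
    raise RuntimeError("could not build an adjacent blob pair")
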