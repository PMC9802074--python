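"""Synthetic labeled mesophyll-cell volumes with known ground truth.

Each generated cell is an ellipsoidal volume containing a central
(super-ellipsoidal) vacuole, one nucleus, a peripheral layer of oblate
chloroplasts tangent to the cell surface, spherical-to-ellipsoidal
peroxisomes and tubular, optionally branched mitochondria — the layout in
which chloroplasts and the vacuole dominate the cell interior and the small
organelles sit between chloroplasts and the vacuole or cell surface.

The generator's central guarantee is a *controlled contact design*: every
peroxisome and mitochondrion is drawn to be Alone, in a binary complex, or
part of a chloroplast-anchored ternary complex, and placement enforces that
face adjacency (which is exactly what the 6-connected voxel-shell detector
reports) exists between designed partners and nowhere else. Ground truth
therefore predicts the downstream contact table voxel-for-voxel at the
partner level.

Default presets encode the dark/light study conditions: per-condition
organelle count ranges, alone/ternary fractions taken from the published
population percentages, larger peroxisomes, shorter and less branched
mitochondria, and larger per-site proximity-area targets in the light.
The default grid is a scaled-down cell (~1/2 linear scale; organelle counts
kept realistic, organelle sizes shrunk accordingly) — all analysis code is
resolution-independent.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .contact import shell, surface_voxels
from .io import (
    CELL_BACKGROUND,
    CHLOROPLAST,
    MITOCHONDRION,
    NUCLEUS,
    PEROXISOME,
    VACUOLE,
    LabelVolume,
)

_FACE = ndimage.generate_binary_structure(3, 1)

CONDITIONS = ("dark", "light")

#: Published per-condition organelle count ranges (instances per cell).
COUNT_RANGES = {
    "dark": {CHLOROPLAST: (15, 22), PEROXISOME: (9, 13), MITOCHONDRION: (34, 45)},
    "light": {CHLOROPLAST: (17, 21), PEROXISOME: (11, 16), MITOCHONDRION: (36, 51)},
}


class PlacementError(RuntimeError):
    """Raised when an organelle cannot be placed within the attempt budget."""


@dataclass
class SynthSpec:
    """Full parameterization of one synthetic cell.

    Sizes are physical (um); the grid is (nz, ny, nx) with spacing
    (dz, dy, dx) in nm. ``frac_alone`` is the per-class probability that an
    organelle is placed contact-free; ``frac_ternary`` the probability that
    a (non-Alone) chloroplast anchors a ternary complex.
    ``site_area_vox`` is the per-designed-contact overlap-voxel target the
    placement "wrap" step grows toward. ``contact_gap_vox`` 0 places
    designed partners face-adjacent (detectable); 1 leaves a one-voxel gap
    (beyond the 6-connected shell reach).
    """

    condition: str = "dark"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (56, 176, 176)
    spacing_nm: tuple[float, float, float] = (100.0, 50.0, 50.0)
    count_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(COUNT_RANGES["dark"])
    )
    frac_alone: dict[str, float] = field(
        default_factory=lambda: {CHLOROPLAST: 0.096, PEROXISOME: 0.226,
                                 MITOCHONDRION: 0.347}
    )
    frac_ternary: float = 0.33
    contact_gap_vox: int = 0
    site_area_vox: int = 30
    #: probability a binary (non-ternary) chloroplast's partner is a
    #: mitochondrion rather than a peroxisome
    binary_partner_mito_p: float = 0.9
    cell_semiaxes_um: tuple[float, float, float] = (2.6, 4.2, 4.2)
    #: per-cell uniform scale jitter applied to the cell (and chloroplast
    #: radii), emulating cell-to-cell size variation; chloroplast volume
    #: then tracks cell volume, as observed in real cells
    cell_scale_range: tuple[float, float] = (0.84, 1.02)
    #: cap region for the vacuole; the vacuole fills this region's
    #: intersection with the cell interior minus a one-voxel moat around
    #: every organelle (plant vacuoles fill whatever space is left)
    vacuole_semiaxes_um: tuple[float, float, float] = (2.4, 4.0, 4.0)
    vacuole_exponent: float = 4.0
    #: cytoplasm margin (voxels of 6-connected erosion) kept between the
    #: vacuole and the plasma membrane
    vacuole_wall_margin_vox: int = 2
    nucleus_semiaxes_um: tuple[float, float, float] = (0.7, 1.0, 1.0)
    chl_radius_um: tuple[float, float] = (1.0, 1.12)
    chl_flattening: tuple[float, float] = (0.53, 0.62)
    per_radius_um: tuple[float, float] = (0.22, 0.34)
    mito_radius_um: tuple[float, float] = (0.15, 0.17)
    mito_length_um: tuple[float, float] = (1.2, 2.4)
    mito_branch_p: float = 0.5
    max_attempts: int = 1000
    wrap_max_iters: int = 14

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.contact_gap_vox not in (0, 1):
            raise ValueError("contact_gap_vox must be 0 or 1")
        for cls, p in self.frac_alone.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"frac_alone[{cls}] out of [0, 1]")
        if not 0.0 <= self.frac_ternary <= 1.0:
            raise ValueError("frac_ternary out of [0, 1]")


def dark_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Default dark-condition preset."""
    defaults = dict(count_ranges=dict(COUNT_RANGES["dark"]))
    defaults.update(overrides)
    return SynthSpec(condition="dark", seed=seed, **defaults)


def light_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Default light-condition preset.

    Relative to dark: no Alone chloroplasts and fewer Alone peroxisomes /
    mitochondria, more ternary anchoring, larger peroxisomes, shorter and
    less branched (slightly fatter) mitochondria, larger per-site
    proximity-area targets.
    """
    defaults = dict(
        count_ranges=dict(COUNT_RANGES["light"]),
        frac_alone={CHLOROPLAST: 0.0, PEROXISOME: 0.05, MITOCHONDRION: 0.147},
        frac_ternary=0.57,
        site_area_vox=55,
        per_radius_um=(0.28, 0.42),
        mito_radius_um=(0.17, 0.19),
        mito_length_um=(0.7, 1.4),
        mito_branch_p=0.15,
    )
    defaults.update(overrides)
    return SynthSpec(condition="light", seed=seed, **defaults)


def spec_for(condition: str, seed: int = 0, **overrides) -> SynthSpec:
    if condition == "dark":
        return dark_spec(seed, **overrides)
    if condition == "light":
        return light_spec(seed, **overrides)
    raise ValueError(f"unknown condition {condition!r}")


# --------------------------------------------------------------------------
# ground truth


@dataclass
class InstanceTruth:
    label: int
    organelle_class: str
    category_partners: frozenset[str]  # partner classes achieved by design
    partner_ids: frozenset[int]
    shape: dict = field(default_factory=dict)


@dataclass
class PairTruth:
    label_a: int
    label_b: int
    gap_vox: int
    area_target_vox: int
    contact: bool  # detectable (face-adjacent) by design


@dataclass
class GroundTruth:
    """Generator intentions: one record per instance plus the pair design."""

    cell_id: str
    condition: str
    seed: int
    instances: dict[int, InstanceTruth] = field(default_factory=dict)
    pairs: list[PairTruth] = field(default_factory=list)

    def labels_of_class(self, organelle_class: str) -> list[int]:
        return sorted(
            k for k, v in self.instances.items()
            if v.organelle_class == organelle_class
        )

    def count(self, organelle_class: str) -> int:
        return len(self.labels_of_class(organelle_class))

    def intended_partner_classes(self, label: int) -> frozenset[str]:
        return self.instances[label].category_partners

    def alone_fraction(self, organelle_class: str) -> float:
        ids = self.labels_of_class(organelle_class)
        if not ids:
            return float("nan")
        alone = sum(1 for i in ids if not self.instances[i].category_partners)
        return alone / len(ids)

    def ternary_fraction(self, organelle_class: str) -> float:
        ids = self.labels_of_class(organelle_class)
        if not ids:
            return float("nan")
        tern = sum(1 for i in ids if len(self.instances[i].category_partners) == 2)
        return tern / len(ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": self.cell_id,
                "condition": self.condition,
                "label": t.label,
                "organelle_class": t.organelle_class,
                "partner_classes": "+".join(sorted(t.category_partners)),
                "partner_ids": ";".join(str(i) for i in sorted(t.partner_ids)),
                "shape": json.dumps(t.shape, sort_keys=True),
            }
            for t in self.instances.values()
        ]
        return pd.DataFrame(rows)

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        Path(json_path).write_text(
            json.dumps(
                {
                    "cell_id": self.cell_id,
                    "condition": self.condition,
                    "seed": self.seed,
                    "pairs": [dataclasses.asdict(p) for p in self.pairs],
                },
                indent=2,
            )
            + "\n"
        )


# --------------------------------------------------------------------------
# geometry helpers (physical nm coordinates, voxelized at voxel centers)


def _voxel_centers(sl: tuple[slice, ...], spacing: np.ndarray) -> list[np.ndarray]:
    axes = [np.arange(s.start, s.stop) * d for s, d in zip(sl, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _clip_slice(center_vox, half_extent_vox, shape) -> tuple[slice, ...] | None:
    sl = []
    for c, h, n in zip(center_vox, half_extent_vox, shape):
        lo, hi = int(np.floor(c - h)) - 1, int(np.ceil(c + h)) + 2
        if hi <= 0 or lo >= n:
            return None
        sl.append(slice(max(lo, 0), min(hi, n)))
    return tuple(sl)


def _spheroid_mask(sl, spacing, center_nm, axis_dir, c_nm, a_nm):
    """Oblate spheroid: symmetry (short) axis ``axis_dir``, semi-axes c < a."""
    zz, yy, xx = _voxel_centers(sl, spacing)
    pz, py, px = zz - center_nm[0], yy - center_nm[1], xx - center_nm[2]
    n = np.asarray(axis_dir, dtype=float)
    n /= np.linalg.norm(n)
    dot = pz * n[0] + py * n[1] + px * n[2]
    r2 = pz * pz + py * py + px * px
    return dot * dot / c_nm**2 + (r2 - dot * dot) / a_nm**2 <= 1.0


def _superellipsoid_mask(sl, spacing, center_nm, semiaxes_nm, exponent=2.0):
    zz, yy, xx = _voxel_centers(sl, spacing)
    t = (
        np.abs((zz - center_nm[0]) / semiaxes_nm[0]) ** exponent
        + np.abs((yy - center_nm[1]) / semiaxes_nm[1]) ** exponent
        + np.abs((xx - center_nm[2]) / semiaxes_nm[2]) ** exponent
    )
    return t <= 1.0


def _tube_points(rng, start_nm, length_nm, step_nm=250.0, z_damp=0.35,
                 init_dir=None, confine=None, drift=None):
    """Persistent random-walk polyline, z excursions damped.

    ``confine`` is an optional (center_nm, semiaxes_nm) ellipsoid the walk
    is reflected back into (with projection fallback), keeping tubes inside
    the cell. ``drift`` adds a constant directional bias to every step
    (used to steer attached tubes out of the crowded chloroplast belt).
    """
    n_steps = max(2, int(round(length_nm / step_nm)))
    d = np.asarray(init_dir, float).copy() if init_dir is not None \
        else rng.normal(size=3)
    d[0] *= z_damp
    d /= np.linalg.norm(d)
    pts = [np.asarray(start_nm, dtype=float)]
    for _ in range(n_steps):
        d = d + 0.45 * rng.normal(size=3) * np.array([z_damp, 1.0, 1.0])
        if drift is not None:
            d = d + 0.30 * np.asarray(drift, float)
        d /= np.linalg.norm(d)
        nxt = pts[-1] + d * step_nm
        if confine is not None:
            center, semi = confine
            rel = (nxt - center) / semi
            val = float(rel @ rel)
            if val > 1.0:
                normal = (nxt - center) / semi**2
                normal /= np.linalg.norm(normal)
                d = d - 2.0 * float(d @ normal) * normal
                d /= np.linalg.norm(d)
                nxt = pts[-1] + d * step_nm
                rel = (nxt - center) / semi
                val = float(rel @ rel)
                if val > 1.0:  # reflected step still outside: project in
                    nxt = center + (nxt - center) * np.sqrt(0.96 / val)
        pts.append(nxt)
    return np.asarray(pts)


def _polyline_tube_mask(points_nm, radius_nm, sl, spacing):
    """Voxels within ``radius_nm`` of a polyline, evaluated per-segment on
    each segment's own subwindow (cheap for long winding tubes)."""
    shape = tuple(s.stop - s.start for s in sl)
    lo_vox = np.array([s.start for s in sl])
    mask = np.zeros(shape, dtype=bool)
    r2 = radius_nm * radius_nm
    for a, b in zip(points_nm[:-1], points_nm[1:]):
        seg_lo = np.floor((np.minimum(a, b) - radius_nm) / spacing).astype(int)
        seg_hi = np.ceil((np.maximum(a, b) + radius_nm) / spacing).astype(int) + 1
        seg_lo = np.maximum(seg_lo, lo_vox)
        seg_hi = np.minimum(seg_hi, lo_vox + shape)
        if (seg_hi <= seg_lo).any():
            continue
        sub = tuple(slice(int(p), int(q)) for p, q in zip(seg_lo, seg_hi))
        zz, yy, xx = _voxel_centers(sub, spacing)
        ab = b - a
        denom = float(ab @ ab)
        pz, py, px = zz - a[0], yy - a[1], xx - a[2]
        if denom == 0:
            d2 = pz * pz + py * py + px * px
        else:
            t = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / denom, 0.0, 1.0)
            d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
        view = tuple(slice(int(p - o), int(q - o))
                     for p, q, o in zip(seg_lo, seg_hi, lo_vox))
        mask[view] |= d2 <= r2
    return mask


# --------------------------------------------------------------------------
# generator state and placement primitives


class _GenState:
    def __init__(self, spec: SynthSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.spacing = np.asarray(spec.spacing_nm, dtype=float)
        self.labels = np.zeros(spec.grid_shape, dtype=np.int32)
        self.class_of: dict[int, str] = {}
        self.next_label = 1
        nz, ny, nx = spec.grid_shape
        self.center_nm = 0.5 * np.array([nz, ny, nx]) * self.spacing
        self.cell_scale = float(rng.uniform(*spec.cell_scale_range))
        self.cell_semi_nm = (np.asarray(spec.cell_semiaxes_um) * 1e3
                             * self.cell_scale)
        sl = tuple(slice(0, n) for n in spec.grid_shape)
        self.cell_mask = _superellipsoid_mask(
            sl, self.spacing, self.center_nm, self.cell_semi_nm, exponent=2.0
        )
        # organelles must stay >= 1 voxel inside the plasma membrane
        self.cell_core = ndimage.binary_erosion(self.cell_mask, _FACE, border_value=0)

    def new_label(self, organelle_class: str) -> int:
        lbl = self.next_label
        self.next_label += 1
        self.class_of[lbl] = organelle_class
        return lbl

    def radius_along(self, direction: np.ndarray) -> float:
        """Cell-ellipsoid radius (nm) along a unit direction."""
        d = direction / np.linalg.norm(direction)
        return 1.0 / np.sqrt(np.sum((d / self.cell_semi_nm) ** 2))

    def can_place(self, sl, mask_local, allowed: tuple[int, ...] = ()) -> bool:
        """No overlap with anything; no face adjacency except to ``allowed``;
        stays inside the cell core."""
        if (mask_local & ~self.cell_core[sl]).any():
            return False
        crop = self.labels[sl]
        occ = crop > 0
        if (mask_local & occ).any():
            return False
        others = occ if not allowed else (occ & ~np.isin(crop, allowed))
        if not others.any():
            return True
        grown = ndimage.binary_dilation(mask_local, _FACE)
        return not (grown & others).any()

    def commit(self, sl, mask_local, label: int) -> None:
        crop = self.labels[sl]
        assert not (mask_local & (crop > 0)).any()
        crop[mask_local] = label

    def mask_of(self, label: int, sl) -> np.ndarray:
        return self.labels[sl] == label

    def bbox(self, label: int, pad: int = 0) -> tuple[slice, ...]:
        idx = np.argwhere(self.labels == label)
        lo = idx.min(axis=0) - pad
        hi = idx.max(axis=0) + 1 + pad
        return tuple(
            slice(max(int(a), 0), min(int(b), n))
            for a, b, n in zip(lo, hi, self.labels.shape)
        )


def _make_shape_local(state: _GenState, organelle_class: str, shape: dict,
                      center_nm: np.ndarray):
    """Voxelize one organelle shape near ``center_nm``; returns (sl, mask)."""
    sp = state.spacing
    if organelle_class == PEROXISOME:
        r = shape["radius_nm"]
        half = np.ceil(r / sp) + 1
        sl = _clip_slice(center_nm / sp, half, state.labels.shape)
        if sl is None:
            return None
        return sl, _superellipsoid_mask(sl, sp, center_nm, (r, r, r))
    if organelle_class == CHLOROPLAST:
        a, c = shape["a_nm"], shape["c_nm"]
        half = np.ceil(a / sp) + 1
        sl = _clip_slice(center_nm / sp, half, state.labels.shape)
        if sl is None:
            return None
        return sl, _spheroid_mask(sl, sp, center_nm, shape["axis"], c, a)
    if organelle_class == MITOCHONDRION:
        pts = np.asarray(shape["points_nm"])
        r = shape["radius_nm"]
        lo = (pts.min(axis=0) - r) / sp
        hi = (pts.max(axis=0) + r) / sp
        cen = (lo + hi) / 2
        half = (hi - lo) / 2 + 1
        sl = _clip_slice(cen, half, state.labels.shape)
        if sl is None:
            return None
        return sl, _polyline_tube_mask(pts, r, sl, sp)
    raise ValueError(organelle_class)


def _place_touching(
    state: _GenState,
    organelle_class: str,
    shape_or_factory,
    anchor_ids: tuple[int, ...],
    gap_vox: int,
    attempts: int = 80,
):
    """Place a shape face-adjacent (or at a 1-voxel gap) to the anchors.

    Picks a random anchor surface voxel, spawns the shape outside along the
    local outward direction and slides it inward one voxel at a time along
    the dominant axis. The first disjoint, face-adjacent position is taken
    (sliding from a disjoint non-adjacent position always passes through
    face adjacency before overlap). ``shape_or_factory`` is a static shape
    dict or a callable ``(start_nm, init_dir) -> shape`` evaluated per
    candidate ray (tubes are grown in place, confined to the cell).
    Returns (label, sl, shape) or None.
    """
    rng = state.rng
    sp = state.spacing
    union_sl = None
    for a in anchor_ids:
        b = state.bbox(a, pad=2)
        union_sl = b if union_sl is None else tuple(
            slice(min(x.start, y.start), max(x.stop, y.stop))
            for x, y in zip(union_sl, b)
        )
    anchor_mask = np.isin(state.labels[union_sl], anchor_ids)
    surf = np.argwhere(surface_voxels(anchor_mask))
    if len(surf) == 0:
        return None
    origin = np.array([s.start for s in union_sl])
    centroid_nm = (np.argwhere(anchor_mask).mean(axis=0) + origin + 0.5) * sp

    for _ in range(attempts):
        v = surf[rng.integers(len(surf))] + origin
        v_nm = (v + 0.5) * sp
        out_dir = v_nm - centroid_nm
        if np.linalg.norm(out_dir) == 0:
            continue
        out_dir /= np.linalg.norm(out_dir)
        # prefer the anchor's inward/lateral faces: the thin gap between a
        # peripheral chloroplast and the cell wall almost never fits a
        # partner, while the belt toward the cell interior is open
        radial = v_nm - state.center_nm
        radial /= max(np.linalg.norm(radial), 1e-12)
        if float(out_dir @ radial) > 0.35:
            continue
        axis = int(np.argmax(np.abs(out_dir / sp)))  # dominant voxel axis
        sign = 1 if out_dir[axis] >= 0 else -1
        step_nm = np.zeros(3)
        step_nm[axis] = sign * sp[axis]

        center0 = v_nm + out_dir * 1.0  # shape reference point near v
        if callable(shape_or_factory):
            tang = np.cross(out_dir, rng.normal(size=3))
            tang /= max(np.linalg.norm(tang), 1e-12)
            shape = shape_or_factory(center0, tang, -radial)
        else:
            shape = shape_or_factory

        # spawn with clearance, then slide inward
        if organelle_class == CHLOROPLAST:
            extent = shape["a_nm"]
        else:
            extent = shape["radius_nm"]
        start_k = int(np.ceil(extent / sp[axis])) + 3
        prev = None  # (sl, mask, shape) at last disjoint non-adjacent offset
        for k in range(start_k, -1, -1):
            shp_center = center0 + k * step_nm
            made = _make_shape_local(state, organelle_class,
                                     _center_shape(shape, shp_center),
                                     shp_center)
            if made is None:
                break
            sl, m = made
            if not m.any():
                break
            crop = state.labels[sl]
            a_mask = np.isin(crop, anchor_ids)
            if (m & a_mask).any():
                break  # slid past adjacency into overlap: give up this ray
            others = (crop > 0) & ~a_mask
            grown = ndimage.binary_dilation(m, _FACE)
            if (m & others).any() or (grown & others).any():
                break  # blocked by a third organelle
            if (m & ~state.cell_core[sl]).any():
                continue  # partly outside the cell: keep sliding inward
            adjacent = (grown & a_mask).any()
            if adjacent:
                if gap_vox == 0:
                    lbl = state.new_label(organelle_class)
                    state.commit(sl, m, lbl)
                    return lbl, sl, _center_shape(shape, shp_center)
                if prev is not None:  # gap 1: previous non-adjacent position
                    psl, pm, pshape = prev
                    lbl = state.new_label(organelle_class)
                    state.commit(psl, pm, lbl)
                    return lbl, psl, pshape
                break
            prev = (sl, m, _center_shape(shape, shp_center))
    return None


def _center_shape(shape: dict, center_nm: np.ndarray) -> dict:
    """Re-anchor a shape description at a new reference point."""
    out = dict(shape)
    if "points_nm" in shape:
        pts = np.asarray(shape["points_nm"])
        out["points_nm"] = (pts - pts[0] + center_nm).tolist()
    else:
        out["center_nm"] = np.asarray(center_nm).tolist()
    return out


def _wrap_contact(
    state: _GenState,
    label: int,
    anchor_ids: tuple[int, ...],
    target_vox: int,
    max_iters: int,
) -> dict[int, bool]:
    """Grow ``label`` one voxel layer at a time along the anchors' shell.

    Expands the designed contact patch until the overlap-voxel count
    reaches ``target_vox`` (or growth stalls). Growth never overlaps or
    becomes face-adjacent to any instance other than the anchors. Returns
    per-anchor face-adjacency achieved.
    """
    pad = max_iters + 3
    sl = state.bbox(label, pad=pad)
    crop = state.labels[sl]
    S = crop == label
    A = np.isin(crop, anchor_ids)
    others = (crop > 0) & ~S & ~A
    shell_A = shell(A, 6)
    blocked = ndimage.binary_dilation(others, _FACE) | others | ~state.cell_core[sl]
    for _ in range(max_iters):
        n_overlap = int((shell_A & surface_voxels(S)).sum())
        grown = ndimage.binary_dilation(S, _FACE)
        all_adjacent = all((grown & (crop == a)).any() for a in anchor_ids)
        if n_overlap >= target_vox and all_adjacent:
            break
        add = (
            ndimage.binary_dilation(S, _FACE)
            & shell_A
            & ~S
            & ~blocked
            & (crop == 0)
        )
        if not add.any():
            break
        crop[add] = label
        S |= add
    grown = ndimage.binary_dilation(S, _FACE)
    return {a: bool((grown & (crop == a)).any()) for a in anchor_ids}


# --------------------------------------------------------------------------
# per-class placement routines


def _fibonacci_dirs(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(phi), np.sin(phi) * np.sin(theta), np.sin(phi) * np.cos(theta)],
        axis=1,
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    return q


def _try_chloroplast(state: _GenState, d: np.ndarray, a_nm: float,
                     c_nm: float):
    """Attempt one tangential oblate chloroplast along direction ``d``."""
    sp = state.spacing
    semi = state.cell_semi_nm
    r_dir = state.radius_along(d)
    # sink deep enough that the flat disc's rim clears the curved wall:
    # worst-case sagitta a^2 / (2 R_min), R_min = c^2/a of the cell
    r_min = float(min(semi) ** 2 / max(semi))
    sag = a_nm**2 / (2.0 * r_min)
    depth = c_nm + sag + 1.5 * float(sp.max())
    center_nm = state.center_nm + d * (r_dir - depth)
    normal = (center_nm - state.center_nm) / semi**2
    half = np.ceil(a_nm / sp) + 1
    sl = _clip_slice(center_nm / sp, half, state.labels.shape)
    if sl is None:
        return None
    m = _spheroid_mask(sl, sp, center_nm, normal, c_nm, a_nm)
    if not m.any() or not state.can_place(sl, m):
        return None
    lbl = state.new_label(CHLOROPLAST)
    state.commit(sl, m, lbl)
    shape = {"center_nm": center_nm.tolist(), "a_nm": a_nm, "c_nm": c_nm,
             "axis": (normal / np.linalg.norm(normal)).tolist()}
    return lbl, shape


def _place_chloroplasts(state: _GenState, n: int) -> list[tuple[int, dict]]:
    """Tile ``n`` oblate chloroplasts tangentially along the cell surface.

    Uses a randomly rotated Fibonacci lattice of exactly ``n`` directions
    (mesophyll chloroplasts tile the periphery densely, so independent
    rejection sampling cannot reach the required packing); on local
    conflict the equatorial radius is shrunk a few times, then fresh
    jittered/random directions are tried.
    """
    spec, rng = state.spec, state.rng
    placed: list[tuple[int, dict]] = []
    rot = _random_rotation(rng)
    dirs = _fibonacci_dirs(n) @ rot.T
    attempts = 0

    def attempt(d: np.ndarray) -> bool:
        nonlocal attempts
        a_nm = rng.uniform(*spec.chl_radius_um) * 1e3 * state.cell_scale
        ratio = rng.uniform(*spec.chl_flattening)
        for _ in range(6):  # adaptive shrink on conflict
            attempts += 1
            res = _try_chloroplast(state, d, a_nm, a_nm * ratio)
            if res is not None:
                placed.append(res)
                return True
            a_nm *= 0.86
        return False

    for d in dirs[rng.permutation(n)]:
        if len(placed) >= n:
            break
        attempt(d / np.linalg.norm(d))
    while len(placed) < n and attempts < spec.max_attempts:
        d = rng.normal(size=3)
        attempt(d / np.linalg.norm(d))
    if len(placed) < n:
        raise PlacementError(
            f"placed only {len(placed)}/{n} chloroplasts after "
            f"{attempts} attempts"
        )
    return placed


def _random_interior_center(state: _GenState, margin_nm: float) -> np.ndarray:
    """Random point in the organelle belt between vacuole and cell wall."""
    rng = state.rng
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    r = state.radius_along(d)
    s_lo, s_hi = 0.25, 1.0 - (margin_nm + 100.0) / r
    # volume-uniform radial position (uniform s oversamples the center)
    u = rng.uniform(s_lo**3, s_hi**3)
    return state.center_nm + d * r * u ** (1.0 / 3.0)


def _place_free(state: _GenState, organelle_class: str, shape_at,
                margin_nm: float, attempts: int) -> tuple[int, dict] | None:
    """Place one contact-free organelle (no adjacency to anything).

    ``shape_at`` is a callable ``(center_nm, scale) -> shape`` so tubes can
    be grown in place; ``scale`` shrinks the shape as attempts accumulate
    (late retries happen in a crowded cell).
    """
    sp = state.spacing
    for i in range(attempts):
        center = _random_interior_center(state, margin_nm)
        # cheap pre-check: a 3x3x3 neighborhood of the center must be free
        c = np.round(center / sp).astype(int)
        pre = tuple(slice(max(v - 1, 0), v + 2) for v in c)
        if (state.labels[pre] > 0).any():
            continue
        scale = 1.0 if i < attempts // 3 else (0.65 if i < 2 * attempts // 3
                                               else 0.4)
        shape = _center_shape(shape_at(center, scale), center)
        made = _make_shape_local(state, organelle_class, shape, center)
        if made is None:
            continue
        sl, m = made
        if not m.any():
            continue
        if state.can_place(sl, m):
            lbl = state.new_label(organelle_class)
            state.commit(sl, m, lbl)
            return lbl, shape
    return None


def _per_shape(state: _GenState, scale: float = 1.0) -> dict:
    r = state.rng.uniform(*state.spec.per_radius_um) * 1e3 * scale
    return {"radius_nm": r}


def _mito_shape(state: _GenState, start_nm, init_dir=None, drift=None,
                length_scale: float = 1.0) -> dict:
    """Tube shape anchored at ``start_nm``, confined to the cell interior."""
    spec, rng = state.spec, state.rng
    r = rng.uniform(*spec.mito_radius_um) * 1e3
    length = rng.uniform(*spec.mito_length_um) * 1e3 * length_scale \
        * state.cell_scale
    margin = r + 2.5 * float(state.spacing.max())
    confine = (state.center_nm, state.cell_semi_nm - margin)
    start = np.asarray(start_nm, float)
    pts = _tube_points(rng, start, length, init_dir=init_dir, confine=confine,
                       drift=drift)
    branched = False
    if rng.random() < spec.mito_branch_p and len(pts) >= 4:
        k = int(rng.integers(1, len(pts) - 2))
        bdir = rng.normal(size=3)
        bdir[0] *= 0.35
        bdir /= np.linalg.norm(bdir)
        bpts = _tube_points(rng, pts[k], 0.6 * length, init_dir=bdir,
                            confine=confine, drift=drift)
        pts = np.vstack([pts, bpts])  # polyline union; distance field handles it
        branched = True
    return {"points_nm": pts.tolist(), "radius_nm": r, "branched": branched,
            "length_nm": length}


# --------------------------------------------------------------------------
# the generator


def generate_cell(spec: SynthSpec) -> tuple[LabelVolume, GroundTruth]:
    """Generate one labeled cell volume plus its ground truth.

    Deterministic in ``spec`` (identical spec -> bit-identical volume).
    Raises :class:`PlacementError` when the requested organelle counts do
    not fit, reporting achieved counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 9151]))
    state = _GenState(spec, rng)
    gt = GroundTruth(cell_id=f"{spec.condition[0].upper()}{spec.seed}",
                     condition=spec.condition, seed=spec.seed)

    counts = {
        cls: int(rng.integers(lo, hi + 1))
        for cls, (lo, hi) in spec.count_ranges.items()
    }

    # nucleus first (needs contiguous room), then the chloroplast layer
    nuc_lbl = None
    nuc_semi = np.asarray(spec.nucleus_semiaxes_um) * 1e3 * state.cell_scale
    for _ in range(spec.max_attempts):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        r = state.radius_along(d)
        center = state.center_nm + d * r * rng.uniform(0.35, 0.55)
        sl = _clip_slice(center / state.spacing,
                         np.ceil(nuc_semi.max() / state.spacing) + 1,
                         state.labels.shape)
        if sl is None:
            continue
        m = _superellipsoid_mask(sl, state.spacing, center, nuc_semi)
        if m.any() and state.can_place(sl, m):
            nuc_lbl = state.new_label(NUCLEUS)
            state.commit(sl, m, nuc_lbl)
            break
    if nuc_lbl is None:
        raise PlacementError("could not place nucleus")

    chloros = _place_chloroplasts(state, counts[CHLOROPLAST])
    chl_ids = [lbl for lbl, _ in chloros]
    for lbl, shape in chloros:
        gt.instances[lbl] = InstanceTruth(lbl, CHLOROPLAST, frozenset(),
                                          frozenset(), shape)
    gt.instances[nuc_lbl] = InstanceTruth(nuc_lbl, NUCLEUS, frozenset(),
                                          frozenset(), {})

    # ----- contact design ------------------------------------------------
    fa = spec.frac_alone
    alone_chl = {c: rng.random() < fa.get(CHLOROPLAST, 0.0) for c in chl_ids}
    engaged_chl = [c for c in chl_ids if not alone_chl[c]]
    p_tern = spec.frac_ternary
    if engaged_chl and len(engaged_chl) < len(chl_ids):
        p_tern = min(1.0, spec.frac_ternary * len(chl_ids) / len(engaged_chl))
    ternary_chl = [c for c in engaged_chl if rng.random() < p_tern]
    binary_chl = [c for c in engaged_chl if c not in ternary_chl]
    binary_chl_partner = {
        c: (MITOCHONDRION if rng.random() < spec.binary_partner_mito_p
            else PEROXISOME)
        for c in binary_chl
    }

    per_alone_draws = [rng.random() < fa.get(PEROXISOME, 0.0)
                       for _ in range(counts[PEROXISOME])]
    mit_alone_draws = [rng.random() < fa.get(MITOCHONDRION, 0.0)
                       for _ in range(counts[MITOCHONDRION])]
    n_per_engaged = per_alone_draws.count(False)
    n_mit_engaged = mit_alone_draws.count(False)

    # budget: each ternary anchor consumes one engaged per + one engaged mit;
    # each binary chloroplast one partner of its class. Downgrade ternary
    # anchors (to binary-with-mito) if peroxisomes run short.
    need_per = len(ternary_chl) + sum(
        1 for c in binary_chl if binary_chl_partner[c] == PEROXISOME
    )
    while need_per > n_per_engaged and ternary_chl:
        moved = ternary_chl.pop(rng.integers(len(ternary_chl)))
        binary_chl.append(moved)
        binary_chl_partner[moved] = MITOCHONDRION
        need_per -= 1
    need_mit = len(ternary_chl) + sum(
        1 for c in binary_chl if binary_chl_partner[c] == MITOCHONDRION
    )
    while need_mit > n_mit_engaged and binary_chl:
        # extremely rare: not enough engaged mitochondria; make the excess
        # binary chloroplasts peroxisome-partnered if possible
        cands = [c for c in binary_chl if binary_chl_partner[c] == MITOCHONDRION]
        if not cands or need_per >= n_per_engaged:
            break
        c = cands[int(rng.integers(len(cands)))]
        binary_chl_partner[c] = PEROXISOME
        need_per += 1
        need_mit -= 1

    # Pending-job queues: every engaged chloroplast must end up with at
    # least its designed partner, so jobs that fail on a crowded anchor are
    # retried by later organelles of the same class (any pending anchor is
    # an equivalent target); once no jobs are pending, further engaged
    # organelles attach to random eligible anchors as extras.
    gap = spec.contact_gap_vox
    per_queue: list[tuple[int, ...]] = [(c,) for c in ternary_chl]
    per_queue += [(c,) for c in binary_chl
                  if binary_chl_partner[c] == PEROXISOME]
    extra_per_anchors = list(per_queue)

    tern_per_of: dict[int, int] = {}  # ternary chl -> its peroxisome label

    def _attach_from_queue(organelle_class, queue, extra_pool, try_one):
        """Try pending anchors in order, then a few random extras."""
        for qi in range(len(queue)):
            res = try_one(queue[qi])
            if res is not None:
                return res, queue.pop(qi), True
        pool = [a for a in extra_pool if a] or [(c,) for c in engaged_chl]             or [(c,) for c in chl_ids]
        for a in rng.permutation(len(pool))[:6]:
            anc = pool[int(a)]
            res = try_one(anc)
            if res is not None:
                return res, anc, False
        return None, None, False

    per_records: list[tuple[int, dict, tuple[int, ...], tuple[int, ...]]] = []
    for alone in per_alone_draws:
        if alone:
            res = _place_free(
                state, PEROXISOME,
                lambda c, sc: _per_shape(state, max(sc, 0.7)),
                spec.per_radius_um[1] * 1e3, spec.max_attempts,
            )
            if res is None:
                raise PlacementError(
                    f"could not place free peroxisome (placed "
                    f"{len(per_records)}/{counts[PEROXISOME]})"
                )
            lbl, shape = res
            per_records.append((lbl, shape, (), ()))
            continue

        def try_per(anc):
            r = _place_touching(state, PEROXISOME, _per_shape(state), anc,
                                gap, attempts=50)
            if r is None:
                r = _place_touching(
                    state, PEROXISOME,
                    {"radius_nm": spec.per_radius_um[0] * 1e3}, anc, gap,
                    attempts=50,
                )
            return r

        res, anchors, _ = _attach_from_queue(PEROXISOME, per_queue,
                                             extra_per_anchors, try_per)
        if res is None:
            warnings.warn("engaged peroxisome fell back to free placement")
            res2 = _place_free(
                state, PEROXISOME,
                lambda c, sc: _per_shape(state, max(sc, 0.7)),
                spec.per_radius_um[1] * 1e3, spec.max_attempts,
            )
            if res2 is None:
                raise PlacementError("could not place peroxisome")
            lbl, shape2 = res2
            per_records.append((lbl, shape2, (), ()))
            continue
        lbl, _sl, shape = res
        if gap == 0:
            r_mid = 0.5 * sum(spec.per_radius_um) * 1e3
            target = max(
                6,
                int(round(spec.site_area_vox
                          * (shape["radius_nm"] / r_mid) ** 2)),
            )
            adj = _wrap_contact(state, lbl, anchors, target,
                                spec.wrap_max_iters)
            achieved = tuple(a for a in anchors if adj.get(a, False))
        else:
            achieved = ()
        per_records.append((lbl, shape, achieved, anchors))
        if achieved and anchors[0] in ternary_chl                 and anchors[0] not in tern_per_of:
            tern_per_of[anchors[0]] = lbl

    # mitochondria: ternary complexes (anchor = chl + its peroxisome) first,
    # then mito-partnered binary chloroplasts, then extras
    mit_queue: list[tuple[int, ...]] = []
    for c in ternary_chl:
        if c in tern_per_of:
            mit_queue.append((c, tern_per_of[c]))
        else:
            mit_queue.append((c,))
    mit_queue += [(c,) for c in binary_chl
                  if binary_chl_partner[c] == MITOCHONDRION]
    extra_mit_anchors = list(mit_queue)

    mit_records: list[tuple[int, dict, tuple[int, ...], tuple[int, ...]]] = []
    for alone in mit_alone_draws:
        if alone:
            res = _place_free(state, MITOCHONDRION,
                              lambda c, sc: _mito_shape(state, c,
                                                        length_scale=sc),
                              spec.mito_radius_um[1] * 1e3 + 400.0,
                              spec.max_attempts)
            if res is None:
                raise PlacementError(
                    f"could not place free mitochondrion (placed "
                    f"{len(mit_records)}/{counts[MITOCHONDRION]})"
                )
            lbl, shape = res
            mit_records.append((lbl, shape, (), ()))
            continue

        def try_mit(anc):
            for ls in (1.0, 0.55):  # shorter tubes on crowded anchors
                factory = (lambda scale: lambda start, d, drift:
                           _mito_shape(state, start, init_dir=d, drift=drift,
                                       length_scale=scale))(ls)
                r = _place_touching(state, MITOCHONDRION, factory, anc, gap,
                                    attempts=50)
                if r is None and len(anc) > 1:
                    r = _place_touching(state, MITOCHONDRION, factory,
                                        anc[:1], gap, attempts=50)
                if r is not None:
                    return r
            return None

        res, anchors, _ = _attach_from_queue(MITOCHONDRION, mit_queue,
                                             extra_mit_anchors, try_mit)
        if res is None:
            warnings.warn("engaged mitochondrion fell back to free placement")
            res2 = _place_free(state, MITOCHONDRION,
                               lambda c, sc: _mito_shape(state, c,
                                                         length_scale=sc),
                               spec.mito_radius_um[1] * 1e3 + 400.0,
                               spec.max_attempts)
            if res2 is None:
                raise PlacementError("could not place mitochondrion")
            lbl, shape2 = res2
            mit_records.append((lbl, shape2, (), ()))
            continue
        lbl, _sl, shape = res
        if gap == 0:
            adj = _wrap_contact(state, lbl, anchors[:1], spec.site_area_vox,
                                spec.wrap_max_iters)
            if len(anchors) > 1:
                adj.update(
                    _wrap_contact(state, lbl, anchors[1:],
                                  max(spec.site_area_vox // 2, 8),
                                  spec.wrap_max_iters)
                )
            achieved = tuple(a for a in anchors if adj.get(a, False))
        else:
            achieved = ()
        mit_records.append((lbl, shape, achieved, anchors))

    # ----- ground-truth records ------------------------------------------
    partner_ids: dict[int, set[int]] = {lbl: set() for lbl in state.class_of}
    for lbl, shape, achieved, _designed in per_records + mit_records:
        for a in achieved:
            partner_ids[lbl].add(a)
            partner_ids[a].add(lbl)
    for cls, records in ((PEROXISOME, per_records), (MITOCHONDRION, mit_records)):
        for lbl, shape, achieved, designed in records:
            gt.instances[lbl] = InstanceTruth(
                lbl, cls,
                frozenset(state.class_of[a] for a in partner_ids[lbl]),
                frozenset(partner_ids[lbl]), shape,
            )
            for a in achieved:
                gt.pairs.append(
                    PairTruth(lbl, a, gap, spec.site_area_vox, True)
                )
            if gap != 0:  # designed-but-undetectable pairs (one-voxel gap)
                for a in designed:
                    gt.pairs.append(PairTruth(lbl, a, gap, 0, False))
    for lbl in chl_ids:
        gt.instances[lbl] = dataclasses.replace(
            gt.instances[lbl],
            category_partners=frozenset(
                state.class_of[p] for p in partner_ids[lbl]
            ),
            partner_ids=frozenset(partner_ids[lbl]),
        )

    # ----- vacuole and cytoplasm -----------------------------------------
    # The vacuole fills the interior (capped by a super-ellipsoid) left
    # free after keeping a thin cytoplasmic layer under the wall and a
    # one-voxel moat around every organelle.
    vac_semi = np.asarray(spec.vacuole_semiaxes_um) * 1e3 * state.cell_scale
    sl_all = tuple(slice(0, n) for n in spec.grid_shape)
    vac_region = _superellipsoid_mask(sl_all, state.spacing, state.center_nm,
                                      vac_semi, spec.vacuole_exponent)
    interior = ndimage.binary_erosion(
        state.cell_core, _FACE, iterations=spec.vacuole_wall_margin_vox,
        border_value=0,
    )
    occupied = state.labels > 0
    moat = ndimage.binary_dilation(occupied, _FACE)
    vac = vac_region & interior & ~moat
    if vac.any():
        lab, ncomp = ndimage.label(vac, ndimage.generate_binary_structure(3, 3))
        if ncomp > 1:
            vac = lab == (np.bincount(lab.ravel())[1:].argmax() + 1)
        vac_lbl = state.new_label(VACUOLE)
        state.labels[vac] = vac_lbl
        gt.instances[vac_lbl] = InstanceTruth(vac_lbl, VACUOLE, frozenset(),
                                              frozenset(), {})
    else:
        warnings.warn("vacuole region vanished after carving")

    cyto = state.cell_mask & (state.labels == 0)
    cyto_lbl = state.new_label(CELL_BACKGROUND)
    state.labels[cyto] = cyto_lbl
    gt.instances[cyto_lbl] = InstanceTruth(cyto_lbl, CELL_BACKGROUND,
                                           frozenset(), frozenset(), {})

    vol = LabelVolume(
        labels=state.labels,
        spacing_nm=tuple(spec.spacing_nm),
        class_map=dict(state.class_of),
        cell_id=gt.cell_id,
        condition=spec.condition,
    )
    return vol, gt


def generate_condition_panel(
    n_cells: int, condition: str, seed: int, **overrides
) -> list[tuple[LabelVolume, GroundTruth]]:
    """Generate ``n_cells`` independent cells of one condition.

    Cell seeds are derived deterministically from ``seed``; cell ids are
    ``D1..`` / ``L1..``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ss = np.random.SeedSequence([seed, 0 if condition == "dark" else 1])
    out = []
    for i, child in enumerate(ss.spawn(n_cells)):
        cell_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = spec_for(condition, seed=cell_seed, **overrides)
        vol, gt = generate_cell(spec)
        vol.cell_id = f"{condition[0].upper()}{i + 1}"
        gt.cell_id = vol.cell_id
        out.append((vol, gt))
    return out


def occupancy_fractions(vol: LabelVolume) -> dict[str, float]:
    """Per-class voxel-volume fraction of the whole cell (all labels)."""
    total = int((vol.labels > 0).sum())
    out: dict[str, float] = {}
    for cls in set(vol.class_map.values()):
        n = int(np.isin(vol.labels, vol.labels_of_class(cls)).sum())
        out[cls] = n / total if total else float("nan")
    return out
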