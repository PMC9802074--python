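"""Per-instance 3D morphometry on anisotropic label grids.

Quantities
----------
volume
    ``V = n_voxels * dz * dy * dx`` (nm^3 -> um^3), exact by definition.
surface area
    Sum of triangle areas of a marching-cubes isosurface (level 0.5) built
    with physical vertex coordinates, so anisotropic spacing is honored.
sphericity
    Wadell sphericity ``psi = pi^(1/3) (6V)^(2/3) / SA``; 1 for a sphere,
    smaller for flattened, elongated or branched shapes.
MCI
    Mitochondria complex(ity) intensity, here sphere-normalized as
    ``MCI = SA^3 / (36 pi V^2) = psi^-3``; 1 for a sphere, invariant under
    uniform rescaling (shape-only, "not affected by volume"), increasing
    with elongation and branching.
length
    Mitochondria only: longest geodesic path through the 3D skeleton of
    the mask, edge lengths in physical units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

from .io import MITOCHONDRION, LabelVolume

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6
NM_PER_UM = 1e3


def volume_um3(n_voxels: int, spacing_nm: tuple[float, float, float]) -> float:
    """Volume of ``n_voxels`` voxels: n * dz * dy * dx, nm^3 -> um^3."""
    dz, dy, dx = spacing_nm
    return n_voxels * dz * dy * dx / NM3_PER_UM3


def surface_area_um2(
    mask: np.ndarray,
    spacing_nm: tuple[float, float, float],
    smooth_sigma: float = 0.7,
    thin_sigma: float = 0.5,
    thin_radius_vox: float = 4.5,
) -> float:
    """Isosurface area of a binary mask in um^2.

    The mask is padded with background so the surface closes at the grid
    boundary, lightly Gaussian-smoothed (in index space) to suppress the
    systematic ~9% staircase overestimate of meshing raw binary data, and
    meshed at level 0.5 with physical vertex coordinates. Marginally
    resolved objects (largest inscribed radius below ``thin_radius_vox``
    voxels) use the gentler ``thin_sigma`` so smoothing does not erode
    them; objects too thin to survive smoothing at all are re-meshed
    unsmoothed, and degenerate meshes fall back to the summed area of
    exposed voxel faces, with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    padded = np.pad(mask, 2).astype(np.float32)
    sigma = smooth_sigma
    if smooth_sigma > 0:
        inscribed = float(ndimage.distance_transform_edt(padded).max())
        if inscribed < thin_radius_vox:
            sigma = thin_sigma
    vol = ndimage.gaussian_filter(padded, sigma) if sigma > 0 else padded
    if vol.max() <= 0.5:  # thinner than the smoothing support
        vol = padded
    try:
        verts, faces, _, _ = skmeasure.marching_cubes(
            vol, level=0.5, spacing=tuple(float(s) for s in spacing_nm)
        )
        area_nm2 = float(skmeasure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        warnings.warn("degenerate mesh; falling back to voxel-face surface area")
        area_nm2 = _voxel_face_area_nm2(mask, spacing_nm)
    return area_nm2 / NM2_PER_UM2


def _voxel_face_area_nm2(mask: np.ndarray, spacing_nm) -> float:
    dz, dy, dx = spacing_nm
    face_areas = (dy * dx, dz * dx, dz * dy)  # faces normal to z, y, x
    padded = np.pad(mask, 1)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        total += fa * np.count_nonzero(diff)
    return total


def sphericity(volume: float, surface_area: float) -> float:
    """Wadell sphericity psi = pi^(1/3) (6V)^(2/3) / SA."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface_area


def mci(volume: float, surface_area: float) -> float:
    """Sphere-normalized complexity index SA^3 / (36 pi V^2) = psi^-3."""
    if volume <= 0 or surface_area <= 0:
        raise ValueError("volume and surface area must be positive")
    return surface_area**3 / (36.0 * np.pi * volume**2)


def sphere_surface_area(volume: float) -> float:
    """Theoretical sphere curve SA = (36 pi)^(1/3) V^(2/3)."""
    return (36.0 * np.pi) ** (1 / 3) * volume ** (2 / 3)


_FULL = ndimage.generate_binary_structure(3, 3)
# offsets of the 26-neighborhood, split to unique half to build an
# undirected skeleton graph once per instance
_HALF_OFFSETS = [
    (oz, oy, ox)
    for oz in (-1, 0, 1)
    for oy in (-1, 0, 1)
    for ox in (-1, 0, 1)
    if (oz, oy, ox) > (0, 0, 0)
]


def skeleton_length_um(
    mask: np.ndarray, spacing_nm: tuple[float, float, float]
) -> float:
    """Longest geodesic path through the 3D skeleton, in micrometres.

    The mask is thinned to a 1-voxel skeleton; skeleton voxels become graph
    nodes connected to their 26-neighbors with anisotropic Euclidean edge
    weights, and the length is the largest shortest-path distance within
    the largest connected component (exact all-pairs for small skeletons,
    double-sweep otherwise). An empty skeleton falls back to the maximal
    physical extent of the voxel set, with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no skeleton")
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        warnings.warn("empty skeleton; using maximal physical extent as length")
        coords = np.argwhere(mask)
    if len(coords) == 1:
        return 0.0
    sp = np.asarray(spacing_nm, dtype=float)
    index = -np.ones(skel.shape if skel.any() else mask.shape, dtype=np.int64)
    index[tuple(coords.T)] = np.arange(len(coords))
    rows, cols, weights = [], [], []
    shape = index.shape
    for off in _HALF_OFFSETS:
        nbr = coords + off
        ok = np.all((nbr >= 0) & (nbr < shape), axis=1)
        j = np.full(len(coords), -1, dtype=np.int64)
        j[ok] = index[tuple(nbr[ok].T)]
        ok &= j >= 0
        if not ok.any():
            continue
        w = np.linalg.norm(np.asarray(off, dtype=float) * sp)
        rows.append(np.arange(len(coords))[ok])
        cols.append(j[ok])
        weights.append(np.full(ok.sum(), w))
    if not rows:
        return 0.0
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    n = len(coords)
    graph = coo_matrix((weights, (rows, cols)), shape=(n, n))
    graph = graph + graph.T
    n_comp, comp = connected_components(graph, directed=False)
    if n_comp > 1:
        largest = np.argmax(np.bincount(comp))
        keep = np.flatnonzero(comp == largest)
        graph = graph.tocsr()[keep][:, keep]
        n = len(keep)
    graph = graph.tocsr()
    if n <= 600:
        dist = dijkstra(graph, directed=False)
        longest = float(dist[np.isfinite(dist)].max())
    else:  # double sweep: exact on trees, excellent on near-tree skeletons
        d0 = dijkstra(graph, directed=False, indices=0)
        far = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
        d1 = dijkstra(graph, directed=False, indices=far)
        longest = float(np.max(d1[np.isfinite(d1)]))
    return longest / NM_PER_UM


@dataclass
class OrganelleInstance:
    """Morphometry record of one segmented organelle."""

    label: int
    organelle_class: str
    n_voxels: int
    volume_um3: float
    surface_area_um2: float
    sphericity: float
    mci: float
    length_um: float | None = None  # mitochondria only


def extract_instances(
    vol: LabelVolume,
    classes: tuple[str, ...] | None = None,
    measure_length: bool = True,
) -> list[OrganelleInstance]:
    """Measure every labeled instance of a volume.

    One record per nonzero label (labels define identity; a label whose
    voxels form several disconnected 26-components is kept as one instance,
    with a warning). ``classes`` restricts measurement to the given
    organelle classes; skeleton length is computed for mitochondria only.
    """
    out: list[OrganelleInstance] = []
    objects = ndimage.find_objects(vol.labels)
    for lbl in vol.present_labels():
        cls = vol.class_map[lbl]
        if classes is not None and cls not in classes:
            continue
        sl = objects[lbl - 1]
        mask = vol.labels[sl] == lbl
        n_vox = int(mask.sum())
        _, n_comp = ndimage.label(mask, structure=_FULL)
        if n_comp > 1:
            warnings.warn(
                f"label {lbl} ({cls}) has {n_comp} disconnected components; "
                "kept as one instance"
            )
        v = volume_um3(n_vox, vol.spacing_nm)
        sa = surface_area_um2(mask, vol.spacing_nm)
        length = None
        if measure_length and cls == MITOCHONDRION:
            length = skeleton_length_um(mask, vol.spacing_nm)
        out.append(
            OrganelleInstance(
                label=lbl,
                organelle_class=cls,
                n_voxels=n_vox,
                volume_um3=v,
                surface_area_um2=sa,
                sphericity=sphericity(v, sa),
                mci=mci(v, sa),
                length_um=length,
            )
        )
    return out


def instances_frame(
    instances: list[OrganelleInstance], cell_id: str = "", condition: str | None = None
) -> pd.DataFrame:
    """Tabulate instance records (one row per organelle)."""
    rows = [
        {
            "cell_id": cell_id,
            "condition": condition,
            "label": i.label,
            "organelle_class": i.organelle_class,
            "n_voxels": i.n_voxels,
            "volume_um3": i.volume_um3,
            "surface_area_um2": i.surface_area_um2,
            "sphericity": i.sphericity,
            "mci": i.mci,
            "length_um": i.length_um,
        }
        for i in instances
    ]
    cols = [
        "cell_id", "condition", "label", "organelle_class", "n_voxels",
        "volume_um3", "surface_area_um2", "sphericity", "mci", "length_um",
    ]
    return pd.DataFrame(rows, columns=cols)
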