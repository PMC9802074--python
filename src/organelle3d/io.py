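"""Reading and writing instance-labeled 3D volumes.

A labeled volume is a multi-page TIFF of integer instance labels (one page
per serial section, pages in ascending z) plus a JSON sidecar carrying the
physical voxel spacing, the label -> organelle-class map, a cell identifier
and optionally the light condition. Label 0 is reserved for unlabeled
background; every other label present in the grid is one organelle instance
and must have a class entry.

Axis convention: arrays are indexed (z, y, x), z being the sectioning axis.
Spacing is (dz, dy, dx) in nanometres; the default (100, 10, 10) nm matches
100 nm serial sections imaged at 10 x 10 nm pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Organelle classes understood by the analysis modules.
CHLOROPLAST = "chloroplast"
PEROXISOME = "peroxisome"
MITOCHONDRION = "mitochondrion"
NUCLEUS = "nucleus"
VACUOLE = "vacuole"
CELL_BACKGROUND = "cell_background"

KNOWN_CLASSES = frozenset(
    {CHLOROPLAST, PEROXISOME, MITOCHONDRION, NUCLEUS, VACUOLE, CELL_BACKGROUND}
)

#: Classes participating in contact analysis, in canonical (alphabetical)
#: order; the first class of a pair is the shell-bearing primary.
CONTACT_CLASSES = (CHLOROPLAST, MITOCHONDRION, PEROXISOME)

DEFAULT_SPACING_NM = (100.0, 10.0, 10.0)


class ValidationError(ValueError):
    """Raised when a labeled volume violates its metadata contract."""


@dataclass
class LabelVolume:
    """An instance-labeled 3D grid with physical metadata.

    Parameters
    ----------
    labels
        (nz, ny, nx) integer array; 0 is background, every other value is
        one organelle instance.
    spacing_nm
        (dz, dy, dx) voxel edge lengths in nanometres, all > 0.
    class_map
        Maps each nonzero label present in ``labels`` to its organelle
        class string.
    cell_id
        Identifier of the source cell (e.g. ``"D1"``).
    condition
        Optional experimental condition, ``"dark"`` or ``"light"``.
    """

    labels: np.ndarray
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM
    class_map: dict[int, str] = field(default_factory=dict)
    cell_id: str = "cell"
    condition: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        self.class_map = {int(k): str(v) for k, v in self.class_map.items()}
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.labels.ndim != 3:
            raise ValidationError(
                f"labels must be 3D (z, y, x), got ndim={self.labels.ndim}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError(f"labels must be integer, got {self.labels.dtype}")
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValidationError(
                f"spacing_nm must be 3 positive values, got {self.spacing_nm}"
            )
        if 0 in self.class_map:
            raise ValidationError("label 0 is reserved for background; remove it "
                                  "from class_map")
        present = self.present_labels()
        missing = sorted(set(present) - set(self.class_map))
        if missing:
            raise ValidationError(
                f"labels present in grid but absent from class_map: {missing}"
            )

    def present_labels(self) -> list[int]:
        """Sorted nonzero labels actually present in the grid."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def mask(self, label: int) -> np.ndarray:
        """Boolean mask of one instance."""
        return self.labels == label

    def class_mask(self, organelle_class: str) -> np.ndarray:
        """Boolean mask of all instances of one class."""
        ids = self.labels_of_class(organelle_class)
        if not ids:
            return np.zeros(self.labels.shape, dtype=bool)
        return np.isin(self.labels, ids)

    def labels_of_class(self, organelle_class: str) -> list[int]:
        return sorted(k for k, v in self.class_map.items() if v == organelle_class)

    @property
    def voxel_volume_nm3(self) -> float:
        dz, dy, dx = self.spacing_nm
        return dz * dy * dx

    def __eq__(self, other: object) -> bool:  # labels + metadata identity
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return (
            np.array_equal(self.labels, other.labels)
            and self.spacing_nm == other.spacing_nm
            and self.class_map == other.class_map
            and self.cell_id == other.cell_id
            and self.condition == other.condition
        )


def _default_meta_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_label_volume(
    vol: LabelVolume, stack_path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write a multi-page TIFF label stack and its JSON sidecar.

    Labels are stored as unsigned 16-bit; page order maps to ascending z.
    """
    stack_path = Path(stack_path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(stack_path)
    if vol.labels.size and vol.labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("labels exceed uint16 range; relabel before writing")
    if vol.labels.size and vol.labels.min() < 0:
        raise ValidationError("negative labels are not allowed")
    tifffile.imwrite(stack_path, vol.labels.astype(np.uint16), photometric="minisblack")
    meta = {
        "spacing_nm": list(vol.spacing_nm),
        "class_map": {str(k): v for k, v in sorted(vol.class_map.items())},
        "cell_id": vol.cell_id,
        "condition": vol.condition,
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")


def read_label_volume(
    stack_path: str | Path, meta_path: str | Path | None = None
) -> LabelVolume:
    """Read a label stack written by :func:`write_label_volume`.

    Raises
    ------
    ValidationError
        If metadata keys are missing, spacing is non-positive, or the grid
        contains labels absent from the class map (the offending labels are
        named in the message).
    """
    stack_path = Path(stack_path)
    meta_path = Path(meta_path) if meta_path is not None else _default_meta_path(stack_path)
    if not meta_path.exists():
        raise ValidationError(f"metadata sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("spacing_nm", "class_map", "cell_id"):
        if key not in meta:
            raise ValidationError(f"metadata key missing: {key!r} in {meta_path}")
    labels = np.asarray(tifffile.imread(stack_path))
    if labels.ndim == 2:  # single-page stack
        labels = labels[None, :, :]
    return LabelVolume(
        labels=labels.astype(np.int32),
        spacing_nm=tuple(meta["spacing_nm"]),
        class_map={int(k): v for k, v in meta["class_map"].items()},
        cell_id=meta["cell_id"],
        condition=meta.get("condition"),
    )
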