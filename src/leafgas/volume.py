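"""Labeled leaf volumes: the segmented-microCT container and its TIFF/JSON I/O.

A :class:`LabeledVolume` is a 3D integer label array (axes ``z, y, x`` with
``z`` running from the adaxial to the abaxial side of the leaf) plus an
isotropic voxel size in micrometres and a map from tissue name to label
value.  Seven tissue classes are supported: background, the two epidermes,
mesophyll cells, intercellular airspace (IAS), bundle sheath extensions
(BSE) and veins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_LABELS",
    "LabeledVolume",
    "save_labeled_volume",
    "load_labeled_volume",
]

#: Canonical tissue-name -> label-value map used throughout the package.
DEFAULT_LABELS: dict[str, int] = {
    "background": 0,
    "epidermis_adaxial": 1,
    "epidermis_abaxial": 2,
    "mesophyll_cell": 3,
    "ias": 4,
    "bse": 5,
    "vein": 6,
}

#: Labels that make up the mesophyll region (between the epidermes).
MESOPHYLL_REGION = ("mesophyll_cell", "ias", "bse", "vein")


@dataclass
class LabeledVolume:
    """Segmented leaf volume.

    Parameters
    ----------
    labels
        ``(nz, ny, nx)`` integer array; ``z`` axis runs adaxial -> abaxial.
    voxel_size_um
        Isotropic voxel edge length in micrometres; must be positive.
    label_map
        Tissue name -> integer label.  Defaults to :data:`DEFAULT_LABELS`.
    """

    labels: np.ndarray
    voxel_size_um: float
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        declared = set(self.label_map.values())
        present = set(np.unique(self.labels).tolist())
        if not present <= declared:
            raise ValueError(
                f"volume contains undeclared labels {sorted(present - declared)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the named tissues."""
        values = [self.label_map[n] for n in names]
        return np.isin(self.labels, values)

    def count(self, *names: str) -> int:
        return int(self.mask(*names).sum())

    def transposed(self) -> "LabeledVolume":
        """Swap the in-plane (y, x) axes; all traits should be invariant."""
        return LabeledVolume(
            np.swapaxes(self.labels, 1, 2).copy(), self.voxel_size_um, dict(self.label_map)
        )


def save_labeled_volume(
    volume: LabeledVolume, tiff_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """Write a label stack as a multi-page TIFF plus a JSON sidecar.

    One TIFF page per z-slice, uint8 labels.  The sidecar records the
    label map and the voxel size so that the stack is self-describing.
    """
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, volume.labels.astype(np.uint8))
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    Path(sidecar_path).write_text(
        json.dumps(
            {"voxel_size_um": volume.voxel_size_um, "labels": volume.label_map},
            indent=2,
        )
    )


def load_labeled_volume(
    tiff_path: str | Path, sidecar_path: str | Path | None = None
) -> LabeledVolume:
    """Read a label stack written by :func:`save_labeled_volume`."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    labels = tifffile.imread(tiff_path)
    return LabeledVolume(
        labels=np.asarray(labels),
        voxel_size_um=float(meta["voxel_size_um"]),
        label_map={str(k): int(v) for k, v in meta["labels"].items()},
    )
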