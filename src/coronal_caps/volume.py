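"""3D brain volume container and NIfTI-1 I/O.

The volume is the unit that flows through the whole preprocessing chain:
quality control, brain extraction, spatial normalization, intensity
normalization and coronal grid construction. Axes follow the fixed
anatomical convention x = left-right, y = posterior-anterior,
z = inferior-superior; ``origin`` marks the anterior-commissure analogue
in voxel coordinates, and coronal slice offsets are millimetres along y
relative to it (negative = posterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

MIN_DIM = 16


@dataclass
class BrainVolume:
    """A 3D intensity array with voxel spacing (mm) and anatomical origin.

    Parameters
    ----------
    data : (nx, ny, nz) float array of intensities.
    spacing : voxel edge lengths in mm, strictly positive.
    origin : voxel index of the anatomical origin; must lie inside the array.
    labels : optional congruent integer label map (phantom ground truth).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[int, int, int]
    labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < MIN_DIM:
            raise ValueError(f"all dimensions must be >= {MIN_DIM}, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.origin = tuple(int(o) for o in self.origin)
        if any(not (0 <= o < n) for o, n in zip(self.origin, self.data.shape)):
            raise ValueError(f"origin {self.origin} outside array of shape {self.data.shape}")
        if self.labels is not None and self.labels.shape != self.data.shape:
            raise ValueError("labels must be congruent with data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "BrainVolume":
        return replace(
            self,
            data=self.data.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    # --- NIfTI-1 round trip ------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write as .nii/.nii.gz; the affine encodes spacing and origin."""
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = -np.asarray(self.origin) * np.asarray(self.spacing)
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BrainVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(
            int(round(-affine[i, 3] / affine[i, i])) for i in range(3)
        )
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        origin = tuple(int(np.clip(o, 0, n - 1)) for o, n in zip(origin, data.shape))
        return cls(data=data, spacing=spacing, origin=origin)
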