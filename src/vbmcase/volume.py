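"""Minimal 3-D volume container used throughout the pipeline.

A :class:`Volume` pairs a scalar grid with a NIfTI-style affine (voxel index
-> world mm). All images, probability maps, masks and statistical maps are
carried in this form; I/O goes through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3-D scalar grid with a world affine in millimetres."""

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires a 3-D array, got shape {self.data.shape}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on this grid carrying ``data``."""
        return Volume(np.asarray(data), self.affine.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(self.to_nifti(), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), img.affine)

    @classmethod
    def from_voxel_size(cls, data: np.ndarray, voxel_size: float | tuple[float, float, float]) -> "Volume":
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        return cls(data, affine)
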