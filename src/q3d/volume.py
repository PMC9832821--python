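"""Two-channel 3D image container and volume I/O.

Coordinate convention (repo-wide): 0-based voxel indices; voxel ``i`` along an
axis spans the half-open world interval ``[origin + i*s, origin + (i+1)*s)``
micrometres, where ``s`` is the voxel size on that axis.  Voxel *centers* sit
at ``origin + (i + 0.5)*s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile


@dataclass
class ImageVolume:
    """A two-channel acquisition volume.

    Channel ``q`` is the 498-520 nm (qFTAA, mature-core) emission band and
    channel ``h`` the 565-605 nm (hFTAA, whole-plaque) band.  Both share a
    voxel grid; the hFTAA channel drives plaque detection.

    Parameters
    ----------
    q, h : ndarray, 3D
        Per-channel intensity grids with identical shape.
    voxel_size : tuple of float
        Micrometres per voxel along each axis.  The light-sheet default is
        anisotropic (3.26, 3.26, 3.0).
    origin : tuple of float
        World offset of the grid corner in micrometres.
    """

    q: np.ndarray
    h: np.ndarray
    voxel_size: tuple[float, float, float] = (3.26, 3.26, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q)
        self.h = np.asarray(self.h)
        if self.q.ndim != 3 or self.h.ndim != 3:
            raise ValueError("channels must be 3D arrays")
        if self.q.shape != self.h.shape:
            raise ValueError(
                f"channel shape mismatch: q {self.q.shape} vs h {self.h.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.h.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return float(np.prod(self.voxel_size))

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (um) of the centers of the given (N, 3) voxel indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.array(self.voxel_size) + np.array(self.origin) + 0.5 * np.array(self.voxel_size)

    # ---- I/O -------------------------------------------------------------

    def to_tiff(self, q_path: str | Path, h_path: str | Path) -> None:
        """Write each channel as a multi-page TIFF (pages along axis 0)."""
        res_kw = dict(
            resolution=(1e4 / self.voxel_size[1], 1e4 / self.voxel_size[2]),
            metadata={"spacing": self.voxel_size[0], "unit": "um"},
        )
        tifffile.imwrite(str(q_path), np.asarray(self.q, dtype=np.float32), **res_kw)
        tifffile.imwrite(str(h_path), np.asarray(self.h, dtype=np.float32), **res_kw)

    @classmethod
    def from_tiff(
        cls,
        q_path: str | Path,
        h_path: str | Path,
        voxel_size: tuple[float, float, float] = (3.26, 3.26, 3.0),
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "ImageVolume":
        return cls(
            q=tifffile.imread(str(q_path)),
            h=tifffile.imread(str(h_path)),
            voxel_size=voxel_size,
            origin=origin,
        )

    def to_nifti(self, q_path: str | Path, h_path: str | Path) -> None:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.q, dtype=np.float32), aff), str(q_path))
        nib.save(nib.Nifti1Image(np.asarray(self.h, dtype=np.float32), aff), str(h_path))

    @classmethod
    def from_nifti(cls, q_path: str | Path, h_path: str | Path) -> "ImageVolume":
        iq, ih = nib.load(str(q_path)), nib.load(str(h_path))
        aff = iq.affine
        return cls(
            q=np.asarray(iq.dataobj),
            h=np.asarray(ih.dataobj),
            voxel_size=tuple(np.abs(np.diag(aff)[:3])),
            origin=tuple(aff[:3, 3]),
        )


def save_grid_nifti(grid: np.ndarray, path: str | Path, spacing: float = 25.0) -> None:
    """Write a scalar atlas-grid volume as NIfTI with isotropic spacing (um)."""
    aff = np.diag([spacing, spacing, spacing, 1.0])
    data = np.asarray(grid)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, aff), str(path))


def load_grid_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(abs(img.affine[0, 0]))
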