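"""Atlas-space mapping: downsampling, point transforms, region assignment.

The reference space is a 25-um isotropic labeled grid (Allen-style).  The
registration itself (affine + b-spline estimation) is an input, not computed
here: transforms arrive as a 4x4 affine in micrometre world coordinates plus
an optional dense displacement field sampled on the atlas grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import ImageVolume

ATLAS_SPACING_UM = 25.0


@dataclass
class AtlasVolume:
    """Labeled anatomical reference volume on the isotropic atlas grid.

    ``labels`` holds one integer region id per voxel (0 = outside brain);
    ``region_table`` maps each nonzero label to an acronym and full name.
    """

    labels: np.ndarray
    region_table: pd.DataFrame  # columns: label, acronym, name
    spacing: float = ATLAS_SPACING_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 3D integer grid")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.region_table["label"].astype(int))
        if not present <= known:
            raise ValueError(f"labels missing from region_table: {sorted(present - known)}")

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region_name(self, label: int) -> str:
        row = self.region_table.loc[self.region_table["label"] == label]
        return str(row["name"].iloc[0]) if len(row) else "outside"

    def save(self, nifti_path: str | Path, table_path: str | Path) -> None:
        aff = np.diag([self.spacing] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), aff), str(nifti_path))
        self.region_table.to_csv(table_path, index=False)

    @classmethod
    def load(cls, nifti_path: str | Path, table_path: str | Path) -> "AtlasVolume":
        img = nib.load(str(nifti_path))
        return cls(
            labels=np.asarray(img.dataobj).astype(np.int32),
            region_table=pd.read_csv(table_path),
            spacing=float(abs(img.affine[0, 0])),
        )


@dataclass
class SpatialTransform:
    """Acquisition-to-atlas spatial map: affine, then optional dense warp.

    The affine is a 4x4 matrix acting on micrometre coordinates.  The
    displacement field, when present, is sampled at atlas voxel centers and
    stores micrometre offsets (shape ``atlas_shape + (3,)``); it is applied by
    trilinear interpolation at the affinely mapped position.
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    displacement_field: np.ndarray | None = None
    spacing: float = ATLAS_SPACING_UM

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.displacement_field is not None:
            self.displacement_field = np.asarray(self.displacement_field, dtype=float)
            if self.displacement_field.ndim != 4 or self.displacement_field.shape[-1] != 3:
                raise ValueError("displacement field must have shape (X, Y, Z, 3)")
            if not np.all(np.isfinite(self.displacement_field)):
                raise ValueError("displacement field contains non-finite values")

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls()

    @classmethod
    def translation(cls, offset_um) -> "SpatialTransform":
        aff = np.eye(4)
        aff[:3, 3] = offset_um
        return cls(affine=aff)

    def inverse_affine(self) -> "SpatialTransform":
        """Inverse of the affine part (the warp is not invertible in closed form)."""
        return SpatialTransform(affine=np.linalg.inv(self.affine), spacing=self.spacing)

    @property
    def jacobian_summary(self) -> float:
        """Mean Jacobian determinant of the displacement field (1.0 if none)."""
        if self.displacement_field is None:
            return 1.0
        grads = [
            np.gradient(self.displacement_field[..., i], self.spacing, axis=j)
            for i in range(3)
            for j in range(3)
        ]
        J = np.stack(grads, axis=-1).reshape(self.displacement_field.shape[:3] + (3, 3))
        return float(np.linalg.det(np.eye(3) + J).mean())

    def save_json(self, path: str | Path) -> None:
        payload = {"affine": self.affine.tolist(), "spacing": self.spacing}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load_json(cls, path: str | Path, displacement_path: str | Path | None = None) -> "SpatialTransform":
        payload = json.loads(Path(path).read_text())
        disp = None
        if displacement_path is not None:
            disp = np.asarray(nib.load(str(displacement_path)).dataobj)
        return cls(affine=np.asarray(payload["affine"]), displacement_field=disp,
                   spacing=float(payload.get("spacing", ATLAS_SPACING_UM)))


def downsample_volume(
    volume: ImageVolume, target_spacing: float = ATLAS_SPACING_UM
) -> ImageVolume:
    """Block-mean downsample both channels to an isotropic target grid.

    Each source voxel is assigned to the target voxel containing its center
    (half-open convention); the output value is the mean of its member source
    voxels.  This reduces exactly to a block mean when the target spacing is
    an integer multiple of the source spacing, and remains well defined for
    the anisotropic light-sheet grid (3.26 x 3.26 x 3.0 um -> 25 um).
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if any(target_spacing < s for s in volume.voxel_size):
        raise ValueError("target spacing must be >= source spacing on every axis")

    src_shape = np.array(volume.shape)
    vs = np.array(volume.voxel_size)
    # last output voxel is the one holding the last source voxel center, so
    # every output voxel averages at least one source voxel
    out_shape = ((src_shape - 0.5) * vs // target_spacing).astype(int) + 1

    # target bin index of each source voxel center, per axis
    axis_bins = [
        np.minimum(((np.arange(src_shape[a]) + 0.5) * vs[a] // target_spacing).astype(int),
                   out_shape[a] - 1)
        for a in range(3)
    ]
    flat_idx = (
        axis_bins[0][:, None, None] * (out_shape[1] * out_shape[2])
        + axis_bins[1][None, :, None] * out_shape[2]
        + axis_bins[2][None, None, :]
    ).ravel()
    counts = np.bincount(flat_idx, minlength=np.prod(out_shape)).astype(float)

    def _block_mean(channel: np.ndarray) -> np.ndarray:
        sums = np.bincount(flat_idx, weights=channel.ravel().astype(float),
                           minlength=np.prod(out_shape))
        with np.errstate(invalid="ignore"):
            out = sums / counts
        return out.reshape(tuple(out_shape))

    return ImageVolume(
        q=_block_mean(volume.q),
        h=_block_mean(volume.h),
        voxel_size=(target_spacing,) * 3,
        origin=volume.origin,
    )


def apply_transform_to_points(
    points_um: np.ndarray, transform: SpatialTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Map (N, 3) world points (um) through affine then displacement warp.

    Returns ``(mapped_points, valid)``.  Points whose affinely mapped position
    falls outside the displacement-field domain are flagged invalid (their
    affine-mapped coordinates are still returned); callers exclude them
    downstream and report the count.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (N, 3)")
    homo = np.hstack([pts, np.ones((len(pts), 1))])
    mapped = (transform.affine @ homo.T).T[:, :3]
    valid = np.ones(len(pts), dtype=bool)

    disp = transform.displacement_field
    if disp is not None:
        # field samples live at voxel centers: grid coordinate = x/s - 0.5
        grid_coords = mapped / transform.spacing - 0.5
        upper = np.array(disp.shape[:3]) - 1
        valid = np.all((grid_coords >= 0) & (grid_coords <= upper), axis=1)
        offsets = np.full_like(mapped, np.nan)
        for i in range(3):
            offsets[valid, i] = ndimage.map_coordinates(
                disp[..., i], grid_coords[valid].T, order=1, mode="nearest"
            )
        mapped = np.where(valid[:, None], mapped + np.nan_to_num(offsets), mapped)
    return mapped, valid


def assign_regions(points_um: np.ndarray, atlas: AtlasVolume) -> np.ndarray:
    """Anatomical label for each (N, 3) atlas-space point (um).

    Uses the half-open voxel convention: a coordinate exactly on a voxel
    boundary belongs to the higher-index voxel.  Points outside the grid or
    on label-0 voxels get label 0 (outside brain).
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    idx = np.floor(pts / atlas.spacing).astype(int)
    inb = np.all((idx >= 0) & (idx < np.array(atlas.shape)), axis=1)
    labels = np.zeros(len(pts), dtype=atlas.labels.dtype)
    labels[inb] = atlas.labels[tuple(idx[inb].T)]
    return labels


def make_toy_atlas(
    shape: tuple[int, int, int] = (64, 64, 48),
    semi_axes: tuple[float, float, float] | None = None,
    spacing: float = ATLAS_SPACING_UM,
) -> AtlasVolume:
    """Small synthetic labeled atlas: an ellipsoid brain split into 9 regions.

    Eight octants around the center plus a central core, standing in for the
    anatomical parcellation used downstream (the real atlas has 134 regions;
    region count is irrelevant to the mechanics being exercised).
    """
    shp = np.array(shape)
    if semi_axes is None:
        semi_axes = tuple(shp * 0.45)
    center = (shp - 1) / 2.0
    idx = np.indices(shape, dtype=float)
    e = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    mask = e <= 1.0

    octant = (
        (idx[0] >= center[0]).astype(int) * 4
        + (idx[1] >= center[1]).astype(int) * 2
        + (idx[2] >= center[2]).astype(int)
        + 1
    )
    labels = np.where(mask, octant, 0)
    labels[e <= 0.15] = 9  # central core region
    rows = [
        {"label": i, "acronym": f"OCT{i}", "name": f"octant region {i}"} for i in range(1, 9)
    ] + [{"label": 9, "acronym": "CORE", "name": "central core"}]
    return AtlasVolume(labels=labels.astype(np.int32), region_table=pd.DataFrame(rows),
                       spacing=spacing)
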