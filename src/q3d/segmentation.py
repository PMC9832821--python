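"""Plaque segmentation: voxel classification, components, per-plaque metrics.

The hFTAA (565-605 nm) channel at acquisition resolution locates the
aggregates; connected components of the binarized volume are the plaques.
Components below a global volume threshold are discarded as noise.  Plaque
maturity is the ratio of the qFTAA peak to the hFTAA peak: the qFTAA dye
binds dense mature cores, so a higher ratio marks a more compact, older
plaque.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .volume import ImageVolume

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

PLAQUE_COLUMNS = ["id", "x_um", "y_um", "z_um", "n_voxels", "volume_um3",
                  "peak_q", "peak_h", "maturity", "maturity_defined"]


@dataclass
class SegmentationConfig:
    """Knobs of the segmentation stage.

    volume_threshold : um^3
        Global noise floor; components below it are dropped.  Default 200
        um^3 (~6 acquisition voxels), below any plausible plaque.
    connectivity : 6 | 18 | 26
        Voxel adjacency for component labeling; 26 suits compact blobs.
    peak_lookup : "max_in_mask" | "at_center_voxel"
        Where per-channel peak intensity is read: the component-wise maximum
        (robust to hollow cores) or the voxel nearest the center of mass.
    """

    volume_threshold: float = 200.0
    connectivity: int = 26
    peak_lookup: Literal["max_in_mask", "at_center_voxel"] = "max_in_mask"

    def __post_init__(self) -> None:
        if self.volume_threshold < 0:
            raise ValueError("volume_threshold must be >= 0")
        if self.connectivity not in CONNECTIVITY_STRUCTS:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.peak_lookup not in ("max_in_mask", "at_center_voxel"):
            raise ValueError(f"unknown peak_lookup {self.peak_lookup!r}")


class ThresholdClassifier:
    """Classify voxels as plaque where hFTAA intensity exceeds a threshold."""

    kind = "threshold"

    def __init__(self, threshold: float):
        self.threshold = float(threshold)

    def classify(self, volume: ImageVolume) -> np.ndarray:
        return np.asarray(volume.h) > self.threshold


def _feature_stack(channel: np.ndarray) -> np.ndarray:
    """Per-voxel features: raw intensity plus Gaussian-smoothed intensity at
    two scales (sigma 1 and 2 voxels, edge-padded)."""
    x = np.asarray(channel, dtype=np.float32)
    feats = [x,
             ndimage.gaussian_filter(x, 1.0, mode="nearest"),
             ndimage.gaussian_filter(x, 2.0, mode="nearest")]
    return np.stack([f.ravel() for f in feats], axis=1)


class RandomForestVoxelClassifier:
    """Random-forest voxel classifier trained on labeled volumes.

    A lightweight stand-in for an interactively trained Ilastik project:
    the feature bank is raw + multi-scale smoothed intensity of the hFTAA
    channel, and training labels come from synthetic fixtures with known
    plaque support rather than manual annotation.
    """

    kind = "trained"

    def __init__(self, n_estimators: int = 50, max_voxels_per_class: int = 20000,
                 random_state: int = 0):
        self.model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        )
        self.max_voxels_per_class = max_voxels_per_class
        self.random_state = random_state
        self._fitted = False

    def fit(self, volumes: list[ImageVolume], label_masks: list[np.ndarray]
            ) -> "RandomForestVoxelClassifier":
        rng = np.random.default_rng(self.random_state)
        Xs, ys = [], []
        for vol, labels in zip(volumes, label_masks):
            feats = _feature_stack(vol.h)
            y = np.asarray(labels).astype(bool).ravel()
            for cls in (False, True):
                idx = np.flatnonzero(y == cls)
                if len(idx) > self.max_voxels_per_class:
                    idx = rng.choice(idx, self.max_voxels_per_class, replace=False)
                Xs.append(feats[idx])
                ys.append(np.full(len(idx), cls))
        self.model.fit(np.concatenate(Xs), np.concatenate(ys))
        self._fitted = True
        return self

    def classify(self, volume: ImageVolume) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier has not been fitted")
        pred = self.model.predict(_feature_stack(volume.h))
        return pred.reshape(volume.shape).astype(bool)


def classify_voxels(volume: ImageVolume, classifier) -> np.ndarray:
    """Binary plaque mask for the volume (driven by the hFTAA channel)."""
    mask = classifier.classify(volume)
    if mask.shape != volume.shape:
        raise ValueError("classifier returned a mask of the wrong shape")
    return mask.astype(bool)


def connected_components(mask: np.ndarray, connectivity: int = 26
                         ) -> tuple[np.ndarray, int]:
    """Label connected foreground components; returns (labels 1..K, K)."""
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n = ndimage.label(np.asarray(mask).astype(bool),
                              structure=CONNECTIVITY_STRUCTS[connectivity])
    return labels, int(n)


def measure_plaques(
    labels: np.ndarray,
    volume: ImageVolume,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Per-plaque record table from a labeled component grid.

    volume = voxel count x voxel volume; components below the volume
    threshold are dropped.  maturity = peak_q / peak_h; components with a
    non-positive hFTAA peak keep their count/size but are flagged
    ``maturity_defined=False`` and excluded from maturity aggregation.
    """
    config = config or SegmentationConfig()
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame(columns=PLAQUE_COLUMNS)

    ids = np.arange(1, n + 1)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    voxvol = volume.voxel_volume
    keep = counts * voxvol >= config.volume_threshold
    ids = ids[keep]
    if len(ids) == 0:
        return pd.DataFrame(columns=PLAQUE_COLUMNS)

    com = np.array(ndimage.center_of_mass(np.ones_like(labels), labels, ids))
    com_um = volume.voxel_centers_um(com)

    if config.peak_lookup == "max_in_mask":
        peak_q = ndimage.labeled_comprehension(volume.q, labels, ids, np.max, float, np.nan)
        peak_h = ndimage.labeled_comprehension(volume.h, labels, ids, np.max, float, np.nan)
    else:
        cv = np.clip(np.round(com).astype(int), 0, np.array(labels.shape) - 1)
        peak_q = np.asarray(volume.q)[tuple(cv.T)]
        peak_h = np.asarray(volume.h)[tuple(cv.T)]

    defined = peak_h > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        maturity = np.where(defined, peak_q / np.where(defined, peak_h, 1.0), np.nan)

    return pd.DataFrame({
        "id": np.arange(1, len(ids) + 1),
        "x_um": com_um[:, 0], "y_um": com_um[:, 1], "z_um": com_um[:, 2],
        "n_voxels": counts[keep],
        "volume_um3": counts[keep] * voxvol,
        "peak_q": peak_q, "peak_h": peak_h,
        "maturity": maturity,
        "maturity_defined": defined,
    })


def segment_volume(
    volume: ImageVolume,
    classifier,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Full segmentation stage: classify, label, filter, measure."""
    config = config or SegmentationConfig()
    mask = classify_voxels(volume, classifier)
    labels, _ = connected_components(mask, config.connectivity)
    return measure_plaques(labels, volume, config)
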