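"""Atlas-grid heatmaps, spherical smoothing, group statistics, SAV maps.

Per brain, plaques are binned onto the 25-um atlas grid into three metric
heatmaps (count, mean size, mean maturity).  Maps are smoothed by a spherical
ROI (default diameter 15 voxels = 375 um): counts are summed over the ROI,
means become plaque-weighted means over the ROI.  Treated-vs-control voxel
maps are compared with a two-sided t-test (Welch by default), adjusted with
Benjamini-Hochberg over the tested voxels of one metric, and binarized at
alpha 0.05 or 0.10 into Significantly-Altered-Voxel (SAV) maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .atlas import ATLAS_SPACING_UM, AtlasVolume, assign_regions

METRICS = ("count", "mean_size", "mean_maturity")


@dataclass
class SmoothingKernel:
    """Spherical lattice kernel: all integer offsets within diameter/2 of the
    origin (center-to-center Euclidean distance)."""

    diameter_voxels: int = 15

    def __post_init__(self) -> None:
        if self.diameter_voxels < 1:
            raise ValueError("diameter must be >= 1")
        r = self.diameter_voxels / 2.0
        half = int(np.floor(r))
        g = np.arange(-half, half + 1)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        self.footprint = (X ** 2 + Y ** 2 + Z ** 2) <= r ** 2

    @property
    def size(self) -> int:
        """Number of lattice offsets in the sphere (1791 at diameter 15)."""
        return int(self.footprint.sum())


@dataclass
class MetricHeatmap:
    """One brain's per-voxel metric grid on the atlas lattice.

    For mean metrics, ``weights`` carries the per-voxel plaque count that the
    mean is over (needed for plaque-weighted ROI smoothing); voxels with no
    contributing plaque are NaN.
    """

    grid: np.ndarray
    metric: str
    brain_id: str = ""
    smoothed: bool = False
    kernel: SmoothingKernel | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")


@dataclass
class GroupComparison:
    """Voxel-wise two-group test result for one metric."""

    p_map: np.ndarray
    p_adj_map: np.ndarray
    tested_mask: np.ndarray
    n_treated: int
    n_control: int
    metric: str
    t_map: np.ndarray | None = None


@dataclass
class SAVMap:
    grid: np.ndarray  # bool
    threshold: float
    metric: str
    cohort: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)

    @property
    def count(self) -> int:
        return int(self.grid.sum())


def aggregate_to_voxels(
    plaques: pd.DataFrame,
    grid_shape: tuple[int, int, int],
    brain_id: str = "",
    spacing: float = ATLAS_SPACING_UM,
) -> dict[str, MetricHeatmap]:
    """Bin atlas-space plaque records into count / mean-size / mean-maturity
    heatmaps.  Mean maps are NaN where no plaque (or, for maturity, no plaque
    with a defined ratio) falls in the voxel."""
    n = int(np.prod(grid_shape))
    if len(plaques):
        idx = np.floor(plaques[["x_um", "y_um", "z_um"]].to_numpy() / spacing).astype(int)
        inb = np.all((idx >= 0) & (idx < np.array(grid_shape)), axis=1)
        plq = plaques.loc[inb]
        flat = np.ravel_multi_index(tuple(idx[inb].T), grid_shape)
    else:
        plq = plaques
        flat = np.array([], dtype=int)

    count = np.bincount(flat, minlength=n).astype(float)

    def _mean_map(values: np.ndarray, sel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w = np.bincount(flat[sel], minlength=n).astype(float)
        s = np.bincount(flat[sel], weights=values[sel], minlength=n)
        out = np.full(n, np.nan)
        out[w > 0] = s[w > 0] / w[w > 0]
        return out, w

    if len(plq):
        vols = plq["volume_um3"].to_numpy(dtype=float)
        mat = plq["maturity"].to_numpy(dtype=float)
        mat_ok = np.isfinite(mat)
        if "maturity_defined" in plq.columns:
            mat_ok &= plq["maturity_defined"].to_numpy(dtype=bool)
        size_map, size_w = _mean_map(vols, np.ones(len(plq), dtype=bool))
        mat_map, mat_w = _mean_map(np.nan_to_num(mat), mat_ok)
    else:
        size_map = np.full(n, np.nan); size_w = np.zeros(n)
        mat_map = np.full(n, np.nan); mat_w = np.zeros(n)

    shp = tuple(grid_shape)
    return {
        "count": MetricHeatmap(count.reshape(shp), "count", brain_id),
        "mean_size": MetricHeatmap(size_map.reshape(shp), "mean_size", brain_id,
                                   weights=size_w.reshape(shp)),
        "mean_maturity": MetricHeatmap(mat_map.reshape(shp), "mean_maturity", brain_id,
                                       weights=mat_w.reshape(shp)),
    }


def smooth_spherical(hm: MetricHeatmap, kernel: SmoothingKernel | None = None
                     ) -> MetricHeatmap:
    """Spherical-ROI smoothing.

    Count maps: the smoothed value is the plaque count summed over the ROI,
    truncated at the volume boundary (zero-padded convolution).  Mean maps:
    plaque-weighted mean over the ROI — sum(metric x count) / sum(count) —
    NaN where the ROI holds no plaque.
    """
    kernel = kernel or SmoothingKernel()
    if hm.smoothed:
        raise ValueError("heatmap already smoothed")
    if any(k > s for k, s in zip(kernel.footprint.shape, hm.grid.shape)):
        raise ValueError("kernel larger than volume")
    foot = kernel.footprint.astype(float)

    if hm.metric == "count":
        out = signal.fftconvolve(hm.grid, foot, mode="same")
        out = np.maximum(out, 0.0)
        return MetricHeatmap(out, hm.metric, hm.brain_id, smoothed=True, kernel=kernel)

    if hm.weights is None:
        raise ValueError("mean heatmap lacks per-voxel plaque weights")
    num = signal.fftconvolve(np.nan_to_num(hm.grid) * hm.weights, foot, mode="same")
    den = signal.fftconvolve(hm.weights, foot, mode="same")
    out = np.full_like(num, np.nan)
    ok = den > 0.5  # fp-safe: weights are integer counts
    out[ok] = num[ok] / den[ok]
    return MetricHeatmap(out, hm.metric, hm.brain_id, smoothed=True, kernel=kernel,
                         weights=den)


def voxelwise_ttest(
    treated: list[MetricHeatmap],
    control: list[MetricHeatmap],
    equal_var: bool = False,
    brain_mask: np.ndarray | None = None,
) -> GroupComparison:
    """Two-sided t-test at every voxel across groups (Welch by default).

    A voxel is tested when each group has >= 2 finite values there and the
    two groups are not jointly constant; untested voxels are NaN in the p
    map and excluded from the BH family.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 brains per group")
    shapes = {hm.grid.shape for hm in treated + control}
    if len(shapes) != 1:
        raise ValueError("heatmap grids mismatch")
    metric = treated[0].metric
    T = np.stack([hm.grid for hm in treated])
    C = np.stack([hm.grid for hm in control])

    n_t = np.isfinite(T).sum(axis=0)
    n_c = np.isfinite(C).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var_t = np.nanvar(T, axis=0)
        var_c = np.nanvar(C, axis=0)
    tested = (n_t >= 2) & (n_c >= 2) & ~((var_t == 0) & (var_c == 0))
    if brain_mask is not None:
        tested &= np.asarray(brain_mask).astype(bool)

    p_map = np.full(T.shape[1:], np.nan)
    t_map = np.full(T.shape[1:], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(T[:, tested], C[:, tested], axis=0,
                              equal_var=equal_var, nan_policy="omit")
    p_map[tested] = res.pvalue
    t_map[tested] = res.statistic
    # degenerate voxels (identical constant groups) slip scipy as NaN; drop them
    bad = tested & ~np.isfinite(p_map)
    tested &= ~bad
    p_map[bad] = np.nan

    p_adj = adjust_bh(p_map, tested)
    return GroupComparison(p_map=p_map, p_adj_map=p_adj, tested_mask=tested,
                           n_treated=len(treated), n_control=len(control),
                           metric=metric, t_map=t_map)


def adjust_bh(p_map: np.ndarray, tested_mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over the tested voxels.

    Standard step-up: p_adj(i) = min_{j >= i} min(1, m p_(j) / j) over the
    family of tested voxels only; untested voxels stay NaN.
    """
    p_map = np.asarray(p_map, dtype=float)
    tested = np.asarray(tested_mask).astype(bool)
    p = p_map[tested]
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values outside [0, 1] on the tested mask")
    out = np.full(p_map.shape, np.nan)
    if p.size:
        out[tested] = multipletests(p, method="fdr_bh")[1]
    return out


def binarize_sav(comparison: GroupComparison, alpha: float = 0.05,
                 cohort: str = "") -> SAVMap:
    """SAV map: tested voxels whose BH-adjusted p falls below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        grid = comparison.tested_mask & (comparison.p_adj_map < alpha)
    return SAVMap(grid=grid, threshold=alpha, metric=comparison.metric, cohort=cohort)


def region_stats(
    brains: list[tuple[str, str, pd.DataFrame]],
    atlas: AtlasVolume,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-region group comparison of plaque density, mean size, maturity.

    ``brains`` is a list of (brain_id, group, plaque table in atlas um).
    Density is plaque count per cubic millimetre of region; means are over
    the plaques in the region.  Per metric family, a two-sided t-test across
    groups plus BH adjustment over regions.  Regions with no plaques in any
    brain are left NaN.
    """
    groups = {g for _, g, _ in brains}
    if groups != {"control", "treated"}:
        raise ValueError("groups must be exactly {'control', 'treated'}")

    region_labels = atlas.region_table["label"].astype(int).tolist()
    vox_mm3 = (atlas.spacing / 1000.0) ** 3
    region_vol = {
        lab: float((atlas.labels == lab).sum()) * vox_mm3 for lab in region_labels
    }

    per_brain: dict[str, dict[int, dict[str, float]]] = {}
    brain_group = {}
    for brain_id, group, plq in brains:
        brain_group[brain_id] = group
        labels = assign_regions(plq[["x_um", "y_um", "z_um"]].to_numpy(), atlas) \
            if len(plq) else np.array([], dtype=int)
        stats_b = {}
        for lab in region_labels:
            sel = labels == lab
            sub = plq.loc[sel] if len(plq) else plq
            mat = sub["maturity"].to_numpy(dtype=float) if len(sub) else np.array([])
            mat = mat[np.isfinite(mat)]
            stats_b[lab] = {
                "density": len(sub) / region_vol[lab] if region_vol[lab] > 0 else np.nan,
                "mean_size": float(sub["volume_um3"].mean()) if len(sub) else np.nan,
                "mean_maturity": float(mat.mean()) if len(mat) else np.nan,
            }
        per_brain[brain_id] = stats_b

    rows = []
    for lab in region_labels:
        row = {"label": lab,
               "acronym": atlas.region_table.set_index("label")["acronym"].get(lab, ""),
               "n_voxels": int((atlas.labels == lab).sum())}
        for metric in ("density", "mean_size", "mean_maturity"):
            vals = {g: [] for g in ("control", "treated")}
            for brain_id, stats_b in per_brain.items():
                v = stats_b[lab][metric]
                if np.isfinite(v):
                    vals[brain_group[brain_id]].append(v)
            t_vals, c_vals = np.array(vals["treated"]), np.array(vals["control"])
            row[f"{metric}_control"] = c_vals.mean() if len(c_vals) else np.nan
            row[f"{metric}_treated"] = t_vals.mean() if len(t_vals) else np.nan
            if len(t_vals) >= 2 and len(c_vals) >= 2 and (t_vals.var() + c_vals.var()) > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    p = stats.ttest_ind(t_vals, c_vals, equal_var=equal_var).pvalue
            else:
                p = np.nan
            row[f"{metric}_p"] = p
        rows.append(row)
    df = pd.DataFrame(rows)

    for metric in ("density", "mean_size", "mean_maturity"):
        p = df[f"{metric}_p"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        adj = np.full(len(p), np.nan)
        if ok.sum():
            adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
        df[f"{metric}_p_adj"] = adj
    # the anatomical-region multiple-testing family is a repo choice: both raw
    # and BH-adjusted p are reported
    df.attrs["p_adjustment"] = "benjamini-hochberg per metric family over regions"
    return df
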