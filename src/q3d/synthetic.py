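"""Seeded synthetic brains, cohorts, atlases, and expression tables.

Every downstream stage of the pipeline is exercised on phantoms generated
here: two-channel volumes with spherical plaques of known position, size and
maturity; cohorts of control/treated brains with effects planted inside known
spherical regions; and spot-table expression atlases with a known subset of
genes tied to a reference map.  All generators are bit-reproducible given
their spec (seeds flow through ``numpy.random.SeedSequence`` spawning).

The phantoms emulate the plaque fields of an APP/PS1 amyloidosis brain:
plaque radii are log-normal (the field offers no canonical size law; the
log-normal is a modelling choice), maturity (qFTAA/hFTAA peak ratio) drifts
along a spatial gradient, and treated cohorts carry multiplicative effects on
count, size, or maturity confined to spherical atlas regions — mirroring the
regiospecific drug effects the statistics stages are meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json
import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import ATLAS_SPACING_UM
from .expression import ExpressionAtlas
from .volume import ImageVolume

GT_COLUMNS = ["id", "x_um", "y_um", "z_um", "radius_um", "volume_um3",
              "peak_q", "peak_h", "maturity"]


@dataclass
class PhantomSpec:
    """Generative description of one synthetic two-channel brain.

    Plaques are uniform-intensity spheres (optionally edge-blurred with a
    Gaussian of ``edge_sigma`` acquisition voxels) on a constant background
    with additive Gaussian noise.  Radii are log-normal in micrometres;
    ``maturity_base``/``maturity_gradient`` define a linear-in-position
    expected qFTAA/hFTAA peak ratio, clipped to stay positive.
    """

    shape: tuple[int, int, int] = (160, 160, 120)
    voxel_size: tuple[float, float, float] = (3.26, 3.26, 3.0)
    brain_semi_axes: tuple[float, float, float] | None = None  # voxels; default 0.45*shape
    n_plaques: int = 100
    radius_log_mean: float = math.log(8.0)   # ln(um): median radius 8 um
    radius_log_sigma: float = 0.35
    maturity_base: float = 0.45
    maturity_gradient: tuple[float, float, float] = (0.0, 0.0, 0.3)  # per unit normalized axis
    peak_h_mean: float = 1000.0
    peak_h_cv: float = 0.15
    background: tuple[float, float] = (100.0, 100.0)   # (q, h)
    noise_sigma: tuple[float, float] = (20.0, 20.0)    # (q, h)
    edge_sigma: float = 1.0              # voxels; 0 = sharp spheres
    min_separation_factor: float = 1.5   # x (r_i + r_j) center distance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brain_semi_axes is None:
            self.brain_semi_axes = tuple(0.45 * s for s in self.shape)
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be >= 0")
        if any(s < 0 for s in self.noise_sigma) or self.edge_sigma < 0:
            raise ValueError("noise_sigma and edge_sigma must be >= 0")
        if self.radius_log_sigma < 0 or self.peak_h_cv < 0:
            raise ValueError("dispersions must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        for k in ("shape", "voxel_size", "brain_semi_axes", "maturity_gradient",
                  "background", "noise_sigma"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class EffectRegionSpec:
    """A spherical atlas-space region where treatment modifies one metric.

    ``effect_size`` is a multiplicative factor applied inside the region for
    treated brains only: for ``count`` it scales the expected number of
    plaques (thinning when < 1), for ``size`` it scales radii, for
    ``maturity`` it scales the qFTAA peak.  1.0 means no effect.
    """

    center_vox: tuple[float, float, float]
    radius_vox: float
    affected_metric: str  # count | size | maturity
    effect_size: float

    def __post_init__(self) -> None:
        if self.radius_vox <= 0:
            raise ValueError("radius must be > 0")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.affected_metric not in ("count", "size", "maturity"):
            raise ValueError(f"unknown metric {self.affected_metric!r}")

    def contains(self, points_um: np.ndarray, spacing: float = ATLAS_SPACING_UM) -> np.ndarray:
        pts_vox = np.atleast_2d(points_um) / spacing
        d = pts_vox - np.array(self.center_vox)
        return (d ** 2).sum(axis=1) <= self.radius_vox ** 2


@dataclass
class CohortSpec:
    """Two-group synthetic study: control brains plus treated brains with
    planted effect regions, and log-normal inter-brain count variability."""

    n_control: int = 5
    n_treated: int = 5
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    effects: list[EffectRegionSpec] = field(default_factory=list)
    inter_brain_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("need at least one brain per group")
        if self.inter_brain_cv < 0:
            raise ValueError("inter_brain_cv must be >= 0")


@dataclass
class SyntheticBrain:
    brain_id: str
    group: str  # control | treated
    truth: pd.DataFrame
    image: ImageVolume | None = None


@dataclass
class SyntheticExpressionSpec:
    """Scaled-down stand-in for a whole-brain spatial transcriptomics table
    (the real resource spans ~23k genes over ~34k locations)."""

    n_genes: int = 500
    n_spots: int = 2000
    spot_spacing_vox: int = 1
    n_correlated: int = 1
    base_rate: float = 20.0      # mean counts per spot for a typical gene
    dispersion: float = 0.1      # gamma-Poisson overdispersion; 0 = pure Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_correlated > self.n_genes:
            raise ValueError("n_correlated cannot exceed n_genes")
        if self.dispersion < 0 or self.base_rate <= 0:
            raise ValueError("invalid noise model parameters")


# ---------------------------------------------------------------------------
# plaque field sampling

def _ellipsoid_center(shape, semi_axes, voxel_size):
    c_vox = (np.array(shape) - 1) / 2.0
    center_um = (c_vox + 0.5) * np.array(voxel_size)
    semi_um = np.array(semi_axes) * np.array(voxel_size)
    return center_um, semi_um


def _sample_centers(
    rng: np.random.Generator,
    spec: PhantomSpec,
    radii_um: np.ndarray,
    enforce_separation: bool,
) -> np.ndarray:
    """Rejection-sample plaque centers inside the brain ellipsoid.

    Each sphere must fit fully inside the mask; with separation enforced,
    center distances must exceed ``min_separation_factor * (r_i + r_j)``.
    """
    n = len(radii_um)
    center_um, semi_um = _ellipsoid_center(spec.shape, spec.brain_semi_axes, spec.voxel_size)
    accepted = np.empty((n, 3))
    k = 0
    attempts = 0
    max_attempts = 2000 * max(n, 1)
    while k < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} plaques inside the brain mask at the "
                f"requested separation (placed {k}); reduce n_plaques or separation"
            )
        attempts += 1
        cand = center_um + (rng.uniform(-1, 1, 3)) * semi_um
        margin = semi_um - radii_um[k]
        if np.any(margin <= 0):
            raise RuntimeError(f"plaque radius {radii_um[k]:.1f} um exceeds brain semi-axis")
        if (((cand - center_um) / margin) ** 2).sum() > 1.0:
            continue
        if enforce_separation and k > 0:
            d = np.linalg.norm(accepted[:k] - cand, axis=1)
            if np.any(d < spec.min_separation_factor * (radii_um[:k] + radii_um[k])):
                continue
        accepted[k] = cand
        k += 1
    return accepted


def sample_plaque_field(
    spec: PhantomSpec,
    rng: np.random.Generator,
    enforce_separation: bool = True,
    n_plaques: int | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth plaque table (no rasterization).

    Volumes here are analytic sphere volumes; :func:`generate_phantom`
    replaces them with exact lattice-support volumes for rendered brains.
    """
    n = spec.n_plaques if n_plaques is None else n_plaques
    if n == 0:
        return pd.DataFrame(columns=GT_COLUMNS)
    radii = np.exp(rng.normal(spec.radius_log_mean, spec.radius_log_sigma, n))
    centers = _sample_centers(rng, spec, radii, enforce_separation)

    extent = np.array(spec.shape) * np.array(spec.voxel_size)
    pos_norm = centers / extent - 0.5
    maturity = np.clip(
        spec.maturity_base + pos_norm @ np.array(spec.maturity_gradient), 0.02, None
    )
    peak_h = spec.peak_h_mean * np.exp(
        rng.normal(0, math.sqrt(math.log(1 + spec.peak_h_cv ** 2)), n)
        - 0.5 * math.log(1 + spec.peak_h_cv ** 2)
    )
    peak_q = maturity * peak_h
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "x_um": centers[:, 0], "y_um": centers[:, 1], "z_um": centers[:, 2],
        "radius_um": radii,
        "volume_um3": 4.0 / 3.0 * np.pi * radii ** 3,
        "peak_q": peak_q, "peak_h": peak_h, "maturity": maturity,
    })


# ---------------------------------------------------------------------------
# rendering

def _render(spec: PhantomSpec, truth: pd.DataFrame, rng: np.random.Generator
            ) -> tuple[ImageVolume, pd.DataFrame]:
    vs = np.array(spec.voxel_size)
    q = np.zeros(spec.shape, dtype=np.float32)
    h = np.zeros(spec.shape, dtype=np.float32)
    truth = truth.copy()
    coms = np.empty((len(truth), 3))
    vols = np.empty(len(truth))

    for i, row in enumerate(truth.itertuples(index=False)):
        c = np.array([row.x_um, row.y_um, row.z_um])
        r = row.radius_um
        lo = np.maximum(np.floor((c - r) / vs - 1).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / vs + 1).astype(int), np.array(spec.shape))
        sub = np.indices(tuple(hi - lo)).reshape(3, -1).T + lo
        centers_um = (sub + 0.5) * vs
        inside = ((centers_um - c) ** 2).sum(axis=1) <= r ** 2
        voxels = sub[inside]
        if len(voxels) == 0:  # sub-voxel plaque: keep its nearest voxel
            voxels = np.round(c / vs - 0.5).astype(int)[None, :]
        ix = tuple(voxels.T)
        h[ix] = np.maximum(h[ix], row.peak_h)
        q[ix] = np.maximum(q[ix], row.peak_q)
        coms[i] = ((voxels + 0.5) * vs).mean(axis=0)
        vols[i] = len(voxels) * float(np.prod(vs))

    if spec.edge_sigma > 0:
        q = ndimage.gaussian_filter(q, spec.edge_sigma)
        h = ndimage.gaussian_filter(h, spec.edge_sigma)
    q = q + spec.background[0]
    h = h + spec.background[1]
    if spec.noise_sigma[0] > 0:
        q = q + rng.normal(0, spec.noise_sigma[0], spec.shape).astype(np.float32)
    if spec.noise_sigma[1] > 0:
        h = h + rng.normal(0, spec.noise_sigma[1], spec.shape).astype(np.float32)

    if len(truth):
        truth[["x_um", "y_um", "z_um"]] = coms  # lattice center of mass
        truth["volume_um3"] = vols
        # ground truth describes the rendered image: peaks include background
        truth["peak_q"] = truth["peak_q"] + spec.background[0]
        truth["peak_h"] = truth["peak_h"] + spec.background[1]
        truth["maturity"] = truth["peak_q"] / truth["peak_h"]
    return ImageVolume(q=q, h=h, voxel_size=spec.voxel_size), truth


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, pd.DataFrame]:
    """Render one synthetic brain and return it with its ground-truth table.

    The returned table's centers and volumes are exact properties of the
    rendered lattice support (voxel centers within the sphere radius), so a
    perfect segmentation should reproduce them identically on sharp-edged,
    noiseless phantoms.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_field, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    truth = sample_plaque_field(spec, rng_field, enforce_separation=True)
    return _render(spec, truth, rng_noise)


# ---------------------------------------------------------------------------
# cohorts

def _apply_effects(
    truth: pd.DataFrame,
    effects: list[EffectRegionSpec],
    rng: np.random.Generator,
    spacing: float = ATLAS_SPACING_UM,
) -> pd.DataFrame:
    out = truth.copy()
    for eff in effects:
        if eff.effect_size == 1.0:
            continue
        inside = eff.contains(out[["x_um", "y_um", "z_um"]].to_numpy(), spacing)
        if eff.affected_metric == "count":
            if eff.effect_size < 1.0:
                drop = inside & (rng.random(len(out)) > eff.effect_size)
                out = out.loc[~drop].reset_index(drop=True)
            else:
                raise NotImplementedError("count effect_size > 1 not supported")
        elif eff.affected_metric == "size":
            out.loc[inside, "radius_um"] *= eff.effect_size
            out.loc[inside, "volume_um3"] *= eff.effect_size ** 3
        elif eff.affected_metric == "maturity":
            out.loc[inside, "peak_q"] *= eff.effect_size
            out.loc[inside, "maturity"] *= eff.effect_size
    return out


def generate_cohort(spec: CohortSpec, render: bool = False) -> list[SyntheticBrain]:
    """Generate control and treated brains for a two-group study.

    With ``render=False`` (the statistics-stage workhorse) only ground-truth
    plaque tables are produced and the minimum-separation constraint is not
    enforced — overlap only matters when an image is segmented.  With
    ``render=True`` each brain also carries a rendered two-channel volume.
    """
    ss = np.random.SeedSequence(spec.seed)
    brains: list[SyntheticBrain] = []
    groups = [("control", spec.n_control), ("treated", spec.n_treated)]
    child_seeds = iter(ss.spawn(spec.n_control + spec.n_treated))
    sigma = math.sqrt(math.log(1 + spec.inter_brain_cv ** 2))
    for group, n_brains in groups:
        for b in range(n_brains):
            child = next(child_seeds)
            rng_field, rng_eff, rng_noise = (np.random.default_rng(s) for s in child.spawn(3))
            factor = math.exp(rng_field.normal(0, sigma) - 0.5 * sigma ** 2)
            n_b = max(0, int(round(spec.phantom.n_plaques * factor)))
            truth = sample_plaque_field(
                spec.phantom, rng_field, enforce_separation=render, n_plaques=n_b
            )
            if group == "treated":
                truth = _apply_effects(truth, spec.effects, rng_eff)
            image = None
            if render:
                image, truth = _render(spec.phantom, truth, rng_noise)
            brains.append(SyntheticBrain(f"{group}_{b:02d}", group, truth, image))
    return brains


# ---------------------------------------------------------------------------
# expression atlas

def generate_expression_atlas(
    spec: SyntheticExpressionSpec,
    reference_map: np.ndarray,
    mask: np.ndarray,
    spacing: float = ATLAS_SPACING_UM,
) -> tuple[ExpressionAtlas, list[str]]:
    """Synthesize a spot-table expression atlas on the atlas grid.

    The first ``n_correlated`` genes have Poisson rates increasing
    monotonically with the local (Gaussian-smoothed) density of
    ``reference_map``; all other genes are spatially unstructured.  Returns
    the atlas plus the list of planted correlated gene names.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mask = np.asarray(mask).astype(bool)
    vox = np.argwhere(mask)
    if spec.spot_spacing_vox > 1:
        keep = np.all(vox % spec.spot_spacing_vox == 0, axis=1)
        vox = vox[keep]
    if spec.n_spots > len(vox):
        raise ValueError(f"n_spots={spec.n_spots} exceeds {len(vox)} candidate voxels")
    sel = rng.choice(len(vox), size=spec.n_spots, replace=False)
    vox = vox[np.sort(sel)]
    coords = (vox + 0.5) * spacing

    density = ndimage.gaussian_filter(np.asarray(reference_map, dtype=float), 2.0)
    d = density[tuple(vox.T)]
    span = d.max() - d.min()
    d = (d - d.min()) / span if span > 0 else np.zeros_like(d)

    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    values = np.empty((spec.n_spots, spec.n_genes))
    lam_gene = spec.base_rate * np.exp(rng.normal(0, 0.3, spec.n_genes))
    for g in range(spec.n_genes):
        lam = lam_gene[g] * (0.25 + 3.0 * d) if g < spec.n_correlated else \
            np.full(spec.n_spots, lam_gene[g])
        if spec.dispersion > 0:
            lam = lam * rng.gamma(1.0 / spec.dispersion, spec.dispersion, spec.n_spots)
        values[:, g] = rng.poisson(lam)
    return ExpressionAtlas(coords_um=coords, values=values, genes=genes), genes[: spec.n_correlated]
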