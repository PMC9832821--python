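"""Mutual-information ranking of genes against a binary SAV map.

A spatial expression atlas is a table of spots (atlas-space coordinates plus
one expression value per gene).  Each gene is rasterized onto the SAV grid,
discretized into quantile bins over spot-covered voxels, and scored by plug-in
mutual information (natural log) against the binary SAV indicator.  Genes are
then ranked by MI; a high percentile marks genes whose spatial expression
pattern co-varies — linearly or not — with where a treatment altered plaques.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ATLAS_SPACING_UM


@dataclass
class ExpressionAtlas:
    """Spot-indexed gene expression in atlas coordinates.

    ``coords_um`` is (n_spots, 3) in micrometres; ``values`` is
    (n_spots, n_genes), non-negative.
    """

    coords_um: np.ndarray
    values: np.ndarray
    genes: list[str]

    def __post_init__(self) -> None:
        self.coords_um = np.asarray(self.coords_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords_um.ndim != 2 or self.coords_um.shape[1] != 3:
            raise ValueError("coords_um must be (n_spots, 3)")
        if self.values.shape != (len(self.coords_um), len(self.genes)):
            raise ValueError("values must be (n_spots, n_genes)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_spots(self) -> int:
        return len(self.coords_um)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in atlas") from None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords_um, columns=["x_um", "y_um", "z_um"])
        return pd.concat([df, pd.DataFrame(self.values, columns=self.genes)], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionAtlas":
        df = pd.read_csv(path)
        genes = [c for c in df.columns if c not in ("x_um", "y_um", "z_um")]
        return cls(coords_um=df[["x_um", "y_um", "z_um"]].to_numpy(),
                   values=df[genes].to_numpy(), genes=genes)


@dataclass
class MIScore:
    gene: str
    mi: float                 # nats
    normalized_mi: float      # mi / sqrt(H(sav) * H(expr)), 0 when degenerate
    degenerate: bool = False  # constant expression or constant SAV on coverage


def rasterize_spots(
    expr: ExpressionAtlas,
    gene: str,
    grid_shape: tuple[int, int, int],
    spacing: float = ATLAS_SPACING_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel expression map for one gene plus the spot-coverage mask.

    Spots are assigned to the voxel containing them (half-open convention);
    multiple spots in one voxel are averaged.  Comparisons downstream are
    restricted to the coverage mask.
    """
    g = expr.gene_index(gene)
    idx = np.floor(expr.coords_um / spacing).astype(int)
    inb = np.all((idx >= 0) & (idx < np.array(grid_shape)), axis=1)
    idx = idx[inb]
    vals = expr.values[inb, g]
    flat = np.ravel_multi_index(tuple(idx.T), grid_shape)
    n = int(np.prod(grid_shape))
    counts = np.bincount(flat, minlength=n).astype(float)
    sums = np.bincount(flat, weights=vals, minlength=n)
    coverage = counts > 0
    expr_map = np.zeros(n)
    expr_map[coverage] = sums[coverage] / counts[coverage]
    return expr_map.reshape(grid_shape), coverage.reshape(grid_shape)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(
    sav_grid: np.ndarray,
    expr_map: np.ndarray,
    coverage_mask: np.ndarray,
    n_bins: int = 2,
    gene: str = "",
) -> MIScore:
    """Plug-in MI (nats) between the SAV indicator and binned expression.

    Expression is discretized into ``n_bins`` quantile bins over covered
    voxels (default: median split).  Constant expression carries no spatial
    information: MI is 0 by convention and the score flagged degenerate.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sav = np.asarray(sav_grid).astype(bool)[coverage_mask].astype(int)
    vals = np.asarray(expr_map, dtype=float)[coverage_mask]
    if vals.size == 0:
        raise ValueError("empty coverage mask")

    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1)[1:-1])
    binned = np.searchsorted(edges, vals, side="right")
    if np.unique(binned).size < 2 or np.unique(sav).size < 2:
        return MIScore(gene=gene, mi=0.0, normalized_mi=0.0, degenerate=True)

    joint = np.zeros((2, n_bins))
    np.add.at(joint, (sav, binned), 1.0)
    mi = mi_from_joint(joint)
    hx, hy = _entropy(joint.sum(axis=1)), _entropy(joint.sum(axis=0))
    nmi = mi / np.sqrt(hx * hy) if hx > 0 and hy > 0 else 0.0
    return MIScore(gene=gene, mi=float(mi), normalized_mi=float(min(nmi, 1.0)))


def mi_from_joint(joint: np.ndarray) -> float:
    """MI in nats from a 2D joint count table: sum p log(p / (p_x p_y))."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total == 0:
        raise ValueError("empty joint table")
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def rank_genes(scores: list[MIScore]) -> pd.DataFrame:
    """Descending-MI gene ranking with tie-sharing percentiles.

    percentile = 100 * (number of genes with strictly smaller MI) / n_genes,
    so a unique maximum among 100 genes sits at 99.0 and full ties share 0.
    """
    names = [s.gene for s in scores]
    if len(set(names)) != len(names):
        raise ValueError("duplicate gene ids in scores")
    mi = np.array([s.mi for s in scores])
    pct = 100.0 * (mi[:, None] > mi[None, :]).sum(axis=1) / len(mi) if len(mi) < 4000 else \
        100.0 * (pd.Series(mi).rank(method="min") - 1).to_numpy() / len(mi)
    df = pd.DataFrame({
        "gene": names,
        "mi": mi,
        "normalized_mi": [s.normalized_mi for s in scores],
        "degenerate": [s.degenerate for s in scores],
        "percentile": pct,
    })
    return df.sort_values("mi", ascending=False, kind="mergesort").reset_index(drop=True)


def score_genes(
    sav_grid: np.ndarray,
    expr: ExpressionAtlas,
    n_bins: int = 2,
    spacing: float = ATLAS_SPACING_UM,
) -> pd.DataFrame:
    """MI-rank every gene in the atlas against one SAV map."""
    grid_shape = np.asarray(sav_grid).shape
    # coverage and binning are shared across genes; rasterize each gene
    scores = []
    for gene in expr.genes:
        emap, cov = rasterize_spots(expr, gene, grid_shape, spacing)
        scores.append(mutual_information(sav_grid, emap, cov, n_bins=n_bins, gene=gene))
    return rank_genes(scores)
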