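"""Common-essential gene classification across a screen panel.

The 90th-percentile method asks: is a gene still clearly depleted in its
*least* dependent cell lines?  For each screen, genes are ranked by
depletion (rank 1 = most depleted).  A gene's ranks across screens are
sorted ascending; the screens beyond the 90th percentile of that sorted
profile are its least-dependent tail.  Four summaries of the tail are
supported:

* ``average`` — mean tail rank (the most stringent; used for final calls);
* ``fixed``   — the rank exactly at the percentile position;
* ``auc``     — trapezoidal mean of the tail rank curve;
* ``slope``   — least-squares slope of the full sorted-rank profile,
  scaled by the gene-universe size so it is comparable across panels.

Scores of common essentials cluster far below the bulk; the class
boundary is the lowest local minimum of a Gaussian KDE between the two
dominant density modes.  A unimodal density yields an (explicitly
flagged) empty set rather than an arbitrary cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANTS = ("average", "fixed", "auc", "slope")


def gene_rank_matrix(gene_lfc: pd.DataFrame) -> pd.DataFrame:
    """Within-screen depletion ranks (genes × screens; rank 1 = most
    depleted; ties get average ranks).  All screens must share the gene
    universe."""
    if gene_lfc.shape[1] < 2:
        raise ValueError("need at least two screens")
    if gene_lfc.isna().any().any():
        missing = gene_lfc.columns[gene_lfc.isna().any()].tolist()
        raise ValueError(f"gene universe mismatch: NaN LFCs in screens {missing}")
    return gene_lfc.rank(axis=0, method="average", ascending=True)


def percentile_scores(
    rank_matrix: pd.DataFrame, variant: str = "average", percentile: float = 0.90
) -> pd.Series:
    """Per-gene tail score under one variant of the percentile method.

    The tail starts at position t = ceil(percentile · n_screens) of the
    ascending-sorted rank profile (1-indexed, inclusive).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    n = rank_matrix.shape[1]
    g_universe = rank_matrix.shape[0]
    if n < 10:
        warnings.warn(f"only {n} screens; percentile method is unstable below 10", stacklevel=2)
    t = math.ceil(percentile * n)
    t = min(max(t, 1), n)
    sorted_ranks = np.sort(rank_matrix.to_numpy(dtype=float), axis=1)
    tail = sorted_ranks[:, t - 1 :]
    if variant == "average":
        score = tail.mean(axis=1)
    elif variant == "fixed":
        score = sorted_ranks[:, t - 1]
    elif variant == "auc":
        if tail.shape[1] == 1:
            score = tail[:, 0]
        else:
            score = np.trapezoid(tail, axis=1) / (tail.shape[1] - 1)
    else:  # slope over the full sorted profile, universe-scaled
        pos = np.arange(1, n + 1, dtype=float)
        pc = pos - pos.mean()
        score = (sorted_ranks - sorted_ranks.mean(axis=1, keepdims=True)) @ pc / (pc @ pc)
        score = score / g_universe
    return pd.Series(score, index=rank_matrix.index, name=f"score_{variant}")


@dataclass
class CegResult:
    variant: str
    scores: pd.Series
    threshold: float | None
    ceg_set: list[str]
    unimodal: bool
    percentile: float = 0.90
    density_grid: np.ndarray | None = field(default=None, repr=False)
    density: np.ndarray | None = field(default=None, repr=False)


def classify_cegs(
    scores: pd.Series,
    variant: str = "average",
    percentile: float = 0.90,
    grid_size: int = 512,
) -> CegResult:
    """Threshold scores at the KDE density valley separating the
    low-score common-essential mode from the bulk.

    The bulk mode is the global density maximum.  The threshold is the
    lowest local minimum left of the bulk that still has a density mode
    to its own left (so the density is genuinely bimodal there, not just
    shouldered); genes strictly below the threshold are common
    essential.  Boundary extrema are ignored; a unimodal density gives
    an empty, flagged result rather than an arbitrary cut.
    """
    if len(scores) < 50:
        raise ValueError("need at least 50 scored genes")
    x = scores.to_numpy(dtype=float)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    is_min = (dens[interior] < dens[interior - 1]) & (dens[interior] <= dens[interior + 1])
    maxima = interior[is_max]
    minima = interior[is_min]
    if len(maxima) < 2 or len(minima) == 0:
        return CegResult(variant, scores, None, [], True, percentile, grid, dens)
    bulk = maxima[np.argmax(dens[maxima])]
    candidates = [
        m for m in minima if m < bulk and (maxima < m).any()
    ]
    if not candidates:
        return CegResult(variant, scores, None, [], True, percentile, grid, dens)
    thr_idx = min(candidates, key=lambda m: dens[m])
    threshold = float(grid[thr_idx])
    ceg = sorted(scores.index[x < threshold])
    return CegResult(variant, scores, threshold, ceg, False, percentile, grid, dens)


def call_common_essentials(
    gene_lfc: pd.DataFrame, percentile: float = 0.90
) -> dict[str, CegResult]:
    """Run all four percentile-method variants on a gene × screen panel."""
    rm = gene_rank_matrix(gene_lfc)
    out = {}
    for variant in VARIANTS:
        sc = percentile_scores(rm, variant=variant, percentile=percentile)
        out[variant] = classify_cegs(sc, variant=variant, percentile=percentile)
    return out


def nonessential_reference(
    gene_lfc: pd.DataFrame, intergenic_lfc: pd.DataFrame, k: int = 10
) -> list[str]:
    """Top-k genes with the smallest summed per-screen |LFC deviation|
    from the intergenic-control median — a visualization-grade
    "definitely not essential" reference set."""
    if k > gene_lfc.shape[0]:
        raise ValueError("k exceeds gene count")
    med = intergenic_lfc.median(axis=0)
    dev = (gene_lfc - med).abs().sum(axis=1)
    return list(dev.sort_values(kind="stable").index[:k])
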