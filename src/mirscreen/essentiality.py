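"""Per-screen gene essentiality scoring.

Two deliberately different classifiers are combined:

* **Supervised Bayes factors.**  Gaussian kernel densities are fit to the
  LFCs of guides targeting known essential genes (f_ess) and to
  intergenic-control guides (f_null).  Each guide scores
  log2 f_ess(x) − log2 f_null(x); a gene's Bayes factor is the sum over
  its guides.  Training guides are bootstrapped and the reported BF is the
  bootstrap mean.  FDR along the BF ranking is the labelled-control
  imprecision (1 − precision), monotonized down the list.

* **Semi-supervised alpha-RRA.**  All guides are ranked by depletion and
  converted to percentiles.  For a gene with k guides, only guides more
  depleted than the ``alpha`` percentile enter; the gene statistic rho is
  the smallest Beta(j, k−j+1) order-statistic CDF over the gated guides.
  Significance comes from permutation draws of k intergenic-control guide
  percentiles, and FDR from Benjamini–Hochberg across genes.

A gene is a consensus *fitness gene* in a screen when both classifiers put
it below the FDR threshold (default 10%).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import GuideLibrary

_DENSITY_FLOOR = 1e-12
_GRID_SIZE = 512


def _kde_log_density(train: np.ndarray, grid: np.ndarray) -> np.ndarray:
    kde = stats.gaussian_kde(train, bw_method="silverman")
    dens = np.maximum(kde(grid), _DENSITY_FLOOR)
    return np.log2(dens)


def bagel_gene_bf(
    guide_lfc: pd.Series,
    guide_to_gene: pd.Series,
    essential_train_guides,
    null_train_guides,
    n_boot: int = 200,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Bootstrapped KDE Bayes factors per gene for one screen.

    ``guide_lfc`` holds one LFC per guide (replicates already averaged or
    stacked upstream).  Returns a frame indexed by gene_id with columns
    ``bf`` (bootstrap-mean log2 Bayes factor) and ``bootstrap_sd``.
    """
    ess = guide_lfc.reindex(pd.Index(essential_train_guides)).dropna().to_numpy()
    nul = guide_lfc.reindex(pd.Index(null_train_guides)).dropna().to_numpy()
    if len(ess) < 20 or len(nul) < 20:
        raise ValueError("each training set needs at least 20 guides with LFCs")
    if np.std(ess) == 0 or np.std(nul) == 0:
        raise ValueError("degenerate (zero-SD) training set")

    # guides to score: everything with a gene assignment
    scored = guide_lfc.loc[guide_lfc.index.intersection(guide_to_gene.index)]
    genes = guide_to_gene.reindex(scored.index)
    x = scored.to_numpy(dtype=float)

    lo = min(ess.min(), nul.min())
    hi = max(ess.max(), nul.max())
    span = hi - lo
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, _GRID_SIZE)
    x_clamped = np.clip(x, grid[0], grid[-1])

    rng = np.random.default_rng(rng_seed)
    gene_codes, gene_ids = pd.factorize(genes.to_numpy())
    boot_bf = np.zeros((n_boot, len(gene_ids)))
    for b in range(n_boot):
        ess_b = rng.choice(ess, size=len(ess), replace=True)
        nul_b = rng.choice(nul, size=len(nul), replace=True)
        if np.std(ess_b) == 0 or np.std(nul_b) == 0:  # pathological resample
            ess_b = ess
            nul_b = nul
        log_f_ess = np.interp(x_clamped, grid, _kde_log_density(ess_b, grid))
        log_f_null = np.interp(x_clamped, grid, _kde_log_density(nul_b, grid))
        guide_bf = log_f_ess - log_f_null
        boot_bf[b] = np.bincount(gene_codes, weights=guide_bf, minlength=len(gene_ids))
    return pd.DataFrame(
        {
            "bf": boot_bf.mean(axis=0),
            "bootstrap_sd": boot_bf.std(axis=0, ddof=1) if n_boot > 1 else 0.0,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def bf_fdr(
    bf: pd.DataFrame | pd.Series, essential_ids, null_ids
) -> pd.DataFrame:
    """Labelled-precision FDR along the descending-BF ranking.

    At each rank, FDR = 1 − (essential controls seen) / (labelled
    controls seen); ranks before the first labelled control inherit
    FDR 0.  Monotonized by running maximum down the list.
    """
    ser = bf["bf"] if isinstance(bf, pd.DataFrame) else bf
    order = ser.sort_values(ascending=False, kind="stable")
    pos = set(essential_ids)
    neg = set(null_ids)
    is_pos = np.array([g in pos for g in order.index])
    is_lab = np.array([g in pos or g in neg for g in order.index])
    if not is_lab.any():
        raise ValueError("no labelled control genes among scored genes")
    tp = np.cumsum(is_pos)
    lab = np.cumsum(is_lab)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdr = np.where(lab > 0, 1.0 - tp / np.maximum(lab, 1), 0.0)
    fdr = np.maximum.accumulate(fdr)
    out = pd.DataFrame({"bf": order.to_numpy(), "fdr": fdr}, index=order.index)
    return out.reindex(ser.index)


# ---------------------------------------------------------------------------
# alpha-RRA


def _rho_from_sorted_percentiles(p_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise rho: min over alpha-gated j of BetaCDF(p(j); j, k−j+1).

    ``p_sorted`` is (n, k) with each row ascending.  Rows with no gated
    guide get rho 1.
    """
    n, k = p_sorted.shape
    j = np.arange(1, k + 1)
    beta = stats.beta.cdf(p_sorted, j[None, :], (k - j + 1)[None, :])
    gated = p_sorted < alpha
    beta = np.where(gated, beta, np.inf)
    rho = beta.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def rra_score(
    guide_lfc: pd.Series,
    lib: GuideLibrary,
    alpha: float | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    direction: str = "depletion",
    alpha_floor: float = 0.05,
) -> pd.DataFrame:
    """Alpha-robust-rank-aggregation scores for one screen.

    Guides (miRNA-targeting plus intergenic controls, plus any other
    coordinate-bearing guides) are ranked by LFC — ascending for
    depletion, descending for enrichment — and percentile-normalized.
    When ``alpha`` is None the gate is set semi-supervised from the
    intergenic controls: the fraction of universe guides depleted beyond
    the controls' own 5th percentile (floored at ``alpha_floor``, capped
    at 0.5), so that genuinely depleted guides are not crowded out of a
    fixed top slice in a hit-dense screen.  Returns a frame indexed by
    gene_id with ``rho``, ``p`` (permutation, ≥ 1/(n_perm+1)) and ``fdr``
    (Benjamini–Hochberg).
    """
    if direction not in {"depletion", "enrichment"}:
        raise ValueError("direction must be 'depletion' or 'enrichment'")
    rec = lib.records
    universe = rec.loc[rec["guide_class"] != "non_targeting", "guide_id"]
    x = guide_lfc.reindex(universe).dropna()
    vals = x.to_numpy(dtype=float)
    if direction == "enrichment":
        vals = -vals
    ranks = stats.rankdata(vals, method="average")
    pct = pd.Series(ranks / len(ranks), index=x.index)

    g2g = lib.guide_to_gene
    inter_guides = rec.loc[rec["guide_class"] == "intergenic_control", "guide_id"]
    inter_pct = pct.reindex(inter_guides).dropna().to_numpy()
    if len(inter_pct) == 0:
        raise ValueError("no intergenic-control guides with LFCs")
    if alpha is None:
        inter_vals = pd.Series(vals, index=x.index).reindex(inter_guides).dropna()
        tau = float(np.quantile(inter_vals, 0.05))
        alpha = float(np.clip((vals < tau).mean(), alpha_floor, 0.5))

    target_rec = rec[rec["guide_class"].isin(["mirna_targeting", "essential_control"])]
    rng = np.random.default_rng(rng_seed)
    rows = []
    # group genes by guide count so permutation nulls are shared per k
    gene_guides: dict[str, np.ndarray] = {}
    for gene, sub in target_rec.groupby("gene_id", sort=False):
        pcts = pct.reindex(sub["guide_id"]).dropna().to_numpy()
        if len(pcts) == 0:
            continue
        gene_guides[gene] = np.sort(pcts)
    by_k: dict[int, list[str]] = {}
    for gene, pcts in gene_guides.items():
        by_k.setdefault(len(pcts), []).append(gene)

    for k, genes in sorted(by_k.items()):
        obs = np.vstack([gene_guides[g] for g in genes])
        rho = _rho_from_sorted_percentiles(obs, alpha)
        null_draw = rng.choice(inter_pct, size=(n_perm, k), replace=True)
        null_rho = _rho_from_sorted_percentiles(np.sort(null_draw, axis=1), alpha)
        null_sorted = np.sort(null_rho)
        n_le = np.searchsorted(null_sorted, rho, side="right")
        p = (1.0 + n_le) / (n_perm + 1.0)
        for g, r, pv in zip(genes, rho, p):
            rows.append({"gene_id": g, "rho": float(r), "p": float(pv), "n_guides": k})
    out = pd.DataFrame(rows).set_index("gene_id")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# Consensus


def consensus_calls(
    bf: pd.DataFrame,
    rra: pd.DataFrame,
    lib: GuideLibrary,
    fdr_threshold: float = 0.10,
) -> dict:
    """Fitness genes = genes under the FDR threshold for *both* methods.

    Returns the call set restricted to miRNA-targeting genes, the full
    both-significant set, and the recall of essential-control genes.
    """
    common = bf.index.intersection(rra.index)
    only_bf = bf.index.difference(rra.index)
    only_rra = rra.index.difference(bf.index)
    if len(only_bf) and len(only_rra):
        raise ValueError("BF and RRA gene universes are inconsistent")
    sig = set(common[(bf.loc[common, "fdr"] < fdr_threshold)
                     & (rra.loc[common, "fdr"] < fdr_threshold)])
    mirna_genes = set(lib.genes_of_class("mirna_targeting"))
    ess_genes = set(lib.genes_of_class("essential_control")) & set(common)
    recall = (
        len(sig & ess_genes) / len(ess_genes) if ess_genes else float("nan")
    )
    return {
        "fitness_genes": sorted(sig & mirna_genes),
        "all_significant": sorted(sig),
        "fdr_threshold": fdr_threshold,
        "recall_essential_controls": recall,
    }


def score_screen(
    guide_lfc: pd.Series,
    lib: GuideLibrary,
    fdr_threshold: float = 0.10,
    n_boot: int = 200,
    n_perm: int = 1000,
    alpha: float | None = None,
    rng_seed: int = 0,
    pseudogenes: dict[str, list[str]] | None = None,
) -> dict:
    """Full per-screen essentiality scoring: BF + FDR, RRA, consensus.

    Intergenic guides are grouped into contiguous pseudo-genes (built here
    if not supplied) and scored alongside real genes; together with the
    essential-control genes they label the BF ranking for the
    labelled-precision FDR.
    """
    from .integration import make_intergenic_pseudogenes, pseudogene_guide_map

    rec = lib.records
    ess_guides = rec.loc[rec["guide_class"] == "essential_control", "guide_id"]
    null_guides = rec.loc[rec["guide_class"] == "intergenic_control", "guide_id"]
    if pseudogenes is None:
        pseudogenes = make_intergenic_pseudogenes(lib)
    pg_map = pseudogene_guide_map(pseudogenes)
    g2g = lib.guide_to_gene.copy()
    g2g.loc[pg_map.index] = pg_map  # intergenic guides score as pseudo-genes
    bf = bagel_gene_bf(
        guide_lfc, g2g, ess_guides, null_guides,
        n_boot=n_boot, rng_seed=rng_seed,
    )
    ess_genes = lib.genes_of_class("essential_control")
    rra = rra_score(
        guide_lfc, lib, alpha=alpha, n_perm=n_perm, rng_seed=rng_seed + 1
    )
    # positive-selection side: reported for completeness, not consensus
    rra_enrich = rra_score(
        guide_lfc, lib, alpha=alpha, n_perm=n_perm, rng_seed=rng_seed + 2,
        direction="enrichment",
    )
    bf = bf_fdr(bf, ess_genes, sorted(pseudogenes)).join(
        bf[["bootstrap_sd"]], how="left"
    )
    consensus = consensus_calls(bf, rra, lib, fdr_threshold=fdr_threshold)
    return {"bf": bf, "rra": rra, "rra_enrichment": rra_enrich, "consensus": consensus}
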