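"""Replicate- and screen-level quality control.

Gates and metrics used before any essentiality calling:

* read-level gates — a replicate is dropped when fewer than 60% of its
  reads matched the library, or when its total read count falls short of
  100× average coverage per construct;
* reproducibility — Pearson correlation between replicate LFC profiles
  after pre-filtering, and a within-vs-between (WBC) separability score
  contrasting within-screen replicate correlations with the correlations
  each replicate shows to replicates of other screens;
* effect-size separation — null-normalized mean difference (NNMD) and
  Cohen's D between essential-control and null-control guide LFCs (more
  negative = cleaner dropout);
* classification — precision-recall analysis of a ranked essentiality
  scoring against labelled control sets, including the F measure at a
  Bayes-factor threshold of five.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CountTable, GuideLibrary


@dataclass
class QcThresholds:
    min_matched_fraction: float = 0.60
    min_mean_coverage: float = 100.0

    def __post_init__(self) -> None:
        if self.min_matched_fraction <= 0 or self.min_mean_coverage <= 0:
            raise ValueError("QC thresholds must be positive")


def replicate_read_qc(
    counts: CountTable, lib: GuideLibrary, thr: QcThresholds | None = None
) -> pd.DataFrame:
    """Pass/fail per replicate with enumerated reasons.

    Fails a replicate iff its matched-read fraction is below
    ``thr.min_matched_fraction`` or its total reads are below
    ``thr.min_mean_coverage × library size``.
    """
    thr = thr or QcThresholds()
    n_guides = len(lib)
    rows = []
    for sid in counts.replicate_ids:
        mf = counts.samples.loc[sid, "matched_fraction"]
        if pd.isna(mf):
            raise ValueError(f"matched_fraction missing for replicate {sid!r}")
        total = float(counts.counts[sid].sum())
        reasons = []
        if mf < thr.min_matched_fraction:
            reasons.append(
                f"matched_fraction {mf:.3f} < {thr.min_matched_fraction:.2f}"
            )
        if total < thr.min_mean_coverage * n_guides:
            reasons.append(
                f"coverage {total / n_guides:.1f}x < {thr.min_mean_coverage:.0f}x"
            )
        rows.append(
            {
                "replicate_id": sid,
                "cell_line": counts.samples.loc[sid, "cell_line"],
                "matched_fraction": float(mf),
                "total_reads": total,
                "coverage": total / n_guides,
                "passed": not reasons,
                "reasons": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("replicate_id")


# ---------------------------------------------------------------------------
# Reproducibility


def prefilter_guides(
    lfc_wide: pd.DataFrame,
    lib: GuideLibrary,
    active_genes: set[str] | None,
) -> pd.DataFrame:
    """Drop essential-control guides and guides of genes with no fitness
    effect in any screen (``active_genes`` = genes that do show one)."""
    g2g = lib.guide_to_gene
    keep_class = lib.records.loc[
        lib.records["guide_class"] != "essential_control", "guide_id"
    ]
    keep = lfc_wide.index.intersection(keep_class)
    if active_genes is not None:
        genes = g2g.reindex(keep)
        keep = keep[genes.isin(active_genes) | genes.isna()]
    return lfc_wide.loc[keep]


def replicate_reproducibility(
    lfc_wide: pd.DataFrame,
    replicate_screens: pd.Series,
    lib: GuideLibrary,
    active_genes: set[str] | None = None,
    wbc_quantile: float = 0.90,
) -> dict:
    """PCC matrix across replicates and a per-screen WBC score.

    ``lfc_wide`` is guides × replicate columns; ``replicate_screens`` maps
    replicate id → screen (cell line).  The WBC score of a screen is the
    mean of its within-screen replicate-pair correlations minus the
    ``wbc_quantile`` quantile of its replicates' between-screen
    correlations; positive = replicates agree more within than between.
    Computed on LFCs and on dLFCs (LFC minus the gene-wise cross-screen
    consensus).  Screens with a single replicate get a NaN WBC and a flag.
    """
    filt = prefilter_guides(lfc_wide, lib, active_genes)
    pcc = filt.corr(method="pearson")

    g2g = lib.guide_to_gene.reindex(filt.index)
    screen_of = replicate_screens.reindex(filt.columns)
    # gene-wise consensus across screens: mean over screens of per-screen means
    per_screen = filt.T.groupby(screen_of).mean().T  # guides × screens
    consensus_guide = per_screen.mean(axis=1)
    dlfc = filt.sub(consensus_guide, axis=0)
    pcc_d = dlfc.corr(method="pearson")

    def wbc_scores(corr: pd.DataFrame) -> pd.Series:
        out = {}
        for screen in screen_of.unique():
            reps = list(screen_of.index[screen_of == screen])
            others = [r for r in corr.columns if r not in reps]
            if len(reps) < 2:
                out[screen] = np.nan
                continue
            within = [corr.loc[a, b] for i, a in enumerate(reps) for b in reps[i + 1 :]]
            between = corr.loc[reps, others].to_numpy().ravel()
            if len(between) == 0:
                out[screen] = np.nan
                continue
            out[screen] = float(
                np.mean(within) - np.quantile(between, wbc_quantile)
            )
        return pd.Series(out, name="wbc")

    wbc = wbc_scores(pcc)
    wbc_d = wbc_scores(pcc_d)
    return {
        "pcc_matrix": pcc,
        "wbc_lfc": wbc,
        "wbc_dlfc": wbc_d,
        "flagged_screens": sorted(wbc.index[(wbc <= 0) | wbc.isna()]),
        "n_guides_used": int(filt.shape[0]),
    }


# ---------------------------------------------------------------------------
# Effect-size separation


def effect_size_metrics(
    lfc: pd.Series | np.ndarray,
    essential_ids,
    null_ids,
) -> dict[str, float]:
    """NNMD and Cohen's D between essential- and null-control LFCs.

    NNMD = (mean_ess − mean_null) / sd_null;
    Cohen's D = (mean_ess − mean_null) / pooled sd.
    Both are negative for a well-separated dropout screen.
    """
    s = pd.Series(lfc)
    ess = s.loc[s.index.intersection(pd.Index(essential_ids))].to_numpy(dtype=float)
    nul = s.loc[s.index.intersection(pd.Index(null_ids))].to_numpy(dtype=float)
    if len(ess) == 0 or len(nul) == 0:
        raise ValueError("both control sets must be non-empty")
    sd_null = float(np.std(nul, ddof=1)) if len(nul) > 1 else 0.0
    if sd_null == 0:
        raise ValueError("null control SD is zero")
    diff = float(ess.mean() - nul.mean())
    n1, n2 = len(ess), len(nul)
    pooled = np.sqrt(
        ((n1 - 1) * np.var(ess, ddof=1) + (n2 - 1) * np.var(nul, ddof=1)) / (n1 + n2 - 2)
    )
    return {"nnmd": diff / sd_null, "cohens_d": diff / float(pooled)}


# ---------------------------------------------------------------------------
# Classification performance


def precision_recall_curve(
    scores: pd.Series, positive_ids, negative_ids
) -> pd.DataFrame:
    """PR curve over all thresholds of a higher-is-more-essential score.

    Only labelled items contribute; returns one row per rank with the
    threshold score, precision and recall after including that item.
    """
    pos = set(positive_ids)
    neg = set(negative_ids)
    labelled = scores.loc[[i for i in scores.index if i in pos or i in neg]]
    if len({i in pos for i in labelled.index}) < 2:
        raise ValueError("need both positive and negative labels among scored items")
    order = labelled.sort_values(ascending=False, kind="stable")
    is_pos = np.array([i in pos for i in order.index])
    tp = np.cumsum(is_pos)
    k = np.arange(1, len(order) + 1)
    precision = tp / k
    recall = tp / is_pos.sum()
    return pd.DataFrame(
        {"threshold": order.to_numpy(), "precision": precision, "recall": recall},
        index=order.index,
    )


def classification_metrics(
    scores: pd.Series,
    positive_ids,
    negative_ids,
    bf_rule: bool = False,
    bf_threshold: float = 5.0,
) -> dict:
    """AUC-PR (trapezoid on the recall grid) and, under the Bayes-factor
    rule, the F measure at the smallest score ≥ ``bf_threshold``."""
    curve = precision_recall_curve(scores, positive_ids, negative_ids)
    rec = np.concatenate([[0.0], curve["recall"].to_numpy()])
    prec = np.concatenate([[1.0], curve["precision"].to_numpy()])
    auc_pr = float(np.trapezoid(prec, rec))
    out = {"auc_pr": auc_pr, "curve": curve}
    if bf_rule:
        above = curve[curve["threshold"] >= bf_threshold]
        if len(above):
            row = above.iloc[-1]  # smallest threshold still >= bf_threshold
            out["bf_threshold_used"] = float(row["threshold"])
            out["threshold_extrapolated"] = False
        else:
            row = curve.iloc[0]
            out["bf_threshold_used"] = float(row["threshold"])
            out["threshold_extrapolated"] = True
        p, r = float(row["precision"]), float(row["recall"])
        out["precision"] = p
        out["recall"] = r
        out["f_measure"] = 0.0 if p + r == 0 else 2 * p * r / (p + r)
    return out
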