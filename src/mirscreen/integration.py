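"""Cross-screen harmonization and confound analyses.

To compare depletion across screens (and against external panels), each
screen's gene-level LFCs are affinely rescaled so the median of internal
essential-control genes lands at −1 and the median of the null reference
(intergenic pseudo-genes) at 0.  On that shared scale a gene with
LFC < −0.5 counts as depleted.

Intergenic control guides are grouped into genomically contiguous
*pseudo-genes* whose guide-count multiset mirrors the miRNA library's
guides-per-gene distribution; pseudo-genes provide gene-shaped nulls for
precision metrics and for depleted-fraction null distributions.

Because most miRNAs sit inside protein-coding host genes, a miRNA in an
*exon* of a common-essential host can deplete for host-gene reasons;
those genes are excluded.  Off-target analyses check whether guide
depletion tracks the number of predicted protein-coding off-target
sites (decile binning with pairwise t tests, Holm-corrected; hit-class
comparison by Kruskal–Wallis with Dunn's correction).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import GuideLibrary


def scale_lfcs(
    gene_lfc: pd.Series, essential_ids, null_ids
) -> pd.Series:
    """Affine control-anchored scaling of one screen's gene-level LFCs.

    scaled(x) = (x − m_null) / (m_null − m_ess), which maps the
    essential-control median m_ess to −1 and the null-reference median
    m_null to 0.
    """
    ess = gene_lfc.reindex(pd.Index(essential_ids)).dropna()
    nul = gene_lfc.reindex(pd.Index(null_ids)).dropna()
    if len(ess) < 5 or len(nul) < 5:
        raise ValueError("each anchor set needs at least 5 genes with LFCs")
    m_ess = float(ess.median())
    m_null = float(nul.median())
    if m_ess == m_null:
        raise ValueError("anchor medians coincide; scaling undefined")
    return (gene_lfc - m_null) / (m_null - m_ess)


def depleted_fraction(
    scaled: pd.DataFrame, cutoff: float = -0.5, gene_ids=None
) -> dict:
    """Per-screen fraction of genes below the scaled-LFC cutoff.

    ``scaled`` is genes × screens.  Returns per-screen fractions, their
    mean, and a per-gene flag for depletion in at least one screen.
    """
    sub = scaled if gene_ids is None else scaled.loc[scaled.index.intersection(pd.Index(gene_ids))]
    depleted = sub < cutoff
    frac = depleted.mean(axis=0)
    return {
        "per_screen_fraction": frac,
        "mean_fraction": float(frac.mean()),
        "any_screen": depleted.any(axis=1),
        "fraction_any_screen": float(depleted.any(axis=1).mean()),
    }


def make_intergenic_pseudogenes(
    lib: GuideLibrary, size_distribution: dict[int, float] | None = None
) -> dict[str, list[str]]:
    """Partition intergenic guides into contiguous genomic pseudo-genes.

    Guides are sorted by (chrom, pos) and cut into consecutive bins whose
    size multiset follows ``size_distribution`` (default: the library's
    own miRNA guides-per-gene distribution), allocated by largest
    remainder so the partition is deterministic.  Every intergenic guide
    lands in exactly one pseudo-gene.
    """
    inter = lib.guides_of_class("intergenic_control").sort_values(
        ["chrom", "pos"], kind="stable"
    )
    n = len(inter)
    if size_distribution is None:
        from .library import coverage_summary

        dist = coverage_summary(lib)["per_gene"]
        total = sum(k * v for k, v in dist.items())
        size_distribution = {k: k * v / total for k, v in dist.items()}
    sizes = sorted(size_distribution)
    if n < min(sizes):
        raise ValueError("fewer intergenic guides than a single pseudo-gene bin")
    # guides allocated to each size class by largest remainder
    probs = np.array([size_distribution[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    exact = probs * n
    guides_per_class = np.floor(exact).astype(int)
    # round guide budgets down to multiples of the bin size
    guides_per_class -= guides_per_class % np.array(sizes)
    remainder = n - guides_per_class.sum()
    order = np.argsort(-(exact - guides_per_class))
    for idx in itertools.cycle(order):
        s = sizes[idx]
        if remainder >= s:
            guides_per_class[idx] += s
            remainder -= s
        if remainder < min(sizes):
            break
    bin_sizes: list[int] = []
    for s, budget in zip(sizes, guides_per_class):
        bin_sizes.extend([s] * (budget // s))
    bin_sizes.sort(reverse=True)
    if remainder:  # leftover guides join the final bin
        bin_sizes[-1] += remainder
    out: dict[str, list[str]] = {}
    it = iter(inter["guide_id"])
    for i, s in enumerate(bin_sizes):
        out[f"pseudo_{i:04d}"] = list(itertools.islice(it, s))
    return out


def pseudogene_guide_map(pseudogenes: dict[str, list[str]]) -> pd.Series:
    """Flatten a pseudo-gene index into a guide_id → pseudo-gene Series."""
    pairs = [(g, pg) for pg, guides in pseudogenes.items() for g in guides]
    idx, vals = zip(*pairs)
    return pd.Series(vals, index=pd.Index(idx, name="guide_id"))


def host_gene_filter(
    genes, host_annotation: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Drop miRNAs residing in exons of common-essential host genes.

    ``host_annotation`` columns: mirna_id, host_gene, context
    ({exonic, intronic, intergenic}), host_essentiality
    ({common_essential, other}).  Unannotated miRNAs are treated as
    intergenic with a warning.  Returns (kept genes, removed table).
    """
    ann = host_annotation.set_index("mirna_id")
    genes = list(genes)
    missing = [g for g in genes if g not in ann.index]
    if missing:
        warnings.warn(
            f"{len(missing)} miRNA(s) missing host annotation; treated as intergenic",
            stacklevel=2,
        )
    present = ann.reindex([g for g in genes if g in ann.index])
    drop_mask = (present["context"] == "exonic") & (
        present["host_essentiality"] == "common_essential"
    )
    removed = present.loc[drop_mask, ["host_gene", "context", "host_essentiality"]]
    kept = [g for g in genes if g not in set(removed.index)]
    return kept, removed.reset_index()


def host_annotation_from_gff(
    gff_path,
    mirna_positions: pd.DataFrame,
    common_essential_genes,
) -> pd.DataFrame:
    """Best-effort host-gene annotation from a GFF3 of protein-coding genes.

    ``mirna_positions`` needs columns mirna_id, chrom, pos (1-based, e.g.
    the median guide cut site per miRNA).  A miRNA inside a gene feature
    is ``exonic`` if its position overlaps any exon of that gene, else
    ``intronic``; otherwise ``intergenic``.  Host essentiality comes from
    the supplied common-essential gene list.  This is a convenience
    builder — curated annotation tables are preferred when available.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    essential = set(common_essential_genes)
    rows = []
    for r in mirna_positions.itertuples(index=False):
        host, context = None, "intergenic"
        region = (str(r.chrom), int(r.pos), int(r.pos))
        genes = [f for f in db.region(region, featuretype="gene")]
        if genes:
            g = genes[0]
            host = g.attributes.get("gene_name", g.attributes.get("Name", [g.id]))[0]
            exonic = any(
                f.start <= r.pos <= f.end
                for f in db.region(region, featuretype="exon")
            )
            context = "exonic" if exonic else "intronic"
        rows.append(
            {
                "mirna_id": r.mirna_id,
                "host_gene": host,
                "context": context,
                "host_essentiality": (
                    "common_essential" if host in essential else "other"
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Off-target / depletion association


def _dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    var_base = n_total * (n_total + 1) / 12.0 - ties / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[start : start + k].mean()
        start += k
    rows = []
    m = len(names) * (len(names) - 1) // 2
    for a, b in itertools.combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var_base * (1 / na + 1 / nb))
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": p, "p_adj": min(1.0, p * m)})
    return pd.DataFrame(rows)


def offtarget_depletion_analysis(
    guide_lfc: pd.Series,
    lib: GuideLibrary,
    hit_genes=None,
    n_bins: int = 10,
) -> dict:
    """Does guide depletion track predicted off-target load?

    Guides are ranked ascending by LFC (bin 1 = most depleted) and split
    into ``n_bins`` near-equal deciles; per-bin off-target summaries are
    reported with pairwise Welch t tests (Holm-corrected).  When
    ``hit_genes`` is given, off-target counts of guides targeting hit vs
    non-hit miRNAs are compared by Kruskal–Wallis with Dunn's correction.
    """
    rec = lib.records.set_index("guide_id")
    x = guide_lfc.dropna()
    x = x.loc[x.index.intersection(rec.index)]
    if len(x) < n_bins:
        raise ValueError(f"need at least {n_bins} guides")
    order = x.sort_values(kind="stable")
    ot = rec.loc[order.index, "offtarget_count"].to_numpy(dtype=float)
    bins = np.array_split(np.arange(len(order)), n_bins)
    summary = pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "n_guides": [len(b) for b in bins],
            "mean_offtargets": [ot[b].mean() for b in bins],
            "median_offtargets": [float(np.median(ot[b])) for b in bins],
            "mean_lfc": [order.to_numpy()[b].mean() for b in bins],
        }
    ).set_index("bin")
    pvals, pairs = [], []
    for a, b in itertools.combinations(range(n_bins), 2):
        xa, xb = ot[bins[a]], ot[bins[b]]
        if np.var(xa) == 0 and np.var(xb) == 0:
            p = 1.0
        else:
            p = stats.ttest_ind(xa, xb, equal_var=False).pvalue
        pairs.append((a + 1, b + 1))
        pvals.append(float(p))
    p_adj = multipletests(pvals, method="holm")[1] if pvals else []
    pairwise = pd.DataFrame(
        {"bin_a": [p[0] for p in pairs], "bin_b": [p[1] for p in pairs],
         "p": pvals, "p_adj": p_adj}
    )
    # headline contrast: most-depleted decile against everything else
    bottom, rest = ot[bins[0]], np.concatenate([ot[b] for b in bins[1:]])
    if np.var(bottom) == 0 and np.var(rest) == 0:
        bvr = {"t": 0.0, "p": 1.0}
    else:
        res = stats.ttest_ind(bottom, rest, equal_var=False)
        bvr = {"t": float(res.statistic), "p": float(res.pvalue)}
    out = {"decile_summary": summary, "pairwise_tests": pairwise,
           "bottom_vs_rest": bvr}
    if hit_genes is not None:
        hits = set(hit_genes)
        targ = rec[rec["guide_class"] == "mirna_targeting"]
        targ = targ.loc[targ.index.intersection(x.index)]
        groups = {
            "hit": targ.loc[targ["gene_id"].isin(hits), "offtarget_count"].to_numpy(float),
            "non_hit": targ.loc[~targ["gene_id"].isin(hits), "offtarget_count"].to_numpy(float),
        }
        groups = {k: v for k, v in groups.items() if len(v) > 1}
        if len(groups) == 2:
            kw = stats.kruskal(*groups.values())
            out["hit_comparison"] = {
                "kruskal_h": float(kw.statistic),
                "kruskal_p": float(kw.pvalue),
                "dunn": _dunn_test(groups),
            }
    return out
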