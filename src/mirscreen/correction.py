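"""Depth normalization, log2 fold changes, and copy-number bias correction.

In a negative-selection screen, guides cutting inside an amplified genomic
region deplete regardless of whether the targeted gene matters — the cell
responds to the extra double-strand breaks, not the knockout.  Because
this gene-independent artifact is spatially coherent along the genome, it
can be removed without copy-number data: sort guide LFCs by genomic
position, segment each chromosome by recursive mean-shift (CBS-style)
binary segmentation with permutation-assessed significance, and
mean-center every sufficiently large segment whose mean LFC deviates
from zero.

Alternative corrections (e.g. supervised, copy-number-aware ones) can be
compared to this one through rank-biased overlap (RBO) of the corrected
guide rankings, a top-weighted list-similarity measure governed by a
persistence parameter p; :func:`solve_rbo_weight` inverts the prefix-mass
identity so that a stated fraction of the score mass sits in the top-d
ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .library import CountTable, GuideLibrary

LFC_COLUMNS = [
    "guide_id",
    "screen_id",
    "replicate_id",
    "lfc_raw",
    "lfc_corrected",
    "segment_id",
    "corrected_count",
]


def normalize_counts(counts: CountTable, pseudocount: float = 0.0) -> CountTable:
    """Scale every sample to the mean of the sample totals.

    The pseudocount is *not* added here; it enters at ratio-taking time in
    :func:`compute_lfc`.  A sample whose total is zero is an error.
    """
    mat = counts.counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    if (totals <= 0).any():
        bad = [c for c, t in zip(counts.counts.columns, totals) if t <= 0]
        raise ValueError(f"sample(s) with zero total reads: {bad}")
    target = totals.mean()
    norm = mat * (target / totals)
    out = CountTable(
        pd.DataFrame(norm, index=counts.counts.index, columns=counts.counts.columns),
        counts.samples.copy(),
    )
    return out


def compute_lfc(
    norm: CountTable, plasmid_id: str | None = None, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-replicate guide log2 fold changes versus the plasmid reference.

    lfc_raw = log2((count + pc) / (plasmid + pc)) on depth-normalized
    counts.  Returns a long table with the LfcTable schema; corrected
    columns are initialized equal to the raw values.
    """
    plasmid_id = plasmid_id or norm.plasmid_id
    if plasmid_id not in norm.counts.columns:
        raise ValueError(f"plasmid sample {plasmid_id!r} not in count table")
    plasmid = norm.counts[plasmid_id].to_numpy(dtype=float)
    frames = []
    for sid in norm.replicate_ids:
        x = norm.counts[sid].to_numpy(dtype=float)
        lfc = np.log2((x + pseudocount) / (plasmid + pseudocount))
        frames.append(
            pd.DataFrame(
                {
                    "guide_id": norm.counts.index,
                    "screen_id": str(norm.samples.loc[sid, "cell_line"]),
                    "replicate_id": sid,
                    "lfc_raw": lfc,
                    "lfc_corrected": lfc,
                    "segment_id": pd.Series([None] * len(x), dtype=object),
                    "corrected_count": x,
                    "plasmid_norm": plasmid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def guide_lfc_matrix(lfc: pd.DataFrame, value: str = "lfc_corrected") -> pd.DataFrame:
    """Pivot a long LfcTable to guides × replicates (columns = replicate_id)."""
    return lfc.pivot(index="guide_id", columns="replicate_id", values=value)


def screen_mean_lfc(lfc: pd.DataFrame, value: str = "lfc_corrected") -> pd.DataFrame:
    """Guide-level LFC averaged over replicates, one column per screen."""
    return lfc.pivot_table(index="guide_id", columns="screen_id", values=value, aggfunc="mean")


# ---------------------------------------------------------------------------
# CBS-style segmentation


def _batch_max_arc(xs: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise best arc (contiguous window vs the rest) by mean-shift score.

    ``xs`` is (B, n).  Returns (score_max, i_start, j_end) per row; the
    arc is xs[b, i:j].  This is the CBS-style statistic: a single binary
    split cannot see a segment embedded in a flat background, an arc can.
    The score is the squared two-sample t statistic up to the constant
    degrees-of-freedom factor, which cancels when scores of arcs within
    one region (observed or permuted) are compared.
    """
    xs = np.ascontiguousarray(xs, dtype=np.float32)
    B, n = xs.shape
    S = np.empty((B, n + 1), dtype=np.float32)
    S[:, 0] = 0.0
    np.cumsum(xs, axis=1, out=S[:, 1:])
    SS = np.empty((B, n + 1), dtype=np.float32)
    SS[:, 0] = 0.0
    np.cumsum(xs * xs, axis=1, out=SS[:, 1:])
    tot = S[:, -1][:, None]
    tot_ss = SS[:, -1][:, None]
    best_t = np.zeros(B, dtype=np.float32)
    best_i = np.zeros(B, dtype=int)
    best_j = np.full(B, n, dtype=int)
    rows = np.arange(B)
    for L in range(min_len, n):  # outside must be non-empty
        m = n - L + 1  # number of start positions
        s_in = S[:, L : L + m] - S[:, :m]
        ss_in = SS[:, L : L + m] - SS[:, :m]
        diff = s_in / np.float32(L) - (tot - s_in) / np.float32(n - L)
        var_in = ss_in - (s_in * s_in) / np.float32(L)
        var_out = (tot_ss - ss_in) - ((tot - s_in) ** 2) / np.float32(n - L)
        denom = np.maximum(var_in + var_out, np.float32(1e-12)) * np.float32(
            1.0 / L + 1.0 / (n - L)
        )
        t = (diff * diff) / denom
        idx = np.argmax(t, axis=1)
        t_here = t[rows, idx]
        upd = t_here > best_t
        best_t[upd] = t_here[upd]
        best_i[upd] = idx[upd]
        best_j[upd] = idx[upd] + L
    return best_t.astype(float), best_i, best_j


def _arc_is_significant(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    n_perm: int,
    min_len: int,
    rng: np.random.Generator,
    batch: int = 100,
) -> bool:
    """Permutation test of the max-arc statistic with early stopping.

    Stops as soon as the decision at level ``alpha`` is determined (the
    exceedance count already implies p ≥ alpha, or all permutations are
    spent); the decision is identical to running all ``n_perm``.
    """
    not_sig_at = alpha * (n_perm + 1) - 1  # exceedances implying p >= alpha
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.tile(x, (b, 1)), axis=1)
        t_null, _, _ = _batch_max_arc(perm, min_len)
        exceed += int(np.sum(t_null >= t_obs))
        done += b
        if exceed >= not_sig_at:
            return False
    return (1.0 + exceed) / (n_perm + 1.0) < alpha


def _segment_recursive(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    n_perm: int,
    min_size: int,
    rng: np.random.Generator,
    breakpoints: list[int],
) -> None:
    n = hi - lo
    if n < min_size + 1:
        return
    seg = x[lo:hi]
    t_obs, i, j = _batch_max_arc(seg[None, :], min_size)
    t_obs, i, j = float(t_obs[0]), int(i[0]), int(j[0])
    if not _arc_is_significant(seg, t_obs, alpha, n_perm, min_size, rng):
        return
    for bp in (i, j):
        if 0 < bp < n:
            breakpoints.append(lo + bp)
    _segment_recursive(x, lo, lo + i, alpha, n_perm, min_size, rng, breakpoints)
    _segment_recursive(x, lo + i, lo + j, alpha, n_perm, min_size, rng, breakpoints)
    _segment_recursive(x, lo + j, hi, alpha, n_perm, min_size, rng, breakpoints)


def segment_chromosome(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_size: int = 3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Segment an ordered LFC vector; returns a segment label per element."""
    rng = rng or np.random.default_rng(0)
    breakpoints: list[int] = []
    _segment_recursive(x, 0, len(x), alpha, n_perm, min_size, rng, breakpoints)
    labels = np.zeros(len(x), dtype=int)
    for bp in sorted(breakpoints):
        labels[bp:] += 1
    return labels


def segment_correct(
    lfc: pd.DataFrame,
    lib: GuideLibrary,
    min_guides: int = 3,
    seg_alpha: float = 0.01,
    n_perm: int = 1000,
    rng_seed: int = 0,
    min_genes: int | None = 3,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Remove gene-independent positional bias from guide LFCs.

    Per replicate and chromosome, guides are ordered by position and the
    LFC profile is recursively segmented; every segment with at least
    ``min_guides`` guides whose mean differs from 0 at ``seg_alpha``
    (one-sample t-test) is mean-centered.  A corrected segment must also
    span ``min_genes`` distinct genes (pass None to disable): in a
    library whose guides cluster tightly on their target stem-loops, a
    single strongly essential gene is itself a contiguous mean-shifted
    run, and centering it would erase real signal rather than a
    copy-number artifact.  Corrected counts are re-derived so that
    recomputing LFCs from them reproduces ``lfc_corrected`` exactly.
    """
    coords = lib.records.set_index("guide_id")[["chrom", "pos", "gene_id"]]
    out = lfc.copy()
    rng = np.random.default_rng(rng_seed)
    for rep_id, sub in lfc.groupby("replicate_id", sort=False):
        targeting = sub.join(coords, on="guide_id")  # keeps lfc's row index
        targeting = targeting[targeting["chrom"].notna()]
        for chrom, chrom_df in targeting.groupby("chrom", sort=True):
            if len(chrom_df) < min_guides:
                continue
            if not chrom_df["pos"].is_monotonic_increasing:
                chrom_df = chrom_df.sort_values("pos", kind="stable")
            x = chrom_df["lfc_raw"].to_numpy(dtype=float)
            labels = segment_chromosome(
                x, alpha=seg_alpha, n_perm=n_perm, min_size=min_guides, rng=rng
            )
            corrected = x.copy()
            seg_names = np.array([None] * len(x), dtype=object)
            for lab in np.unique(labels):
                mask = labels == lab
                if mask.sum() < min_guides:
                    continue
                if min_genes is not None:
                    if chrom_df.loc[mask, "gene_id"].nunique() < min_genes:
                        continue
                seg = x[mask]
                if np.std(seg, ddof=1) == 0:
                    shifted = seg[0] != 0
                else:
                    _, p0 = stats.ttest_1samp(seg, 0.0)
                    shifted = p0 < seg_alpha
                if shifted:
                    corrected[mask] = seg - seg.mean()
                    seg_names[mask] = f"{rep_id}:{chrom}:{lab}"
            rows = chrom_df.index
            out.loc[rows, "lfc_corrected"] = corrected
            out.loc[rows, "segment_id"] = seg_names
    # exact inverse of compute_lfc so the round trip is identity
    out["corrected_count"] = (
        (out["plasmid_norm"] + pseudocount) * np.exp2(out["lfc_corrected"]) - pseudocount
    )
    return out


# ---------------------------------------------------------------------------
# Rank-biased overlap


@dataclass
class RboConfig:
    """RBO persistence tuned so the top ``anchor_depth`` ranks carry
    ``anchor_mass`` of the score weight."""

    anchor_depth: int = 30
    anchor_mass: float = 0.9289
    eval_depths: tuple[int, ...] = (50, 100, 200, 300, 400)
    p: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p is None:
            self.p = solve_rbo_weight(self.anchor_depth, self.anchor_mass)
        if abs(rbo_prefix_weight(self.p, self.anchor_depth) - self.anchor_mass) > 1e-6:
            raise ValueError("persistence p inconsistent with anchor depth/mass")


def rbo_prefix_weight(p: float, d: int) -> float:
    """Fraction of total RBO weight carried by the top-d ranks.

    Webber's prefix-mass identity:
    W(p, d) = 1 − p^(d−1) + d(1−p)/p · (ln(1/(1−p)) − Σ_{i=1}^{d−1} p^i / i).
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0,1)")
    if d < 1:
        raise ValueError("d must be >= 1")
    i = np.arange(1, d)
    tail = np.log(1.0 / (1.0 - p)) - np.sum(p**i / i)
    return float(1.0 - p ** (d - 1) + d * (1.0 - p) / p * tail)


def solve_rbo_weight(d_star: int, mass: float) -> float:
    """Persistence p for which the top-d* ranks carry the given weight mass.

    W(p, d) decreases from 1 to a d-dependent floor as p → 1, so the root
    is found by bisection (brentq) on (0, 1) to 1e−8.
    """
    if d_star < 1:
        raise ValueError("d_star must be >= 1")
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0,1)")
    f = lambda p: rbo_prefix_weight(p, d_star) - mass
    lo, hi = 1e-9, 1.0 - 1e-9
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(f"no persistence in (0,1) yields mass {mass} at depth {d_star}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


def rbo_similarity(
    rank_a: list | np.ndarray | pd.Index,
    rank_b: list | np.ndarray | pd.Index,
    cfg: RboConfig | None = None,
    depths: tuple[int, ...] | None = None,
) -> dict[int, float]:
    """Extrapolated rank-biased overlap of two rankings at each depth.

    RBO_ext(k) = (X_k / k) p^k + (1−p)/p Σ_{d=1..k} (X_d / d) p^d where
    X_d is the size of the intersection of the two depth-d prefixes.
    Symmetric; 1.0 for identical rankings, 0.0 for prefix-disjoint ones.
    """
    cfg = cfg or RboConfig()
    depths = depths or cfg.eval_depths
    a = list(rank_a)
    b = list(rank_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("rankings must not contain duplicates")
    p = cfg.p
    kmax = min(max(depths), len(a), len(b))
    seen_a: set = set()
    seen_b: set = set()
    overlap = np.zeros(kmax + 1)
    x = 0
    for d in range(1, kmax + 1):
        ea, eb = a[d - 1], b[d - 1]
        if ea == eb:
            x += 1
        else:
            x += (ea in seen_b) + (eb in seen_a)
        seen_a.add(ea)
        seen_b.add(eb)
        overlap[d] = x
    d_arr = np.arange(1, kmax + 1)
    agree = overlap[1:] / d_arr
    weights = p**d_arr
    partial = np.cumsum(agree * weights)
    out: dict[int, float] = {}
    for k in depths:
        kk = min(k, kmax)
        val = agree[kk - 1] * p**kk + (1 - p) / p * partial[kk - 1]
        out[int(k)] = float(min(1.0, max(0.0, val)))
    return out
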