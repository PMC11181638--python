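"""Seeded generator of pooled miRNA-knockout screens with known truth.

The generator emulates the statistical structure every analysis stage
assumes: a lognormal plasmid abundance profile, negative-binomial
replicate counts around depth × abundance, planted gene-level fitness
effects (common essential in every screen, context-specific in a random
subset of screens, null elsewhere), per-guide knockout efficacies drawn
from a Beta distribution, and contiguous genomic segments that depress
every guide cutting inside them regardless of target — the copy-number
artifact.  All randomness flows from a single seed, and identical
configs + seeds reproduce count tables bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import CountTable, GuideLibrary

CHROMS = ("chr1", "chr2", "chr3", "chr4", "chr5")
_BASES = np.array(list("ACGT"))

# Guides-per-gene composition of the published miRNA-targeting knockout
# library this pipeline was designed around: 1769 targetable miRNA genes,
# 1414 of which reach the 5-guide quota, 8105 targeting guides in total
# (93% of genes covered by >= 3 guides).
REFERENCE_COMPOSITION: dict[int, int] = {5: 1414, 4: 135, 3: 102, 2: 71, 1: 47}


def reference_library_config(seed: int = 0, **overrides) -> "SimConfig":
    """SimConfig whose miRNA gene/guide composition matches the published
    reference library exactly (synthetic stand-in: sequences, coordinates
    and controls are generated, only the composition is real)."""
    n_genes = sum(REFERENCE_COMPOSITION.values())
    dist = {k: v / n_genes for k, v in REFERENCE_COMPOSITION.items()}
    kw = dict(
        n_genes=n_genes,
        guides_per_gene_dist=dist,
        n_essential_controls=40,
        n_intergenic=500,
        n_nontargeting=100,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class SimConfig:
    """Study conditions for a synthetic screen panel.

    Defaults follow a desk-scale version of a 45-line miRNA panel: ~500×
    sequencing depth per construct, five guides for most genes, strong
    (−1.5 LFC) common-essential effects, high but variable guide efficacy
    (Beta(5,1), mean 0.83), mild negative-binomial overdispersion, and one
    amplified region adding a gene-independent −0.8 LFC bias.
    """

    n_genes: int = 400
    guides_per_gene_dist: dict[int, float] = field(
        default_factory=lambda: {5: 0.80, 4: 0.08, 3: 0.06, 2: 0.04, 1: 0.02}
    )
    n_essential_controls: int = 20
    guides_per_control: int = 5
    n_intergenic: int = 150
    n_nontargeting: int = 50
    n_screens: int = 12
    n_replicates: int = 3
    depth: float = 500.0
    plasmid_depth_factor: float = 10.0  # plasmid reference sequenced deeper
    plasmid_mu: float = 0.0
    plasmid_sigma: float = 0.5
    n_common_essential: int = 8
    common_effect: float = -1.5
    n_context_essential: int = 40
    context_effect: float = -1.5
    context_inclusion_prob: float = 0.3
    essential_control_effect: float = -1.5
    efficacy_a: float = 5.0
    efficacy_b: float = 1.0
    nb_dispersion: float = 0.01  # variance = mu + alpha * mu^2
    cn_segments: tuple[tuple[str, int, int, float], ...] = (
        ("chr3", 1_000_000, 1_300_000, -0.8),
    )
    noise_sd: float = 0.0  # extra per-replicate LFC-scale gaussian noise
    matched_fraction_mean: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.guides_per_gene_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("guides_per_gene_dist probabilities must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_common_essential + self.n_context_essential > self.n_genes:
            raise ValueError("planted effect classes exceed n_genes")


@dataclass
class SimTruth:
    """Planted ground truth: per-gene class/effect, per-guide efficacy and
    CN bias, per-screen context-effect inclusion, and the seed."""

    genes: pd.DataFrame  # gene_id, gene_class, effect
    guides: pd.DataFrame  # guide_id, efficacy, cn_bias, cn_segment
    context_matrix: pd.DataFrame  # genes x screens, bool inclusion
    seed: int

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.genes.index[self.genes["gene_class"] == cls])

    def effect_in_screen(self, screen_id: str) -> pd.Series:
        eff = self.genes["effect"].copy()
        ctx = self.context_matrix[screen_id]
        mask = (self.genes["gene_class"] == "context") & ~ctx.reindex(eff.index).fillna(False)
        eff[mask] = 0.0
        return eff


def _gene_quotas(cfg: SimConfig) -> list[int]:
    """Deterministic guide-count quota per gene (largest remainder)."""
    sizes = sorted(cfg.guides_per_gene_dist, reverse=True)
    exact = {s: cfg.guides_per_gene_dist[s] * cfg.n_genes for s in sizes}
    counts = {s: int(np.floor(exact[s])) for s in sizes}
    short = cfg.n_genes - sum(counts.values())
    for s in sorted(sizes, key=lambda s: exact[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    quotas: list[int] = []
    for s in sizes:
        quotas.extend([s] * counts[s])
    return quotas


def simulate_library(cfg: SimConfig) -> tuple[GuideLibrary, SimTruth]:
    """Build a synthetic guide library and its ground truth.

    Genes (miRNA plus essential controls) and single intergenic guides are
    shuffled into placement units, distributed across five chromosomes in
    order, and spaced 10 kb apart with guides of one gene clustered within
    a few hundred bp — so genomic neighbourhoods mix gene classes, as the
    segmentation correction assumes.
    """
    rng = np.random.default_rng(cfg.seed)
    quotas = _gene_quotas(cfg)

    gene_rows = []
    units: list[tuple[str, str, int]] = []  # (kind, gene_id, n_guides)
    for i, q in enumerate(quotas):
        gene_rows.append((f"MIRSIM{i:04d}", q))
        units.append(("mirna_targeting", f"MIRSIM{i:04d}", q))
    for i in range(cfg.n_essential_controls):
        units.append(("essential_control", f"ESSCTL{i:03d}", cfg.guides_per_control))
    for i in range(cfg.n_intergenic):
        units.append(("intergenic_control", f"INTERGENIC_{i:04d}", 1))
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # planted classes for miRNA genes
    mirna_ids = [g for g, _ in gene_rows]
    chosen = rng.choice(len(mirna_ids), size=cfg.n_common_essential + cfg.n_context_essential,
                        replace=False)
    common_ids = {mirna_ids[i] for i in chosen[: cfg.n_common_essential]}
    context_ids = {mirna_ids[i] for i in chosen[cfg.n_common_essential :]}

    per_chrom = int(np.ceil(len(units) / len(CHROMS)))
    records = []
    for u_idx, (kind, gene_id, n_guides) in enumerate(units):
        chrom = CHROMS[u_idx // per_chrom]
        base_pos = ((u_idx % per_chrom) + 1) * 10_000
        for j in range(n_guides):
            spacer = "".join(rng.choice(_BASES, size=20))
            records.append(
                {
                    "guide_id": f"{gene_id}_g{j + 1}",
                    "spacer": spacer,
                    "gene_id": gene_id,
                    "guide_class": kind,
                    "chrom": chrom,
                    "pos": base_pos + 30 * j,
                    "strand": "+" if (u_idx + j) % 2 == 0 else "-",
                    "offtarget_count": int(rng.poisson(0.3)),
                }
            )
    for i in range(cfg.n_nontargeting):
        records.append(
            {
                "guide_id": f"NONTARGET_{i:04d}_g1",
                "spacer": "".join(rng.choice(_BASES, size=20)),
                "gene_id": f"NONTARGET_{i:04d}",
                "guide_class": "non_targeting",
                "chrom": None,
                "pos": None,
                "strand": None,
                "offtarget_count": 0,
            }
        )
    lib = GuideLibrary(pd.DataFrame(records))

    gene_class = {}
    effect = {}
    for gid, _ in gene_rows:
        if gid in common_ids:
            gene_class[gid], effect[gid] = "common_essential", cfg.common_effect
        elif gid in context_ids:
            gene_class[gid], effect[gid] = "context", cfg.context_effect
        else:
            gene_class[gid], effect[gid] = "null", 0.0
    for i in range(cfg.n_essential_controls):
        gid = f"ESSCTL{i:03d}"
        gene_class[gid], effect[gid] = "essential_control", cfg.essential_control_effect
    for gid in lib.gene_index:
        if gid not in gene_class:
            gene_class[gid], effect[gid] = "control_null", 0.0
    genes = pd.DataFrame(
        {"gene_class": pd.Series(gene_class), "effect": pd.Series(effect)}
    ).rename_axis("gene_id")

    efficacy = pd.Series(
        rng.beta(cfg.efficacy_a, cfg.efficacy_b, size=len(lib)),
        index=lib.guide_ids,
        name="efficacy",
    )
    # guides without a target knock nothing out
    no_target = lib.records["guide_class"].isin(["non_targeting", "intergenic_control"])
    efficacy[lib.records.loc[no_target.to_numpy(), "guide_id"].to_numpy()] = 0.0

    cn_bias = np.zeros(len(lib))
    cn_label = np.array([None] * len(lib), dtype=object)
    chrom_arr = lib.records["chrom"].to_numpy()
    pos_arr = lib.records["pos"].to_numpy(dtype=object)
    for s_idx, (chrom, start, end, bias) in enumerate(cfg.cn_segments):
        inside = np.array(
            [
                (c == chrom and p is not None and not pd.isna(p) and start <= p <= end)
                for c, p in zip(chrom_arr, pos_arr)
            ]
        )
        cn_bias[inside] += bias
        cn_label[inside] = f"cnseg_{s_idx}"
    guides = pd.DataFrame(
        {
            "efficacy": efficacy.to_numpy(),
            "cn_bias": cn_bias,
            "cn_segment": cn_label,
        },
        index=lib.guide_ids.rename("guide_id"),
    )

    screens = [f"CL{i:02d}" for i in range(cfg.n_screens)]
    ctx = pd.DataFrame(
        rng.random((len(genes), cfg.n_screens)) < cfg.context_inclusion_prob,
        index=genes.index,
        columns=screens,
    )
    ctx[genes["gene_class"] != "context"] = False
    truth = SimTruth(genes=genes, guides=guides, context_matrix=ctx, seed=cfg.seed)
    return lib, truth


def simulate_panel(lib: GuideLibrary, truth: SimTruth, cfg: SimConfig) -> CountTable:
    """Sample plasmid + screen×replicate counts for a simulated library.

    Expected replicate count per guide = depth·N·p_g·2^(efficacy·effect +
    cn_bias), with counts drawn negative-binomially (variance μ + αμ²).
    One shared plasmid pool serves every screen.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(lib)
    abundance = rng.lognormal(cfg.plasmid_mu, cfg.plasmid_sigma, size=n)
    props = abundance / abundance.sum()
    total_reads = cfg.depth * n

    def nb_sample(mu: np.ndarray) -> np.ndarray:
        if cfg.nb_dispersion <= 0:
            return rng.poisson(mu)
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    cols = {}
    meta = {}
    # The single plasmid pool is the reference for every screen, so its
    # measurement noise correlates gene ranks panel-wide.  It is sequenced
    # deeper than screen replicates and, being a clean library prep with
    # no biological/bottleneck variation, is Poisson rather than NB.
    cols["plasmid"] = rng.poisson(cfg.plasmid_depth_factor * total_reads * props)
    meta["plasmid"] = {
        "cell_line": "plasmid",
        "replicate": "ref",
        "is_plasmid": True,
        "matched_fraction": float(np.clip(rng.normal(cfg.matched_fraction_mean, 0.01), 0, 1)),
    }
    g2g = lib.guide_to_gene
    eff_vec = truth.guides["efficacy"].reindex(lib.guide_ids).to_numpy()
    cn_vec = truth.guides["cn_bias"].reindex(lib.guide_ids).to_numpy()
    for screen in truth.context_matrix.columns:
        gene_effect = truth.effect_in_screen(screen)
        guide_effect = gene_effect.reindex(g2g.to_numpy()).fillna(0.0).to_numpy()
        lfc_expected = eff_vec * guide_effect + cn_vec
        for rep in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
            )
            mu = total_reads * props * np.exp2(lfc_expected + noise)
            sid = f"{screen}_rep{rep + 1}"
            cols[sid] = nb_sample(mu)
            meta[sid] = {
                "cell_line": screen,
                "replicate": f"rep{rep + 1}",
                "is_plasmid": False,
                "matched_fraction": float(
                    np.clip(rng.normal(cfg.matched_fraction_mean, 0.01), 0, 1)
                ),
            }
    counts = pd.DataFrame(cols, index=lib.guide_ids.rename("guide_id"))
    samples = pd.DataFrame.from_dict(meta, orient="index")
    return CountTable(counts, samples)


def evaluate_recovery(
    called, truth: SimTruth, positive_classes: tuple[str, ...] = ("common_essential",)
) -> dict:
    """Confusion-matrix metrics of a call set against planted classes.

    Only miRNA-gene classes are evaluated (controls are excluded from the
    universe).  FDR = FP / max(TP + FP, 1).
    """
    called = set(called)
    universe = truth.genes.index[
        truth.genes["gene_class"].isin(["common_essential", "context", "null"])
    ]
    positives = set(truth.genes.index[truth.genes["gene_class"].isin(positive_classes)])
    positives &= set(universe)
    called &= set(universe)
    tp = len(called & positives)
    fp = len(called - positives)
    fn = len(positives - called)
    tn = len(set(universe) - called - positives)
    sens = tp / len(positives) if positives else float("nan")
    fdr = fp / max(tp + fp, 1)
    fpr = fp / max(fp + tn, 1)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "fdr": fdr, "fpr": fpr,
    }
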