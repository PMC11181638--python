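"""End-to-end orchestration: qc → correct → call → integrate → cegs.

A single :class:`RunConfig` (YAML-loadable) names the input files and all
stage parameters; :func:`run_pipeline` executes the stages in order,
writing TSV/JSON outputs plus a run manifest that records parameters,
input hashes, per-stage status, and the seed.  A rerun with an identical
config and seed reuses completed stages (byte-identical outputs); any
config change invalidates the cache.  The global seed fans out to
per-stage seeds by stable hashing of the stage name, so stages are
individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_essentials, correction, essentiality, integration, qc
from .library import GuideLibrary, read_counts, read_library

logger = logging.getLogger("mirscreen")

STAGES = ("qc", "correct", "call", "integrate", "cegs")


@dataclass
class RunConfig:
    library_path: str
    counts_path: str
    metadata_path: str
    output_dir: str
    host_annotation_path: str | None = None
    min_matched_fraction: float = 0.60
    min_mean_coverage: float = 100.0
    pseudocount: float = 0.5
    min_seg_guides: int = 3
    seg_alpha: float = 0.01
    seg_permutations: int = 1000
    fdr_threshold: float = 0.10
    rra_alpha: float | None = None
    rra_permutations: int = 1000
    bf_bootstraps: int = 200
    depleted_cutoff: float = -0.5
    ceg_percentile: float = 0.90
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, resume: bool = True) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = cfg.config_hash()
    prev = {}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == chash:
            prev = {s: st for s, st in old.get("stages", {}).items() if st.get("status") == "ok"}
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "config_hash": chash,
        "seed": cfg.seed,
        "inputs": {},
        "stages": {},
    }
    for key in ("library_path", "counts_path", "metadata_path"):
        p = getattr(cfg, key)
        if not Path(p).exists():
            manifest["stages"]["load"] = {"status": "failed", "error": f"missing file: {p}"}
            _write_manifest(manifest, manifest_path)
            raise FileNotFoundError(p)
        manifest["inputs"][key] = {"path": p, "sha256": _file_hash(p)}

    lib = read_library(cfg.library_path)
    counts = read_counts(cfg.counts_path, cfg.metadata_path, lib)
    state: dict = {"lib": lib, "counts": counts}
    for stage in STAGES:
        done_marker = out / f".{stage}.done"
        if stage in prev and done_marker.exists():
            logger.info("stage %s: cached, skipping", stage)
            manifest["stages"][stage] = prev[stage] | {"cached": True}
            _load_stage_state(stage, out, state, cfg)
            continue
        logger.info("stage %s: running", stage)
        try:
            params = _run_stage(stage, cfg, state, out)
        except Exception as exc:  # noqa: BLE001 - manifest must record the failure
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, manifest_path)
            raise
        manifest["stages"][stage] = {"status": "ok", "params": params}
        done_marker.write_text("ok\n")
        _write_manifest(manifest, manifest_path)
    _write_manifest(manifest, manifest_path)
    return manifest


def _write_manifest(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _run_stage(stage: str, cfg: RunConfig, state: dict, out: Path) -> dict:
    lib: GuideLibrary = state["lib"]
    if stage == "qc":
        thr = qc.QcThresholds(cfg.min_matched_fraction, cfg.min_mean_coverage)
        report = qc.replicate_read_qc(state["counts"], lib, thr)
        report.to_csv(out / "qc_replicates.tsv", sep="\t")
        state["passing_replicates"] = list(report.index[report["passed"]])
        return {"n_pass": int(report["passed"].sum()), "n_fail": int((~report["passed"]).sum())}

    if stage == "correct":
        counts = state["counts"]
        keep = state["passing_replicates"] + [counts.plasmid_id]
        sub = counts.__class__(counts.counts[keep], counts.samples.loc[keep])
        norm = correction.normalize_counts(sub)
        lfc = correction.compute_lfc(norm, pseudocount=cfg.pseudocount)
        lfc = correction.segment_correct(
            lfc,
            lib,
            min_guides=cfg.min_seg_guides,
            seg_alpha=cfg.seg_alpha,
            n_perm=cfg.seg_permutations,
            rng_seed=stage_seed(cfg.seed, "correct"),
            pseudocount=cfg.pseudocount,
        )
        lfc.to_csv(out / "lfc_corrected.tsv", sep="\t", index=False)
        state["lfc"] = lfc
        n_seg = int(lfc["segment_id"].notna().sum())
        return {"n_corrected_guide_lfcs": n_seg}

    if stage == "call":
        lfc = state["lfc"]
        guide_by_screen = correction.screen_mean_lfc(lfc)
        pseudogenes = integration.make_intergenic_pseudogenes(lib)
        state["pseudogenes"] = pseudogenes
        calls = {}
        frames = []
        for i, screen in enumerate(guide_by_screen.columns):
            res = essentiality.score_screen(
                guide_by_screen[screen].dropna(),
                lib,
                fdr_threshold=cfg.fdr_threshold,
                n_boot=cfg.bf_bootstraps,
                n_perm=cfg.rra_permutations,
                alpha=cfg.rra_alpha,
                rng_seed=stage_seed(cfg.seed, f"call:{screen}"),
                pseudogenes=pseudogenes,
            )
            calls[screen] = res
            merged = res["bf"].join(
                res["rra"].add_prefix("rra_"), how="outer"
            )
            merged["consensus_flag"] = merged.index.isin(res["consensus"]["all_significant"])
            merged.insert(0, "screen_id", screen)
            frames.append(merged.rename_axis("gene_id").reset_index())
        pd.concat(frames, ignore_index=True).to_csv(
            out / "essentiality_calls.tsv", sep="\t", index=False
        )
        state["calls"] = calls
        n_fit = {s: len(r["consensus"]["fitness_genes"]) for s, r in calls.items()}
        return {"fitness_genes_per_screen": n_fit}

    if stage == "integrate":
        lfc = state["lfc"]
        pseudogenes = state.get("pseudogenes") or integration.make_intergenic_pseudogenes(lib)
        guide_by_screen = correction.screen_mean_lfc(lfc)
        pg_map = integration.pseudogene_guide_map(pseudogenes)
        g2g = lib.guide_to_gene.copy()
        g2g.loc[pg_map.index] = pg_map
        gene_lfc = guide_by_screen.groupby(g2g.reindex(guide_by_screen.index)).mean()
        ess_genes = lib.genes_of_class("essential_control")
        scaled = pd.DataFrame(
            {
                s: integration.scale_lfcs(gene_lfc[s], ess_genes, sorted(pseudogenes))
                for s in gene_lfc.columns
            }
        )
        mirna = lib.genes_of_class("mirna_targeting")
        if cfg.host_annotation_path:
            ann = pd.read_csv(cfg.host_annotation_path, sep="\t")
            mirna, removed = integration.host_gene_filter(mirna, ann)
            removed.to_csv(out / "host_filtered_genes.tsv", sep="\t", index=False)
        dep = integration.depleted_fraction(scaled, cfg.depleted_cutoff, gene_ids=mirna)
        scaled.rename_axis("gene_id").to_csv(out / "gene_lfc_scaled.tsv", sep="\t")
        gene_lfc.rename_axis("gene_id").to_csv(out / "gene_lfc.tsv", sep="\t")
        state["scaled"] = scaled
        state["gene_lfc"] = gene_lfc
        state["mirna_universe"] = mirna
        return {
            "mean_depleted_fraction": dep["mean_fraction"],
            "fraction_any_screen": dep["fraction_any_screen"],
            "n_mirna_genes": len(mirna),
        }

    if stage == "cegs":
        scaled = state["scaled"].loc[state["mirna_universe"]]
        results = core_essentials.call_common_essentials(scaled, cfg.ceg_percentile)
        rows = []
        summary = {}
        for variant, res in results.items():
            summary[variant] = {
                "threshold": res.threshold,
                "n_ceg": len(res.ceg_set),
                "unimodal": res.unimodal,
            }
            rows.append(
                res.scores.rename(f"score_{variant}").to_frame().assign(
                    **{f"ceg_{variant}": res.scores.index.isin(res.ceg_set)}
                )
            )
        table = pd.concat(rows, axis=1)
        table.rename_axis("gene_id").to_csv(out / "common_essentials.tsv", sep="\t")
        with open(out / "ceg_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        state["cegs"] = results
        return summary

    raise ValueError(f"unknown stage {stage!r}")


def run_synthetic_study(
    seed: int,
    output_dir: str | Path,
    sim_overrides: dict | None = None,
    **config_overrides,
) -> dict:
    """Full pipeline on a freshly simulated panel, scored against truth.

    Simulates a default-condition screen panel, writes its files, runs
    every pipeline stage, and summarizes recovery of the planted effects
    plus the standard screen-quality metrics.  Returns a dict with the
    manifest, the truth object, and a ``summary`` of scalar results.
    """
    from . import qc as qc_mod
    from .library import write_counts, write_library
    from .simulate import SimConfig, evaluate_recovery, simulate_library, simulate_panel

    out = Path(output_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    sim_kw = {"seed": seed}
    sim_kw.update(sim_overrides or {})
    sim_cfg = SimConfig(**sim_kw)
    lib, truth = simulate_library(sim_cfg)
    panel = simulate_panel(lib, truth, sim_cfg)
    write_library(lib, out / "inputs" / "library.csv")
    write_counts(panel, out / "inputs" / "counts.tsv", out / "inputs" / "samples.yaml")

    cfg = RunConfig(
        str(out / "inputs" / "library.csv"),
        str(out / "inputs" / "counts.tsv"),
        str(out / "inputs" / "samples.yaml"),
        str(out / "results"),
        seed=seed,
        **config_overrides,
    )
    manifest = run_pipeline(cfg, resume=False)

    res_dir = Path(cfg.output_dir)
    calls = pd.read_csv(res_dir / "essentiality_calls.tsv", sep="\t")
    scaled = pd.read_csv(res_dir / "gene_lfc_scaled.tsv", sep="\t", index_col=0)
    cegs = pd.read_csv(res_dir / "common_essentials.tsv", sep="\t", index_col=0)
    lfc = pd.read_csv(res_dir / "lfc_corrected.tsv", sep="\t")

    mirna = set(lib.genes_of_class("mirna_targeting"))
    ess_genes = set(lib.genes_of_class("essential_control"))

    # per-screen consensus recovery vs the planted effects active there
    per_screen = []
    for screen, sub in calls.groupby("screen_id"):
        called = set(sub.loc[sub["consensus_flag"], "gene_id"])
        eff = truth.effect_in_screen(screen)
        planted = set(eff.index[(eff < 0) & eff.index.isin(mirna)])
        tp = len(called & planted)
        fp = len((called & mirna) - planted)
        per_screen.append(
            {
                "screen_id": screen,
                "n_fitness": len(called & mirna),
                "sensitivity": tp / len(planted) if planted else float("nan"),
                "fdr": fp / max(tp + fp, 1),
                "recall_essential_controls": len(called & ess_genes) / len(ess_genes),
            }
        )
    per_screen = pd.DataFrame(per_screen).set_index("screen_id")

    # guide-level screen-quality metrics on corrected LFCs
    guide_by_screen = correction.screen_mean_lfc(lfc)
    rec = lib.records
    ess_guides = rec.loc[rec["guide_class"] == "essential_control", "guide_id"]
    int_guides = rec.loc[rec["guide_class"] == "intergenic_control", "guide_id"]
    qrows = []
    for screen in guide_by_screen.columns:
        g = guide_by_screen[screen].dropna()
        es = qc_mod.effect_size_metrics(g, ess_guides, int_guides)
        bf_screen = calls[calls["screen_id"] == screen].set_index("gene_id")["bf"].dropna()
        pseudo = [i for i in bf_screen.index if str(i).startswith("pseudo_")]
        cm = qc_mod.classification_metrics(
            bf_screen, sorted(ess_genes & set(bf_screen.index)), pseudo, bf_rule=True
        )
        qrows.append(
            {"screen_id": screen, **es, "auc_pr": cm["auc_pr"], "f_measure": cm["f_measure"],
             "flag_low_f": cm["f_measure"] < 0.7}
        )
    qc_metrics = pd.DataFrame(qrows).set_index("screen_id")

    ceg_called = list(cegs.index[cegs["ceg_average"]])
    ceg_rec = evaluate_recovery(ceg_called, truth, ("common_essential",))
    dep = integration.depleted_fraction(
        scaled.loc[scaled.index.isin(mirna)], config_overrides.get("depleted_cutoff", -0.5)
    )
    n_screens = scaled.shape[1]
    fitness_any = set(calls.loc[calls["consensus_flag"], "gene_id"]) & mirna
    dep_counts = calls[calls["gene_id"].isin(fitness_any) & calls["consensus_flag"]]
    per_gene_screens = dep_counts.groupby("gene_id").size()
    ceg_majority = [g for g in ceg_called if per_gene_screens.get(g, 0) > n_screens / 2]

    summary = {
        "n_screens": n_screens,
        "median_fitness_genes_per_screen": float(per_screen["n_fitness"].median()),
        "total_fitness_mirnas": len(fitness_any),
        "pct_mirnas_fitness_any_screen": 100.0 * len(fitness_any) / len(mirna),
        "consensus_sensitivity_mean": float(per_screen["sensitivity"].mean()),
        "consensus_fdr_mean": float(per_screen["fdr"].mean()),
        "essential_control_recall_pct": 100.0 * float(per_screen["recall_essential_controls"].mean()),
        "ceg_count": len(ceg_called),
        "ceg_sensitivity": ceg_rec["sensitivity"],
        "ceg_fdr": ceg_rec["fdr"],
        "pct_cegs_essential_majority_of_screens": (
            100.0 * len(ceg_majority) / max(len(ceg_called), 1)
        ),
        "mean_depleted_fraction_pct": 100.0 * dep["mean_fraction"],
        "pct_mirnas_depleted_any_screen": 100.0 * dep["fraction_any_screen"],
        "nnmd_mean": float(qc_metrics["nnmd"].mean()),
        "cohens_d_mean": float(qc_metrics["cohens_d"].mean()),
        "auc_pr_mean": float(qc_metrics["auc_pr"].mean()),
        "f_measure_mean": float(qc_metrics["f_measure"].mean()),
    }
    return {
        "manifest": manifest,
        "truth": truth,
        "lib": lib,
        "summary": summary,
        "per_screen": per_screen,
        "qc_metrics": qc_metrics,
        "ceg_called": ceg_called,
    }


def _load_stage_state(stage: str, out: Path, state: dict, cfg: RunConfig) -> None:
    """Rehydrate the in-memory state a cached stage would have produced."""
    lib: GuideLibrary = state["lib"]
    if stage == "qc":
        report = pd.read_csv(out / "qc_replicates.tsv", sep="\t", index_col=0)
        state["passing_replicates"] = list(report.index[report["passed"]])
    elif stage == "correct":
        state["lfc"] = pd.read_csv(out / "lfc_corrected.tsv", sep="\t")
    elif stage == "call":
        state["pseudogenes"] = integration.make_intergenic_pseudogenes(lib)
        state["calls"] = None  # detailed objects not rehydrated from disk
    elif stage == "integrate":
        state["scaled"] = pd.read_csv(out / "gene_lfc_scaled.tsv", sep="\t", index_col=0)
        state["gene_lfc"] = pd.read_csv(out / "gene_lfc.tsv", sep="\t", index_col=0)
        mirna = lib.genes_of_class("mirna_targeting")
        host_path = cfg.host_annotation_path
        if host_path:
            ann = pd.read_csv(host_path, sep="\t")
            mirna, _ = integration.host_gene_filter(mirna, ann)
        state["mirna_universe"] = mirna
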