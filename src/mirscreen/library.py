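"""Guide library annotations and raw count tables.

A pooled miRNA-knockout library is described by one row per sgRNA: its
20-nt spacer, the miRNA gene (or control class) it targets, its genomic
cut-site coordinate, and a precomputed count of high-confidence
protein-coding off-target sites.  Four guide classes are distinguished:

``mirna_targeting``
    guides against miRNA stem-loops; the objects of the screen.
``essential_control``
    guides against pan-essential protein-coding genes (spliceosome,
    ribosome, transcription factors); positive controls for depletion.
``intergenic_control``
    guides cutting a single non-genic locus; they model Cas9 cutting
    toxicity without gene knockout and anchor the null distribution.
``non_targeting``
    guides with no genomic match; they carry no coordinates.

Counts arrive as PoolQ-style tab-delimited tables (first column
``guide_id``, one column per sample) with a YAML/JSON sidecar mapping each
sample to its cell line / replicate / plasmid role and the fraction of
sequenced reads that matched the library.  Coordinates are 1-based
inclusive throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

GUIDE_CLASSES = frozenset(
    {"mirna_targeting", "essential_control", "intergenic_control", "non_targeting"}
)

LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "gene_id",
    "guide_class",
    "chrom",
    "pos",
    "strand",
    "offtarget_count",
]


class LibraryError(ValueError):
    """Raised when a guide library violates its schema."""


@dataclass
class GuideLibrary:
    """Validated guide annotation table.

    ``records`` keeps file order; ``gene_index`` maps gene_id to the list
    of its guide_ids in that order.
    """

    records: pd.DataFrame
    gene_index: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = _validate_records(self.records)
        idx: dict[str, list[str]] = {}
        for gid, guide in zip(self.records["gene_id"], self.records["guide_id"]):
            idx.setdefault(gid, []).append(guide)
        self.gene_index = idx

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.records["guide_id"])

    def guides_of_class(self, guide_class: str) -> pd.DataFrame:
        if guide_class not in GUIDE_CLASSES:
            raise LibraryError(f"unknown guide_class {guide_class!r}")
        return self.records[self.records["guide_class"] == guide_class]

    def genes_of_class(self, guide_class: str) -> list[str]:
        sub = self.guides_of_class(guide_class)
        return list(dict.fromkeys(sub["gene_id"]))

    @property
    def guide_to_gene(self) -> pd.Series:
        return pd.Series(
            self.records["gene_id"].to_numpy(), index=self.records["guide_id"].to_numpy()
        )


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"library table missing columns: {missing}")
    df = df.loc[:, LIBRARY_COLUMNS].copy().reset_index(drop=True)

    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise LibraryError(f"duplicate guide_id(s): {sorted(set(dup))[:5]}")

    bad_class = set(df["guide_class"]) - GUIDE_CLASSES
    if bad_class:
        raise LibraryError(f"unknown guide_class value(s): {sorted(bad_class)}")

    has_coord = df["chrom"].notna() & (df["chrom"].astype(str) != "")
    nt = df["guide_class"] == "non_targeting"
    if (nt & has_coord).any():
        offenders = df.loc[nt & has_coord, "guide_id"].tolist()[:5]
        raise LibraryError(f"non_targeting guides carry coordinates: {offenders}")
    if (~nt & ~has_coord).any():
        offenders = df.loc[~nt & ~has_coord, "guide_id"].tolist()[:5]
        raise LibraryError(f"targeting guides lack coordinates: {offenders}")

    if df["offtarget_count"].isna().any():
        warnings.warn(
            "offtarget_count missing for some guides; defaulting to 0", stacklevel=3
        )
        df["offtarget_count"] = df["offtarget_count"].fillna(0)
    df["offtarget_count"] = df["offtarget_count"].astype(int)
    if (df["offtarget_count"] < 0).any():
        raise LibraryError("negative offtarget_count")

    df["pos"] = df["pos"].astype("Float64").astype("Int64")
    if ((df.loc[~nt, "pos"] < 1)).any():
        raise LibraryError("coordinates must be 1-based (pos >= 1)")
    return df


def read_library(path: str | Path) -> GuideLibrary:
    """Read a guide library from CSV/TSV (delimiter sniffed from extension).

    Required columns: guide_id, spacer, gene_id, guide_class, chrom, pos,
    strand, offtarget_count.  Coordinates are 1-based.  Duplicated
    guide_ids, unknown classes, and coordinates on non-targeting guides
    are hard errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"guide_id": str, "gene_id": str, "chrom": str})
    return GuideLibrary(df)


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    lib.records.to_csv(path, sep=sep, index=False)


def coverage_summary(lib: GuideLibrary) -> dict:
    """Guides-per-gene distribution over miRNA-targeting genes.

    Returns ``{"per_gene": {k: n_genes}, "fraction_at_least": {k: frac},
    "n_genes": G, "n_guides": total miRNA-targeting guides}``.
    """
    if len(lib) == 0:
        raise LibraryError("empty library")
    sub = lib.guides_of_class("mirna_targeting")
    per_gene = sub.groupby("gene_id").size()
    dist = per_gene.value_counts().sort_index(ascending=False)
    n_genes = int(per_gene.shape[0])
    frac = {
        int(k): float((per_gene >= k).sum()) / n_genes
        for k in sorted(dist.index)
    }
    return {
        "per_gene": {int(k): int(v) for k, v in dist.items()},
        "fraction_at_least": frac,
        "n_genes": n_genes,
        "n_guides": int(len(sub)),
    }


# ---------------------------------------------------------------------------
# Count tables


@dataclass
class CountTable:
    """Guides × samples count matrix plus per-sample metadata.

    ``counts`` is indexed by guide_id with one column per sample;
    ``samples`` is indexed by sample_id with columns ``cell_line``,
    ``replicate``, ``is_plasmid`` and ``matched_fraction``.  Exactly one
    plasmid reference sample is allowed per analysis set.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[list(self.counts.columns)]
        if not np.isfinite(self.counts.to_numpy(dtype=float)).all():
            raise LibraryError("counts contain non-finite values")
        if (self.counts.to_numpy() < 0).any():
            raise LibraryError("negative counts")
        n_plasmid = int(self.samples["is_plasmid"].sum())
        if n_plasmid != 1:
            raise LibraryError(f"expected exactly one plasmid sample, found {n_plasmid}")

    @property
    def plasmid_id(self) -> str:
        return str(self.samples.index[self.samples["is_plasmid"]][0])

    @property
    def replicate_ids(self) -> list[str]:
        return [str(s) for s in self.samples.index[~self.samples["is_plasmid"]]]

    def screens(self) -> dict[str, list[str]]:
        """Map cell line → its replicate sample ids (plasmid excluded)."""
        reps = self.samples[~self.samples["is_plasmid"]]
        out: dict[str, list[str]] = {}
        for sid, cl in zip(reps.index, reps["cell_line"]):
            out.setdefault(str(cl), []).append(str(sid))
        return out

    def check_against_library(self, lib: GuideLibrary) -> None:
        if set(self.counts.index) != set(lib.guide_ids):
            raise LibraryError("count table guide set does not match library")


def read_counts(
    counts_path: str | Path, metadata_path: str | Path, lib: GuideLibrary | None = None
) -> CountTable:
    """Read a PoolQ-style count table plus its sample-metadata sidecar.

    The sidecar (YAML or JSON) maps sample id → ``{cell_line, replicate,
    is_plasmid, matched_fraction}``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    meta_path = Path(metadata_path)
    with open(meta_path) as fh:
        raw = json.load(fh) if meta_path.suffix == ".json" else yaml.safe_load(fh)
    samples = pd.DataFrame.from_dict(raw, orient="index")
    samples.index = samples.index.astype(str)
    for col, default in (
        ("cell_line", ""),
        ("replicate", ""),
        ("is_plasmid", False),
        ("matched_fraction", np.nan),
    ):
        if col not in samples.columns:
            samples[col] = default
    samples["is_plasmid"] = samples["is_plasmid"].astype(bool)
    ct = CountTable(counts, samples)
    if lib is not None:
        ct.check_against_library(lib)
        # keep library order
        ct.counts = ct.counts.loc[lib.guide_ids]
    return ct


def write_counts(ct: CountTable, counts_path: str | Path, metadata_path: str | Path) -> None:
    ct.counts.rename_axis("guide_id").to_csv(counts_path, sep="\t")
    meta = {
        str(sid): {
            "cell_line": str(row["cell_line"]),
            "replicate": str(row["replicate"]),
            "is_plasmid": bool(row["is_plasmid"]),
            "matched_fraction": None
            if pd.isna(row["matched_fraction"])
            else float(row["matched_fraction"]),
        }
        for sid, row in ct.samples.iterrows()
    }
    meta_path = Path(metadata_path)
    with open(meta_path, "w") as fh:
        if meta_path.suffix == ".json":
            json.dump(meta, fh, indent=1)
        else:
            yaml.safe_dump(meta, fh)
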