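import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscreen.integration import (
    depleted_fraction,
    host_gene_filter,
    make_intergenic_pseudogenes,
    offtarget_depletion_analysis,
    pseudogene_guide_map,
    scale_lfcs,
)
from mirscreen.library import GuideLibrary

from conftest import make_library_frame


class TestScaling:
    @staticmethod
    def _panel(m_ess=-2.0, m_null=0.2):
        ess = {f"e{i}": m_ess + d for i, d in enumerate([-0.2, -0.1, 0.0, 0.1, 0.2])}
        nul = {f"n{i}": m_null + d for i, d in enumerate([-0.2, -0.1, 0.0, 0.1, 0.2])}
        other = {"x": -0.9}
        return pd.Series({**ess, **nul, **other}), list(ess), list(nul)

    def test_anchors_land_exactly(self):
        lfc, ess, nul = self._panel()
        scaled = scale_lfcs(lfc, ess, nul)
        assert scaled.loc[ess].median() == pytest.approx(-1.0, abs=1e-9)
        assert scaled.loc[nul].median() == pytest.approx(0.0, abs=1e-9)

    def test_derived_arithmetic_example(self):
        # m_null = 0.2, m_ess = -2, x = -0.9 -> -0.5
        lfc, ess, nul = self._panel()
        scaled = scale_lfcs(lfc, ess, nul)
        assert scaled["x"] == pytest.approx(-0.5, abs=1e-12)

    def test_coincident_anchors_error(self):
        lfc, ess, nul = self._panel(m_ess=0.2, m_null=0.2)
        with pytest.raises(ValueError, match="coincide"):
            scale_lfcs(lfc, ess, nul)

    def test_small_anchor_sets_error(self):
        lfc = pd.Series({"e1": -2.0, "n1": 0.0, "x": -1.0})
        with pytest.raises(ValueError, match="at least 5"):
            scale_lfcs(lfc, ["e1"], ["n1"])

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_affine_scaling_preserves_ordering(self, seed):
        rng = np.random.default_rng(seed)
        lfc, ess, nul = self._panel()
        extra = pd.Series(rng.normal(0, 1, 10), index=[f"g{i}" for i in range(10)])
        full = pd.concat([lfc, extra])
        scaled = scale_lfcs(full, ess, nul)
        assert (full.rank() == scaled.rank()).all()


class TestDepletedFraction:
    def test_simple_fraction(self):
        scaled = pd.DataFrame({"s1": [-0.6, -0.4, 0.1]}, index=["a", "b", "c"])
        out = depleted_fraction(scaled)
        assert out["per_screen_fraction"]["s1"] == pytest.approx(1 / 3)
        assert out["any_screen"].tolist() == [True, False, False]

    def test_all_zero_genes(self):
        scaled = pd.DataFrame(np.zeros((5, 3)))
        assert depleted_fraction(scaled)["mean_fraction"] == 0.0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        scaled = pd.DataFrame(rng.normal(0, 1, (100, 4)))
        fracs = [depleted_fraction(scaled, c)["mean_fraction"] for c in (-1.5, -1.0, -0.5, 0.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_pure_null_panels_rarely_depleted(self):
        # scaled null LFCs ~ N(0, 0.1): essentially nothing below -0.5
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scaled = pd.DataFrame(rng.normal(0, 0.1, (200, 5)))
            vals.append(depleted_fraction(scaled)["mean_fraction"])
        assert np.mean(vals) < 0.01


def _intergenic_library(n_intergenic, mirna_dist=(5, 5, 4)):
    rows = []
    for gi, k in enumerate(mirna_dist):
        for j in range(k):
            rows.append(
                (f"m{gi}_{j}", "A" * 20, f"MIR{gi}", "mirna_targeting", "chr1",
                 1000 + 1000 * gi + 10 * j, "+", 0)
            )
    for i in range(n_intergenic):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        rows.append(
            (f"int{i:03d}", "C" * 20, f"INTERGENIC_{i}", "intergenic_control",
             chrom, 10_000 + 500 * i, "+", 0)
        )
    return GuideLibrary(make_library_frame(rows))


class TestPseudogenes:
    def test_ten_guides_bin_size_five(self):
        lib = _intergenic_library(10)
        pg = make_intergenic_pseudogenes(lib, {5: 1.0})
        assert len(pg) == 2
        assert all(len(v) == 5 for v in pg.values())
        # contiguity: each pseudo-gene's guides are genomically consecutive
        inter = lib.guides_of_class("intergenic_control").sort_values(["chrom", "pos"])
        order = list(inter["guide_id"])
        for guides in pg.values():
            idx = [order.index(g) for g in guides]
            assert idx == list(range(min(idx), max(idx) + 1))

    def test_partition_covers_every_guide_once(self):
        lib = _intergenic_library(47)
        pg = make_intergenic_pseudogenes(lib)
        flat = [g for v in pg.values() for g in v]
        assert len(flat) == 47
        assert len(set(flat)) == 47

    def test_size_multiset_matches_requested_distribution(self):
        lib = _intergenic_library(100)
        pg = make_intergenic_pseudogenes(lib, {5: 0.5, 4: 0.3, 2: 0.2})
        sizes = sorted(len(v) for v in pg.values())
        # 50 guides in 5s, 28 in 4s, 20 in 2s (largest remainder), leftovers merged
        counts = pd.Series(sizes).value_counts().to_dict()
        assert sum(s * c for s, c in counts.items()) == 100
        assert counts.get(5, 0) >= 9 and counts.get(4, 0) >= 6 and counts.get(2, 0) >= 9

    def test_too_few_guides_errors(self):
        lib = _intergenic_library(2)
        with pytest.raises(ValueError, match="fewer intergenic"):
            make_intergenic_pseudogenes(lib, {5: 1.0})

    def test_deterministic_given_library(self):
        lib = _intergenic_library(40)
        assert make_intergenic_pseudogenes(lib) == make_intergenic_pseudogenes(lib)

    def test_guide_map_inverts_index(self):
        lib = _intergenic_library(20)
        pg = make_intergenic_pseudogenes(lib)
        m = pseudogene_guide_map(pg)
        for name, guides in pg.items():
            assert (m.loc[guides] == name).all()


class TestHostGeneFilter:
    ann = pd.DataFrame(
        {
            "mirna_id": ["M1", "M2", "M3", "M4"],
            "host_gene": ["HG1", "HG2", "HG3", None],
            "context": ["exonic", "intronic", "exonic", "intergenic"],
            "host_essentiality": ["common_essential", "common_essential", "other", "other"],
        }
    )

    def test_only_exonic_in_essential_host_removed(self):
        kept, removed = host_gene_filter(["M1", "M2", "M3", "M4"], self.ann)
        assert kept == ["M2", "M3", "M4"]
        assert removed["mirna_id"].tolist() == ["M1"]
        assert removed["host_gene"].tolist() == ["HG1"]

    def test_unannotated_treated_as_intergenic_with_warning(self):
        with pytest.warns(UserWarning, match="missing host annotation"):
            kept, removed = host_gene_filter(["M1", "M9"], self.ann)
        assert "M9" in kept


class TestOfftargetAnalysis:
    @staticmethod
    def _lib_with_offtargets(counts):
        rows = [
            (f"g{i}", "A" * 20, f"MIR{i}", "mirna_targeting", "chr1", 100 + 10 * i, "+", c)
            for i, c in enumerate(counts)
        ]
        return GuideLibrary(make_library_frame(rows))

    def test_constant_offtargets_no_significance(self):
        lib = self._lib_with_offtargets([2] * 100)
        lfc = pd.Series(np.linspace(-2, 1, 100), index=lib.guide_ids)
        out = offtarget_depletion_analysis(lfc, lib)
        assert (out["pairwise_tests"]["p_adj"] == 1.0).all()

    def test_hundred_guides_make_ten_even_bins(self):
        lib = self._lib_with_offtargets(list(range(100)))
        lfc = pd.Series(np.linspace(-2, 1, 100), index=lib.guide_ids)
        out = offtarget_depletion_analysis(lfc, lib)
        assert (out["decile_summary"]["n_guides"] == 10).all()
        # bin 1 holds the most depleted guides
        assert out["decile_summary"]["mean_lfc"].iloc[0] == out["decile_summary"]["mean_lfc"].min()

    def test_planted_bottom_decile_enrichment_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ot = np.concatenate([rng.poisson(5, 10), rng.poisson(1, 90)])
            lib = self._lib_with_offtargets(list(ot))
            lfc = pd.Series(np.linspace(-2, 1, 100), index=lib.guide_ids)
            out = offtarget_depletion_analysis(lfc, lib)
            hits += out["bottom_vs_rest"]["p"] < 0.01
        assert hits == 10

    def test_too_few_guides_errors(self):
        lib = self._lib_with_offtargets([1] * 5)
        lfc = pd.Series(np.zeros(5), index=lib.guide_ids)
        with pytest.raises(ValueError, match="at least 10"):
            offtarget_depletion_analysis(lfc, lib)

    def test_hit_group_comparison_runs(self):
        rng = np.random.default_rng(3)
        ot = list(rng.poisson(1, 100))
        lib = self._lib_with_offtargets(ot)
        lfc = pd.Series(rng.normal(0, 1, 100), index=lib.guide_ids)
        out = offtarget_depletion_analysis(lfc, lib, hit_genes=[f"MIR{i}" for i in range(20)])
        assert "hit_comparison" in out
        assert set(out["hit_comparison"]["dunn"]["group_a"]) <= {"hit", "non_hit"}


class TestHostAnnotationFromGff:
    GFF = """\
##gff-version 3
chr1\t.\tgene\t1000\t5000\t.\t+\t.\tID=gene1;gene_name=HOSTA
chr1\t.\texon\t1000\t1500\t.\t+\t.\tID=exon1;Parent=gene1
chr1\t.\texon\t4000\t5000\t.\t+\t.\tID=exon2;Parent=gene1
chr2\t.\tgene\t100\t900\t.\t-\t.\tID=gene2;gene_name=HOSTB
chr2\t.\texon\t100\t900\t.\t-\t.\tID=exon3;Parent=gene2
"""

    def test_contexts_and_essentiality(self, tmp_path):
        from mirscreen.integration import host_annotation_from_gff

        gff = tmp_path / "genes.gff3"
        gff.write_text(self.GFF)
        pos = pd.DataFrame(
            {
                "mirna_id": ["M_exonic", "M_intronic", "M_intergenic", "M_other_host"],
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "pos": [1200, 2500, 9000, 500],
            }
        )
        ann = host_annotation_from_gff(gff, pos, {"HOSTA"})
        ann = ann.set_index("mirna_id")
        assert ann.loc["M_exonic", "context"] == "exonic"
        assert ann.loc["M_exonic", "host_essentiality"] == "common_essential"
        assert ann.loc["M_intronic", "context"] == "intronic"
        assert ann.loc["M_intergenic", "context"] == "intergenic"
        assert ann.loc["M_other_host", "host_essentiality"] == "other"
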