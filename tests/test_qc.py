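import numpy as np
import pandas as pd
import pytest

from mirscreen.correction import compute_lfc, guide_lfc_matrix, normalize_counts
from mirscreen.library import CountTable
from mirscreen.qc import (
    QcThresholds,
    classification_metrics,
    effect_size_metrics,
    precision_recall_curve,
    replicate_read_qc,
    replicate_reproducibility,
)


def _panel(lib, matched, totals_factor):
    """Count table with chosen matched fractions / coverage multipliers."""
    n = len(lib)
    cols = {"pl": np.full(n, 500)}
    meta = {"pl": {"cell_line": "plasmid", "replicate": "ref", "is_plasmid": True,
                   "matched_fraction": 0.99}}
    for i, (mf, fac) in enumerate(zip(matched, totals_factor)):
        sid = f"r{i}"
        cols[sid] = np.full(n, fac)
        meta[sid] = {"cell_line": f"CL{i}", "replicate": "rep1", "is_plasmid": False,
                     "matched_fraction": mf}
    counts = pd.DataFrame(cols, index=lib.guide_ids)
    return CountTable(counts, pd.DataFrame.from_dict(meta, orient="index"))


class TestReadQc:
    def test_low_matched_fraction_fails(self, toy_library):
        ct = _panel(toy_library, [0.55], [1000])
        rep = replicate_read_qc(ct, toy_library)
        assert not rep["passed"].iloc[0]
        assert "matched_fraction" in rep["reasons"].iloc[0]

    def test_low_coverage_fails(self, toy_library):
        ct = _panel(toy_library, [0.9], [99])  # 99 reads/guide < 100x
        rep = replicate_read_qc(ct, toy_library)
        assert not rep["passed"].iloc[0]
        assert "coverage" in rep["reasons"].iloc[0]

    def test_good_replicate_passes(self, toy_library):
        ct = _panel(toy_library, [0.8], [500])
        rep = replicate_read_qc(ct, toy_library)
        assert rep["passed"].iloc[0]
        assert rep["reasons"].iloc[0] == ""

    def test_missing_matched_fraction_errors(self, toy_library):
        ct = _panel(toy_library, [np.nan], [500])
        with pytest.raises(ValueError, match="matched_fraction"):
            replicate_read_qc(ct, toy_library)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            QcThresholds(min_matched_fraction=-0.1)


class TestEffectSize:
    def test_nnmd_definitional(self):
        lfc = pd.Series({"e1": -1.0, "e2": -1.0, "n1": 0.5, "n2": -0.5})
        out = effect_size_metrics(lfc, ["e1", "e2"], ["n1", "n2"])
        # null sd = sqrt(0.5); nnmd = -1 / 0.7071
        assert out["nnmd"] == pytest.approx(-1.0 / np.std([0.5, -0.5], ddof=1))

    def test_identical_distributions_give_zero(self):
        lfc = pd.Series({"e1": 0.3, "e2": -0.3, "n1": 0.3, "n2": -0.3})
        out = effect_size_metrics(lfc, ["e1", "e2"], ["n1", "n2"])
        assert out["nnmd"] == pytest.approx(0.0)
        assert out["cohens_d"] == pytest.approx(0.0)

    def test_hand_computed_example(self):
        ess = {"e1": -1.2, "e2": -0.8}
        nul = {"n1": 0.1, "n2": -0.1}
        lfc = pd.Series({**ess, **nul})
        out = effect_size_metrics(lfc, list(ess), list(nul))
        diff = np.mean(list(ess.values())) - np.mean(list(nul.values()))
        sd_null = np.std(list(nul.values()), ddof=1)
        pooled = np.sqrt(
            (np.var(list(ess.values()), ddof=1) + np.var(list(nul.values()), ddof=1)) / 2
        )
        assert out["nnmd"] == pytest.approx(diff / sd_null, abs=1e-12)
        assert out["cohens_d"] == pytest.approx(diff / pooled, abs=1e-12)

    def test_zero_null_sd_errors(self):
        lfc = pd.Series({"e1": -1.0, "e2": -2.0, "n1": 0.0, "n2": 0.0})
        with pytest.raises(ValueError, match="SD"):
            effect_size_metrics(lfc, ["e1", "e2"], ["n1", "n2"])

    def test_nnmd_at_least_as_large_as_d_when_null_sd_smaller(self):
        rng = np.random.default_rng(0)
        lfc = pd.Series(
            np.concatenate([rng.normal(-1, 1.0, 50), rng.normal(0, 0.3, 50)]),
            index=[f"e{i}" for i in range(50)] + [f"n{i}" for i in range(50)],
        )
        out = effect_size_metrics(lfc, [f"e{i}" for i in range(50)], [f"n{i}" for i in range(50)])
        assert abs(out["nnmd"]) >= abs(out["cohens_d"])
        assert np.sign(out["nnmd"]) == np.sign(out["cohens_d"])


def _brute_auc_pr(scores, pos):
    """Trapezoid AUC over the PR points of every threshold, by enumeration."""
    order = scores.sort_values(ascending=False, kind="stable")
    pts = [(0.0, 1.0)]
    tp = 0
    for k, g in enumerate(order.index, start=1):
        tp += g in pos
        pts.append((tp / len(pos), tp / k))
    auc = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        auc += (r1 - r0) * (p0 + p1) / 2
    return auc


class TestClassification:
    def test_perfect_separation(self):
        scores = pd.Series({"e1": 10.0, "e2": 9.0, "n1": 1.0, "n2": 0.5})
        out = classification_metrics(scores, ["e1", "e2"], ["n1", "n2"], bf_rule=True)
        assert out["auc_pr"] == pytest.approx(1.0)
        assert out["f_measure"] == pytest.approx(1.0)

    def test_f_measure_harmonic_mean(self):
        # P=0.9, R=0.8 -> F = 2*0.72/1.7
        assert 2 * 0.9 * 0.8 / (0.9 + 0.8) == pytest.approx(0.847, abs=5e-4)

    def test_auc_matches_brute_force_on_interleaved_list(self):
        ids = [f"g{i}" for i in range(10)]
        pos = {ids[i] for i in (0, 2, 4, 6, 8)}
        scores = pd.Series(np.linspace(10, 1, 10), index=ids)
        out = classification_metrics(scores, pos, set(ids) - pos)
        assert out["auc_pr"] == pytest.approx(_brute_auc_pr(scores, pos), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        ids = [f"g{i}" for i in range(12)]
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=12), index=ids)
        pos = set(ids[:6])
        a = classification_metrics(scores, pos, set(ids) - pos)["auc_pr"]
        b = classification_metrics(np.exp(scores * 3), pos, set(ids) - pos)["auc_pr"]
        assert a == pytest.approx(b)

    def test_bf_rule_picks_smallest_threshold_at_least_five(self):
        scores = pd.Series({"a": 12.0, "b": 7.0, "c": 5.5, "d": 3.0, "e": 1.0})
        out = classification_metrics(scores, {"a", "b", "d"}, {"c", "e"}, bf_rule=True)
        assert out["bf_threshold_used"] == 5.5
        # at threshold 5.5: top-3 contains 2 positives of 3 total positives
        assert out["precision"] == pytest.approx(2 / 3)
        assert out["recall"] == pytest.approx(2 / 3)

    def test_single_class_labels_error(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            precision_recall_curve(scores, {"a", "b"}, set())


class TestReproducibility:
    @staticmethod
    def _simulated_panel(lib, n_screens=3, n_reps=2, effect_sd=0.4, noise_sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        guides = lib.guide_ids
        cols = {}
        screens = {}
        base = rng.normal(0, 0.3, len(guides))
        for s in range(n_screens):
            screen_effect = base + rng.normal(0, effect_sd, len(guides))
            for r in range(n_reps):
                sid = f"S{s}_r{r}"
                cols[sid] = screen_effect + rng.normal(0, noise_sd, len(guides))
                screens[sid] = f"S{s}"
        return pd.DataFrame(cols, index=guides), pd.Series(screens)

    def test_identical_replicates_have_unit_pcc(self, small_sim):
        _, lib, _, _ = small_sim
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, len(lib))
        wide = pd.DataFrame({"A_r1": x, "A_r2": x}, index=lib.guide_ids)
        out = replicate_reproducibility(wide, pd.Series({"A_r1": "A", "A_r2": "A"}), lib)
        assert out["pcc_matrix"].loc["A_r1", "A_r2"] == pytest.approx(1.0)

    def test_within_exceeds_between_gives_positive_wbc(self, small_sim):
        _, lib, _, _ = small_sim
        wide, screens = self._simulated_panel(lib, seed=1)
        out = replicate_reproducibility(wide, screens, lib)
        assert (out["wbc_lfc"].dropna() > 0).all()
        assert out["flagged_screens"] == []
        # oracle: brute-force within vs between correlation means
        corr = wide.corr()
        within, between = [], []
        for a in corr.columns:
            for b in corr.columns:
                if a < b:
                    (within if screens[a] == screens[b] else between).append(corr.loc[a, b])
        assert np.mean(within) > np.mean(between)

    def test_single_replicate_screen_flagged(self, small_sim):
        _, lib, _, _ = small_sim
        wide, screens = self._simulated_panel(lib, n_screens=2, seed=2)
        wide = wide.drop(columns="S1_r1")
        screens = screens.drop("S1_r1")
        out = replicate_reproducibility(wide, screens, lib)
        assert np.isnan(out["wbc_lfc"]["S1"])
        assert "S1" in out["flagged_screens"]

    def test_prefilter_removes_essential_controls(self, small_sim):
        _, lib, _, _ = small_sim
        wide, screens = self._simulated_panel(lib, seed=4)
        out = replicate_reproducibility(wide, screens, lib)
        n_ess = (lib.records["guide_class"] == "essential_control").sum()
        assert out["n_guides_used"] == len(lib) - n_ess


def test_planted_separation_gives_high_auc_pr():
    # delta/sigma >= 4: AUC-PR > 0.95 in >= 95% of seeded runs
    wins = 0
    n_runs = 100
    for seed in range(n_runs):
        rng = np.random.default_rng(seed)
        ids = [f"e{i}" for i in range(40)] + [f"n{i}" for i in range(60)]
        scores = pd.Series(
            np.concatenate([rng.normal(4, 1, 40), rng.normal(0, 1, 60)]), index=ids
        )
        out = classification_metrics(scores, set(ids[:40]), set(ids[40:]))
        wins += out["auc_pr"] > 0.95
    assert wins >= 95
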