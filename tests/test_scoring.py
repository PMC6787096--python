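"""Interaction scoring chain: background, filter, differential test, calls."""

import numpy as np
import pandas as pd
import pytest

from tcgi import (
    Category,
    SimulationConfig,
    background_correct,
    build_screen_library,
    call_interactions,
    cpm_filter,
    differential_abundance,
    score_screen,
    simulate_screen,
    tmm_factors,
)
from tcgi.library import Guide, build_cross_library
from tcgi.scoring import DifferentialResult


class TestBackgroundCorrect:
    @pytest.fixture()
    def toy(self):
        # six constructs x two samples; three control-control rows whose
        # sample-1 counts are {5, 7, 9} -> median 7 subtracted from sample 1
        counts = pd.DataFrame(
            {
                "s1": [100, 20, 3, 5, 7, 9],
                "s2": [50, 10, 8, 0, 0, 0],
            },
            index=["cA", "cB", "cC", "ctl1", "ctl2", "ctl3"],
        )
        cats = {
            "cA": Category.DOUBLE_KO,
            "cB": Category.SINGLE_KO_POS2,
            "cC": Category.SINGLE_KO_POS1,
            "ctl1": Category.CTRL_CTRL,
            "ctl2": Category.CTRL_CTRL,
            "ctl3": Category.CTRL_CTRL,
        }
        return counts, cats

    def test_median_subtraction_hand_computed(self, toy):
        counts, cats = toy
        out = background_correct(counts, cats)
        # sample 1: median {5,7,9} = 7 subtracted, floored at zero
        assert out["s1"].tolist() == [93, 13, 0]
        # sample 2: median {0,0,0} = 0, unchanged
        assert out["s2"].tolist() == [50, 10, 8]

    def test_control_rows_removed(self, toy):
        counts, cats = toy
        out = background_correct(counts, cats)
        assert set(out.index) == {"cA", "cB", "cC"}

    def test_never_increases_any_count(self, toy):
        counts, cats = toy
        out = background_correct(counts, cats)
        assert (out.le(counts.loc[out.index])).all().all()

    def test_no_controls_rejected(self, toy):
        counts, _ = toy
        cats = {c: Category.DOUBLE_KO for c in counts.index}
        with pytest.raises(ValueError, match="control-control"):
            background_correct(counts, cats)


class TestCpmFilter:
    @pytest.fixture()
    def matrix(self):
        # 8 constructs x 4 samples with column totals 1e5 -> CPM = count x 10
        data = {
            "s1": [1000, 0, 400, 400, 0, 0, 98200, 0],
            "s2": [1000, 0, 400, 0, 400, 0, 98200, 0],
            "s3": [1000, 0, 0, 0, 0, 400, 98600, 0],
            "s4": [1000, 0, 0, 0, 0, 400, 98600, 0],
        }
        return pd.DataFrame(data, index=[f"c{i}" for i in range(8)])

    def test_survivors_match_manual_cpm_table(self, matrix):
        kept, removed = cpm_filter(matrix, min_cpm=5, min_samples=2)
        # CPM >= 5 means count >= 0.5 here; c1/c7 are all-zero and c3/c4
        # exceed the threshold in a single sample only -> removed
        assert list(kept.index) == ["c0", "c2", "c5", "c6"]
        assert list(removed) == ["c1", "c3", "c4", "c7"]

    def test_boundary_exactly_two_samples_kept(self, matrix):
        kept, _ = cpm_filter(matrix, min_cpm=5, min_samples=2)
        assert "c2" in kept.index  # >= 5 CPM in exactly 2 of 4 samples

    def test_scaling_a_column_leaves_survivors_unchanged(self, matrix):
        scaled = matrix.copy()
        scaled["s1"] = scaled["s1"] * 3
        a, _ = cpm_filter(matrix)
        b, _ = cpm_filter(scaled)
        assert list(a.index) == list(b.index)

    def test_min_samples_exceeding_columns_rejected(self, matrix):
        with pytest.raises(ValueError, match="min_samples"):
            cpm_filter(matrix, min_samples=5)

    def test_zero_total_sample_rejected(self, matrix):
        matrix["s4"] = 0
        with pytest.raises(ValueError, match="positive total"):
            cpm_filter(matrix)


def _toy_library():
    gt = [Guide(f"gTAZ_{i}", "TAZ", p, 1) for i, p in enumerate(
        ["ACGTACGTACGTACGTACGT", "TGCATGCATGCATGCATGCA"], start=1)]
    gc = Guide("gCtrl", "CONTROL", "TTAACCGGTTAACCGGTTAA", 1)
    gx = Guide("gX", "MCL1", "CCGGAATTCCGGAATTCCGG", 2)
    gy = Guide("gY", "BRCA1", "GGCCTTAAGGCCTTAAGGCC", 2)
    gc2 = Guide("gCtrl2", "CONTROL", "AATTCCGGAATTCCGGAATT", 2)
    return build_cross_library([gt[0], gc], [gx, gy, gc2])


def _diff_from(logfc: dict[str, float], pvals: dict[str, float] | None = None) -> DifferentialResult:
    ids = list(logfc)
    p = [pvals.get(i, 1e-9) if pvals else 1e-9 for i in ids]
    table = pd.DataFrame(
        {
            "logFC": [logfc[i] for i in ids],
            "pvalue": p,
            "fdr": p,
            "significant": [x < 0.1 for x in p],
        },
        index=ids,
    )
    return DifferentialResult(table=table, dispersion=0.02)


class TestCallInteractions:
    def test_hand_arithmetic_example(self):
        lib = _toy_library()
        diff = _diff_from(
            {
                "gTAZ_1__gX": -3.0,     # anchor-target double
                "gCtrl__gX": -1.0,      # single knockout
                "gTAZ_1__gCtrl2": -0.5, # anchor alone
            }
        )
        calls = call_interactions(diff, lib, "TAZ")
        row = calls.loc["MCL1"]
        assert row.p_single == pytest.approx(-1.0)
        assert row.p_anchor == pytest.approx(-0.5)
        assert row.p_double_raw == pytest.approx(-3.0)
        assert row.p_double_adj == pytest.approx(-2.5)
        assert row.ratio == pytest.approx(0.4)
        assert bool(row.called) is True

    def test_equal_phenotypes_not_called(self):
        lib = _toy_library()
        diff = _diff_from(
            {"gTAZ_1__gX": -1.0, "gCtrl__gX": -1.0, "gTAZ_1__gCtrl2": 0.0},
            pvals={"gTAZ_1__gCtrl2": 1.0},
        )
        calls = call_interactions(diff, lib, "TAZ")
        assert calls.loc["MCL1", "ratio"] == pytest.approx(1.0)
        assert not calls.loc["MCL1", "called"]

    def test_no_gene_with_ratio_at_or_above_threshold_is_called(self):
        lib = _toy_library()
        diff = _diff_from(
            {
                "gTAZ_1__gX": -2.0, "gCtrl__gX": -1.0,   # ratio 0.5 exactly
                "gTAZ_1__gY": -10.0, "gCtrl__gY": -1.0,  # ratio 0.1
                "gTAZ_1__gCtrl2": 0.0,
            },
            pvals={"gTAZ_1__gCtrl2": 1.0},
        )
        calls = call_interactions(diff, lib, "TAZ")
        called = set(calls.index[calls.called])
        assert called == {"BRCA1"}
        assert (calls.loc[calls.called, "ratio"] < 0.5).all()

    def test_non_depleting_double_is_undefined_never_called(self):
        lib = _toy_library()
        diff = _diff_from(
            {"gTAZ_1__gX": 1.5, "gCtrl__gX": -1.0, "gTAZ_1__gCtrl2": 0.0},
            pvals={"gTAZ_1__gCtrl2": 1.0},
        )
        calls = call_interactions(diff, lib, "TAZ")
        assert calls.loc["MCL1", "status"] == "UNDEFINED"
        assert not calls.loc["MCL1", "called"]

    def test_missing_anchor_rejected(self):
        lib = _toy_library()
        diff = _diff_from({"gTAZ_1__gX": -1.0})
        with pytest.raises(ValueError, match="anchor"):
            call_interactions(diff, lib, "YAP")

    def test_construct_gate_requires_reproducibility(self):
        lib = _toy_library()
        diff = _diff_from(
            {"gTAZ_1__gX": -3.0, "gCtrl__gX": -1.0, "gTAZ_1__gCtrl2": -0.5},
            pvals={"gTAZ_1__gX": 1e-9, "gCtrl__gX": 1e-9, "gTAZ_1__gCtrl2": 1e-9},
        )
        calls = call_interactions(diff, lib, "TAZ", gate="construct", min_sig_constructs=2)
        assert calls.loc["MCL1", "status"] == "NOT_SIGNIFICANT"


class TestDifferentialAbundance:
    def test_identical_timepoints_give_zero_logfc(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 2000, size=200)
        counts = pd.DataFrame(
            {"T0_rep1": base, "T0_rep2": base, "T14_rep1": base, "T14_rep2": base}
        )
        f = tmm_factors(counts)
        res = differential_abundance(counts, f, ["T0_rep1", "T0_rep2"], ["T14_rep1", "T14_rep2"])
        np.testing.assert_allclose(res.table["logFC"], 0.0, atol=1e-12)
        assert (res.table["fdr"] > 0.9).all()

    def test_planted_eightfold_depletion_recovers_minus_three(self):
        planted = [f"GENE{i:04d}" for i in range(1, 6)]
        # high counts (tight abundance spread) and a small depleted mass so
        # the TMM trim fully excludes the depleted tail
        cfg = SimulationConfig(
            n_genes=100, guides_per_gene=1, n_controls_pos2=4, plasmid_sigma=0.3,
            essential_fraction=0.0, anchor_fitness=0.0,
            guide_efficiency_range=(1.0, 1.0), depth_per_construct=2000,
            single_effect_set=[(g, -0.3) for g in planted], seed=8,
        )
        _, _, lib = build_screen_library(cfg)
        counts, _, _ = simulate_screen(cfg, lib)
        sub = counts[["T0_rep1", "T0_rep2", "T14_rep1", "T14_rep2"]]
        res = differential_abundance(
            sub, tmm_factors(sub), ["T0_rep1", "T0_rep2"], ["T14_rep1", "T14_rep2"]
        )
        rows = [c.id for c in lib if c.guide1.is_control and c.guide2.target in planted]
        mean_lfc = res.table.loc[rows, "logFC"].mean()
        assert mean_lfc == pytest.approx(-3.0, abs=0.2)
        assert (res.table.loc[rows, "fdr"] < 0.1).all()

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame({"T0_rep1": [0, 0], "T14_rep1": [5, 5]})
        f = pd.Series([1.0, 1.0], index=counts.columns)
        with pytest.raises(ValueError, match="zero total"):
            differential_abundance(counts, f, ["T0_rep1"], ["T14_rep1"])

    def test_empty_design_rejected(self):
        counts = pd.DataFrame({"T0_rep1": [1, 2]})
        f = pd.Series([1.0], index=counts.columns)
        with pytest.raises(ValueError, match="timepoint"):
            differential_abundance(counts, f, [], ["T0_rep1"])


class TestChainInvariants:
    def test_scale_equivariance_of_calls(self, small_screen):
        cfg, library, counts, _, _ = small_screen
        t0 = [c for c in counts.columns if c.startswith("T0")]
        t14 = [c for c in counts.columns if c.startswith("T14")]
        calls1, _ = score_screen(counts, library, cfg.anchor_gene, t0, t14)
        calls2, _ = score_screen(counts * 2, library, cfg.anchor_gene, t0, t14)
        pd.testing.assert_series_equal(calls1["called"], calls2["called"])

    def test_null_screen_calls_nothing_or_little(self):
        cfg = SimulationConfig(
            n_genes=40, guides_per_gene=3, n_controls_pos2=12,
            essential_fraction=0.0, anchor_fitness=0.0, seed=21,
        )
        _, _, lib = build_screen_library(cfg)
        counts, _, _ = simulate_screen(cfg, lib)
        t0 = [c for c in counts.columns if c.startswith("T0")]
        t14 = [c for c in counts.columns if c.startswith("T14")]
        calls, _ = score_screen(counts, lib, "TAZ", t0, t14)
        assert calls["called"].mean() <= 0.05
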