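"""Statistical decision tree, differential analysis, flank overlap, Alu pairs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circedit import integration
from circedit.annotation import GenomeAnnotation
from circedit.evaluation import _toy_circ_locus
from circedit.integration import (
    alu_pair_orientation,
    choose_test,
    correlate,
    differential,
    differential_circ,
    fpkm,
    host_independence,
    overlap_editing_flanks,
    run_group_test,
)
from circedit.pipeline import RunConfig, run_pipeline
from circedit.synthetic import SimulationConfig


class TestChooseTest:
    def test_two_normal_groups_get_student_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert choose_test([a, b]) == "student_t"

    def test_heavy_tailed_groups_get_mannwhitney(self):
        rng = np.random.default_rng(1)
        a = np.exp(rng.normal(0, 2.5, 20))
        b = np.exp(rng.normal(0, 2.5, 20))
        assert choose_test([a, b]) == "mannwhitney"

    def test_three_normal_groups_get_anova(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(i, 1, 12) for i in range(3)]
        assert choose_test(groups) == "anova_tukey"

    def test_three_nonnormal_groups_get_kruskal(self):
        rng = np.random.default_rng(3)
        groups = [np.exp(rng.normal(0, 2.5, 20)) for _ in range(3)]
        assert choose_test(groups) == "kruskal"

    def test_paired_nonnormal_gets_wilcoxon(self):
        rng = np.random.default_rng(4)
        a = np.exp(rng.normal(0, 2.5, 15))
        b = a * np.exp(rng.normal(0, 1, 15))
        assert choose_test([a, b], paired=True) == "wilcoxon"

    def test_tiny_groups_warn_and_go_nonparametric(self):
        with pytest.warns(UserWarning):
            assert choose_test([np.array([1.0, 2.0]), np.array([3.0, 4.0])]) == "mannwhitney"

    def test_degenerate_input_yields_nan(self):
        name, p = run_group_test([np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 1.0])])
        assert name == "none" and np.isnan(p)

    def test_tukey_posthoc_runs(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(i, 1, 12) for i in range(3)]
        table = integration.tukey_posthoc(groups, ["a", "b", "c"])
        assert len(table) == 3  # all pairwise comparisons


class TestDifferential:
    def _counts(self, rng, effect=4.0, n=5):
        samples = [f"c{i}" for i in range(n)] + [f"h{i}" for i in range(n)]
        groups = {s: ("control" if s.startswith("c") else "HF") for s in samples}
        data = {
            "circA": np.r_[rng.poisson(20, n), rng.poisson(20 * effect, n)],
            "circB": np.r_[rng.poisson(30, n), rng.poisson(30, n)],
        }
        return pd.DataFrame(data, index=samples).T, groups

    def test_planted_effect_significant_up(self):
        rng = np.random.default_rng(7)
        counts, groups = self._counts(rng)
        res = differential_circ(counts, groups)
        assert bool(res.loc["circA", "significant"]) and res.loc["circA", "direction"] == "up"
        assert res.loc["circA", "fold_change"] == pytest.approx(4.0, rel=0.5)

    def test_all_zero_feature_excluded(self):
        counts = pd.DataFrame(
            {"s1": [0, 5], "s2": [0, 6], "s3": [0, 7], "s4": [0, 8], "s5": [0, 3], "s6": [0, 4]},
            index=["dead", "alive"],
        )
        groups = {f"s{i}": ("control" if i <= 3 else "HF") for i in range(1, 7)}
        res = differential(counts, groups)
        assert list(res.index) == ["alive"]

    def test_zero_control_mean_flagged_infinite(self):
        counts = pd.DataFrame(
            {"s1": [0], "s2": [0], "s3": [0], "s4": [4], "s5": [5], "s6": [6]},
            index=["x"],
        )
        groups = {f"s{i}": ("control" if i <= 3 else "HF") for i in range(1, 7)}
        res = differential(counts, groups)
        assert np.isinf(res.loc["x", "fold_change"]) and bool(res.loc["x", "fold_change_undefined"])

    def test_bh_option_is_no_less_conservative(self):
        rng = np.random.default_rng(8)
        samples = [f"c{i}" for i in range(5)] + [f"h{i}" for i in range(5)]
        groups = {s: ("control" if s.startswith("c") else "HF") for s in samples}
        counts = pd.DataFrame(
            rng.poisson(20, size=(30, 10)), columns=samples,
            index=[f"f{i}" for i in range(30)],
        )
        raw = differential(counts, groups)
        adj = differential(counts, groups, bh_correct=True)
        assert "q_value" in adj.columns
        assert adj["significant"].sum() <= raw["significant"].sum()


class TestHostIndependence:
    @pytest.mark.parametrize(
        "circ_sig,host_sig,expected",
        [
            (True, False, "host_independent"),
            (True, True, "host_coupled"),
            (False, False, "not_regulated"),
        ],
    )
    def test_classification(self, circ_sig, host_sig, expected):
        circ = pd.DataFrame({"significant": [circ_sig]}, index=["c1"])
        host = pd.DataFrame({"significant": [host_sig]}, index=["G1"])
        res = host_independence(circ, host, {"c1": "G1"})
        assert res.loc["c1", "classification"] == expected

    def test_unannotated_host_unclassified(self):
        circ = pd.DataFrame({"significant": [True]}, index=["c1"])
        host = pd.DataFrame({"significant": [False]}, index=["G1"])
        res = host_independence(circ, host, {})
        assert res.loc["c1", "classification"] == "unclassified"

    def test_synthetic_design_all_independent(self, pipeline_result):
        # circRNA counts are planted independently of host transcription, so
        # every regulated circle must classify as host-independent
        res = pipeline_result["independence"]
        assert set(res["classification"]) == {"host_independent"}


class TestOverlapEditingFlanks:
    def test_boundary_site_excluded_by_half_open_convention(self):
        from circedit.editing import EditingSite

        gene, junction, _els = _toy_circ_locus(["+"], ["-"])
        ann = GenomeAnnotation([gene], [])
        up, down = ann.flanking_introns(junction)  # [100,500) and [600,1000)
        sites = [
            EditingSite("chrT", up.end, "A", "G", 5, 10),      # exactly at end: outside
            EditingSite("chrT", up.end - 1, "A", "G", 5, 10),  # last base: inside
        ]
        per_sample, _comp = overlap_editing_flanks(
            [junction], {"s1": sites, "s2": []},
            ann, {"s1": "control", "s2": "HF"},
        )
        row = per_sample[per_sample["sample_id"] == "s1"].iloc[0]
        assert row["upstream"] == 1 and row["downstream"] == 0

    def test_no_editing_gives_zero_counts(self, pipeline_result):
        ann = pipeline_result["annotation"]
        junctions = [j for j in pipeline_result["junctions"] if j.passed]
        groups = pipeline_result["groups"]
        per_sample, _ = overlap_editing_flanks(
            junctions, {sid: [] for sid in groups}, ann, groups
        )
        assert (per_sample["joint"] == 0).all()

    def test_hf_flank_editing_significantly_lower_in_power_design(self, tmp_path):
        """With six samples per group and editing rates spanning the caller's
        detection threshold, halving the rates must significantly reduce
        flanking-intron editing-event counts."""
        cfg = SimulationConfig(
            seed=31, n_genes=2, n_samples_per_group=6,
            sites_per_alu=20, editing_rate_range=(0.08, 0.3),
        )
        res = run_pipeline(RunConfig(outdir=str(tmp_path), simulation=cfg))
        joint = res["flank_comp"]
        joint = joint[joint["flank"] == "joint"]
        assert len(joint) == 2
        assert (joint["direction"] == "down").all()
        assert joint["significant"].all()

    def test_missing_flank_reported_nan_in_split_view(self):
        from circedit.annotation import GeneModel
        from circedit.circ import BackspliceJunction
        from circedit.io_formats import GenomicInterval

        exons = [GenomicInterval("c", 0, 100, "+"), GenomicInterval("c", 200, 300, "+")]
        gene = GeneModel("G", "protein_coding", GenomicInterval("c", 0, 300, "+"), {"t": exons})
        ann = GenomeAnnotation([gene], [])
        j = BackspliceJunction(chrom="c", strand="+", acceptor_pos=0, donor_pos=300)
        per_sample, comp = overlap_editing_flanks(
            [j], {"s1": [], "s2": []}, ann, {"s1": "control", "s2": "HF"}
        )
        assert per_sample["upstream"].isna().all()
        assert "upstream" not in set(comp["flank"])


class TestAluPairOrientation:
    @pytest.mark.parametrize(
        "up,down,expected",
        [
            (["+"], ["-"], (1, 0, 0)),            # convergent
            (["-"], ["+"], (0, 1, 0)),            # divergent
            (["+", "-"], ["+", "-"], (1, 1, 2)),  # 2x2 mixed
            ([], ["+"], (0, 0, 0)),               # empty flank
            (["+"], [], (0, 0, 0)),
        ],
    )
    def test_examples(self, up, down, expected):
        gene, junction, els = _toy_circ_locus(up, down)
        ann = GenomeAnnotation([gene], els)
        got = alu_pair_orientation(junction, ann)
        assert (got.n_convergent, got.n_divergent, got.n_same_orientation) == expected
        assert got.n_inverted == expected[0] + expected[1]

    @given(
        up=st.lists(st.sampled_from("+-"), max_size=4),
        down=st.lists(st.sampled_from("+-"), max_size=4),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_counts_equal_product_formula(self, up, down):
        gene, junction, els = _toy_circ_locus(up, down)
        ann = GenomeAnnotation([gene], els)
        got = alu_pair_orientation(junction, ann)
        assert got.n_convergent == up.count("+") * down.count("-")
        assert got.n_divergent == up.count("-") * down.count("+")
        assert got.n_same_orientation == (
            up.count("+") * down.count("+") + up.count("-") * down.count("-")
        )


class TestCorrelate:
    def test_proportional_vectors_give_r_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(50, 5, 20)
        method, r, p = correlate(x, 2 * x)
        assert r == pytest.approx(1.0) and p < 1e-6

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [4, 5, 6])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])

    def test_nonnormal_data_uses_spearman(self):
        rng = np.random.default_rng(10)
        x = np.exp(rng.normal(0, 2.5, 30))
        y = np.exp(rng.normal(0, 2.5, 30))
        method, _r, _p = correlate(x, y)
        assert method == "spearman"

    def test_independent_vectors_usually_not_significant(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(10):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            _m, _r, p = correlate(x, y)
            pvals.append(p)
        assert np.median(pvals) > 0.05


class TestFpkm:
    def test_worked_example(self):
        assert fpkm(100, 2000, 1_000_000) == pytest.approx(50.0)

    def test_zero_count(self):
        assert fpkm(0, 2000, 1_000_000) == 0.0

    def test_doubling_total_halves_value(self):
        assert fpkm(10, 1500, 2_000_000) == pytest.approx(fpkm(10, 1500, 1_000_000) / 2)

    @pytest.mark.parametrize("length,total", [(0, 1e6), (2000, 0)])
    def test_invalid_inputs(self, length, total):
        with pytest.raises(ValueError):
            fpkm(10, length, total)
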