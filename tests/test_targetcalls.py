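"""CPM, differential filters, intersection, time-course classification,
half-life bounds and ddCt quantitation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from gonadscan import panels
from gonadscan import targetcalls as tc
from gonadscan.synth import ExpressionConfig, generate_expression


class TestCpm:
    def test_counts_per_million_definition(self):
        counts = pd.DataFrame({"s1": [2, 999998]}, index=["a", "b"])
        out = tc.cpm(counts)
        assert out.loc["a", "s1"] == pytest.approx(2.0)

    def test_all_zero_gene_stays_zero_and_columns_sum_to_1e6(self, rng):
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 4)), columns=list("abcd"))
        counts.iloc[7] = 0
        out = tc.cpm(counts)
        assert (out.iloc[7] == 0).all()
        np.testing.assert_allclose(out.sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            tc.cpm(pd.DataFrame({"s1": [0, 0]}))


class TestDeTable:
    def test_identical_groups_have_zero_log2fc(self, rng):
        counts = pd.DataFrame(rng.integers(10, 1000, (100, 3)), columns=["a1", "a2", "a3"])
        joint = pd.concat([counts, counts.rename(columns={c: c.replace("a", "b") for c in counts})], axis=1)
        table = tc.de_table(joint, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        np.testing.assert_allclose(table["log2fc"], 0.0)

    def test_type_one_error_calibrated_on_null_data(self):
        """With no planted effects, about 5% of genes reach p < 0.05."""
        genes = [f"g{i}" for i in range(2000)]
        cfg = ExpressionConfig(
            n_genes=2000,
            gene_ids=genes,
            bound_genes=[],
            planted_primaries=[],
            planted_secondaries=[],
            planted_dependent=[],
            effect_log2fc={},
            half_life_hours={},
            dispersion=0.02,
            timepoints=(0.0,),
        )
        data = generate_expression(cfg, seed=13)
        joint = data.counts_on.join(data.counts_off)
        table = tc.de_table(joint, list(data.counts_on.columns), list(data.counts_off.columns))
        frac = (table["p_value"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)


class TestFilterRegulated:
    @pytest.mark.parametrize(
        "fc,fdr,cpm_,included",
        [(2.5, 0.01, 3.0, True), (2.5, 0.06, 3.0, False), (2.5, 0.01, 1.9, False), (1.9, 0.01, 3.0, False)],
    )
    def test_threshold_combinations(self, fc, fdr, cpm_, included):
        table = pd.DataFrame(
            {"mean_cpm": [cpm_], "log2fc": [np.log2(fc)], "p_value": [fdr / 2], "fdr": [fdr]},
            index=["gene"],
        )
        assert (("gene" in tc.filter_regulated(table, "up")) is included)

    def test_down_direction_uses_reciprocal_fold(self):
        table = pd.DataFrame(
            {"mean_cpm": [10.0, 10.0], "log2fc": [-1.5, -0.5], "p_value": [0.001] * 2, "fdr": [0.001] * 2},
            index=["down_far", "down_near"],
        )
        assert tc.filter_regulated(table, "down") == {"down_far"}

    def test_relaxing_thresholds_never_shrinks_the_set(self, rng):
        table = pd.DataFrame(
            {
                "mean_cpm": rng.uniform(0, 10, 300),
                "log2fc": rng.normal(0, 2, 300),
                "p_value": rng.uniform(0, 1, 300),
                "fdr": rng.uniform(0, 1, 300),
            },
            index=[f"g{i}" for i in range(300)],
        )
        strict = tc.filter_regulated(table, "up", fc_min=2.0, fdr_max=0.05, cpm_min=2.0)
        for kwargs in ({"fc_min": 1.5}, {"fdr_max": 0.1}, {"cpm_min": 1.0}):
            relaxed = tc.filter_regulated(table, "up", **{"fc_min": 2.0, "fdr_max": 0.05, "cpm_min": 2.0, **kwargs})
            assert strict <= relaxed


class TestBenjaminiHochberg:
    @staticmethod
    def bh_oracle(pvals):
        """Literal step-up definition on a short p-value list."""
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            adj[i] = running
        return adj

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_statsmodels_bh_matches_brute_force(self, pvals):
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(fdr, self.bh_oracle(np.asarray(pvals)), atol=1e-12)


class TestIntersect:
    def test_disjoint_and_identical_sets(self):
        assert tc.intersect_targets({"a", "b"}, {"c"}) == []
        assert tc.intersect_targets({"b", "a"}, {"a", "b"}) == ["a", "b"]

    def test_output_sorted_by_gene_id(self):
        assert tc.intersect_targets({"z", "m", "a"}, {"z", "a", "q"}) == ["a", "z"]


def _table(rows):
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["mean_cpm", "log2fc", "p_value", "fdr"])
    return frame


class TestClassifyTimecourse:
    REG = (50.0, -1.8, 1e-6, 1e-4)  # passes the down filter
    FLAT = (50.0, 0.0, 0.9, 0.95)

    def test_paperlike_toy_classification(self):
        tables = {
            2.0: _table({"early_bound": self.REG, "late_free": self.FLAT, "never": self.FLAT}),
            4.0: _table({"early_bound": self.REG, "late_free": self.REG, "never": self.FLAT}),
        }
        dependence = _table({"early_bound": self.FLAT, "late_free": (50.0, 1.8, 1e-6, 1e-4), "never": self.FLAT})
        calls = tc.classify_timecourse(tables, bound_genes={"early_bound"}, targets_dependence=dependence)
        frame = calls.calls
        assert frame.loc["early_bound", "class"] == "primary"
        assert frame.loc["late_free", "class"] == "secondary"
        assert bool(frame.loc["late_free", "targets_dependent"])
        assert frame.loc["never", "class"] == "unclassified"

    def test_bound_gene_regulated_late_is_not_secondary(self):
        tables = {
            2.0: _table({"g": self.FLAT}),
            4.0: _table({"g": self.REG}),
        }
        calls = tc.classify_timecourse(tables, bound_genes={"g"})
        assert calls.calls.loc["g", "class"] == "unclassified"

    def test_missing_earliest_time_point_rejected(self):
        with pytest.raises(ValueError, match="earliest"):
            tc.classify_timecourse({4.0: _table({"g": self.FLAT})}, bound_genes=set())

    def test_planted_recovery_over_twenty_seeds(self):
        """Across 20 independent datasets the two planted primaries are
        recovered exactly and no planted secondary is ever called primary."""
        cfg = panels.load_expression_config("paper_like")
        for seed in range(20):
            data = generate_expression(cfg, seed=seed)
            tables = tc.timecourse_de(data.timecourse)
            calls = tc.classify_timecourse(
                {t: tables[t] for t in (2.0, 4.0, 48.0)}, set(data.bound_genes)
            )
            assert calls.genes_in_class("primary") == sorted(data.truth.planted_primaries)
            secondaries = set(calls.genes_in_class("secondary"))
            assert set(data.truth.planted_secondaries) <= secondaries


class TestHalfLifeBound:
    def test_printed_fold_examples(self):
        assert tc.half_life_bound({1.0: 3.0}) == 1.0
        assert tc.half_life_bound({2.0: 5.0, 4.0: 10.0}) == 2.0

    def test_no_twofold_drop_gives_no_bound(self):
        assert tc.half_life_bound({1.0: 1.2, 2.0: 1.8}) is None

    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            tc.half_life_bound({1.0: 0.5})

    def test_bound_is_conservative_for_exponential_decay(self):
        """A gene with true half-life 0.63 h sampled at {0.5, 1, 2, 4} h is
        bounded at 1 h, and the bound always exceeds the true half-life."""
        true_hl = 0.63
        folds = {t: 2.0 ** (t / true_hl) for t in (0.5, 1.0, 2.0, 4.0)}
        bound = tc.half_life_bound(folds)
        assert bound == 1.0
        assert bound >= true_hl

    @given(st.floats(min_value=0.05, max_value=10.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bound_exceeds_true_half_life_for_any_decay(self, true_hl):
        folds = {t: 2.0 ** (t / true_hl) for t in (0.5, 1.0, 2.0, 4.0, 48.0)}
        bound = tc.half_life_bound(folds)
        if bound is not None:
            assert bound >= true_hl


class TestDeltaCt:
    @staticmethod
    def _ct_table():
        rows = []
        for rep in (1, 2, 3):
            rows += [
                ("ama-1", "off", rep, 15.0),
                ("ama-1", "on", rep, 15.0),
                ("lst-1", "off", rep, 22.0),
                ("lst-1", "on", rep, 19.0),
            ]
        return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])

    def test_reference_condition_is_exactly_one(self):
        rel = tc.delta_ct(self._ct_table(), reference_condition="off")
        assert rel.loc["lst-1", "off"] == 1.0

    def test_ddct_exponent_arithmetic(self):
        rel = tc.delta_ct(self._ct_table(), reference_condition="off")
        # ddCt = (19 - 15) - (22 - 15) = -3 -> 8-fold up
        assert rel.loc["lst-1", "on"] == pytest.approx(8.0)

    @pytest.mark.parametrize("ddct,expected", [(-1.0, 2.0), (2.0, 0.25)])
    def test_two_power_minus_ddct(self, ddct, expected):
        table = self._ct_table()
        table.loc[(table.gene == "lst-1") & (table.condition == "on"), "ct"] = 22.0 + ddct
        rel = tc.delta_ct(table, reference_condition="off")
        assert rel.loc["lst-1", "on"] == pytest.approx(expected)

    def test_missing_reference_gene_rejected(self):
        table = self._ct_table()
        table = table[table.gene != "ama-1"]
        with pytest.raises(ValueError, match="reference gene"):
            tc.delta_ct(table)


class TestFoldDrops:
    def test_matches_decay_model_at_zero_dispersion(self):
        cfg = panels.load_expression_config("paper_like")
        data = generate_expression(cfg, seed=0)
        folds = tc.fold_drops(data.timecourse, data.truth.planted_primaries)
        # half-life 0.63 h, floor 0.05: ~2.7-fold at 1 h, ~6.5-fold at 2 h
        assert folds[1.0] == pytest.approx(2.7, rel=0.15)
        assert folds[2.0] == pytest.approx(6.5, rel=0.15)
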