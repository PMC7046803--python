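"""Comparative-CT math, hemolysis QC, and the group-comparison stage."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirreg.qpcr import (
    CtRecord, CtTable, compare_groups, expression_table, fold_change,
    hemolysis_qc, qc_table, relative_expression, spearman_correlation,
)
from mirreg.synthetic import GroupSpec, QpcrSimConfig, simulate_ct_table

cts = st.floats(min_value=5.0, max_value=39.0, allow_nan=False)


class TestHemolysisQc:
    @pytest.mark.parametrize("ct23,ct451,passed,delta", [
        (25.0, 20.0, True, 5.0),
        (28.0, 20.0, False, 8.0),
        (27.0, 20.0, True, 7.0),     # boundary: exactly 7 passes (">7" excludes)
        (27.001, 20.0, False, 7.001),
    ])
    def test_threshold_semantics(self, ct23, ct451, passed, delta):
        r = hemolysis_qc(ct23, ct451)
        assert r.passed is passed
        assert r.delta_ct_hemolysis == pytest.approx(delta)

    def test_missing_marker_excluded_as_unassessable(self, caplog):
        r = hemolysis_qc(None, 20.0, sample_id="S1")
        assert not r.passed and r.delta_ct_hemolysis is None
        assert "un-assessable" in caplog.text

    def test_non_positive_ct_rejected(self):
        with pytest.raises(ValueError):
            hemolysis_qc(-1.0, 20.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(ct23=cts, ct451=cts, bump=st.floats(min_value=0, max_value=10))
    def test_monotone_increasing_ct23_never_rescues_a_sample(self, ct23, ct451, bump):
        before = hemolysis_qc(ct23, ct451)
        after = hemolysis_qc(ct23 + bump, ct451)
        assert not (not before.passed and after.passed)


class TestRelativeExpression:
    def test_delta_ct_four_gives_one_sixteenth(self):
        e = relative_expression(25.0, [20.0, 22.0])
        assert e.value == pytest.approx(0.0625)

    def test_target_equal_to_single_reference_is_unity(self):
        assert relative_expression(24.0, [24.0]).value == pytest.approx(1.0)

    def test_empty_reference_list_rejected(self):
        with pytest.raises(ValueError):
            relative_expression(24.0, [])

    def test_log_value_follows_configured_base(self):
        e10 = relative_expression(25.0, [20.0], log_base=10)
        e2 = relative_expression(25.0, [20.0], log_base=2)
        assert e10.log_value == pytest.approx(np.log10(e10.value))
        assert e2.log_value == pytest.approx(-5.0)

    def test_random_inputs_match_exp2_of_mean_centred_cts(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = float(rng.uniform(15, 35))
            refs = list(rng.uniform(15, 35, size=int(rng.integers(1, 6))))
            assert relative_expression(t, refs).value == \
                pytest.approx(np.exp2(-(t - np.mean(refs))))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(t=cts, r1=cts, r2=cts, shift=st.floats(min_value=-5, max_value=5))
    def test_scale_equivariance_in_ct_space(self, t, r1, r2, shift):
        base = relative_expression(t, [r1, r2]).value
        shifted = relative_expression(t + shift, [r1 + shift, r2 + shift]).value
        assert shifted == pytest.approx(base, rel=1e-9)


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change([2.0, 2.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_identity(self):
        assert fold_change([1.5, 2.5], [1.5, 2.5]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])

    def test_noise_free_simulation_recovers_planted_ddct(self):
        """Planted ddCT = -3 between groups must come back as fold 8.0."""
        cfg = QpcrSimConfig(
            groups={"treated": GroupSpec(2.0, 0.0, 4), "control": GroupSpec(5.0, 0.0, 4)},
            reference_ct_sd=0.0, hemolysis_fraction=0.0)
        table, _ = simulate_ct_table(cfg, seed=3)
        refs = sorted(cfg.reference_means)
        expr = {g: [relative_expression(table.mean_ct(s, cfg.target),
                                        [table.mean_ct(s, r) for r in refs])
                    for s in table.sample_ids() if table.sample_groups[s] == g]
                for g in ("treated", "control")}
        assert fold_change(expr["treated"], expr["control"]) == pytest.approx(8.0)


class TestCompareGroups:
    def test_identical_groups_give_zero_t(self):
        cmp = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert cmp.statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_all_groups_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            compare_groups({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_multi_group_runs_anova_then_pairwise(self):
        rng = np.random.default_rng(6)
        groups = {g: list(rng.normal(m, 1, 10)) for g, m in
                  [("a", 0.0), ("b", 0.5), ("c", 2.0)]}
        cmp = compare_groups(groups, design="multi_group")
        assert set(cmp.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
        from scipy import stats
        f, p = stats.f_oneway(*(np.asarray(groups[g]) for g in sorted(groups)))
        assert cmp.statistic == pytest.approx(float(f))

    def test_descriptives_support_boxplot_reporting(self):
        cmp = compare_groups({"a": [1.0, 2.0, 6.0], "b": [2.0, 3.0, 4.0]})
        d = cmp.descriptives["a"]
        assert (d.n, d.minimum, d.maximum) == (3, 1.0, 6.0)
        assert d.mean == pytest.approx(3.0)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]})

    def test_spearman_helper_monotone_association(self):
        rho, p = spearman_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)


class TestCtTableWorkflow:
    def test_replicates_collapsed_by_mean(self):
        table = CtTable(records=[
            CtRecord("S1", "miR-21-5p", 24.0, replicate=1),
            CtRecord("S1", "miR-21-5p", 26.0, replicate=2),
        ])
        assert table.mean_ct("S1", "miR-21-5p") == pytest.approx(25.0)

    def test_duplicate_triples_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CtTable(records=[CtRecord("S1", "a", 20.0), CtRecord("S1", "a", 21.0)])

    def test_near_undetected_ct_flagged_not_rejected(self, caplog):
        CtRecord("S1", "a", 41.0)
        assert "near-undetected" in caplog.text
        with pytest.raises(ValueError):
            CtRecord("S1", "a", 51.0)

    def test_hemolysed_samples_excluded_from_expression(self, demo_ct):
        table, truth = demo_ct
        qc = qc_table(table)
        expr = expression_table(table, "miR-21-5p",
                                ["miR-93-5p", "miR-191-5p", "miR-423-4p", "miR-103a"],
                                qc=qc)
        quantified = {e.sample_id for e in expr}
        for sid, hem in truth.hemolysed.items():
            assert (sid in quantified) == (not hem)

    def test_pipeline_determinism_same_table_twice(self, demo_ct):
        table, _ = demo_ct
        refs = ["miR-93-5p", "miR-191-5p", "miR-423-4p", "miR-103a"]
        a = expression_table(table, "miR-21-5p", refs, qc=qc_table(table))
        b = expression_table(table, "miR-21-5p", refs, qc=qc_table(table))
        assert a == b
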