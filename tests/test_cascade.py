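"""Filter-cascade stages: monotonicity, criteria logic and panel selection."""

import dataclasses

import numpy as np
import pytest

from crossres.cascade import (
    CascadeConfig,
    cohort_consistency_filter,
    cumulative_panel_selection,
    fit_rules,
    fold_change_filter,
    run_cascade,
    survival_significance_filter,
)
from crossres.cohort import Cohort, RNA
from crossres.cutpoint import CutoffRule, GE
from crossres.simulate import SimulationConfig, generate_cohort_pair, truth_table


def test_stage_survivors_nested(small_pair):
    """Every stage's survivors are a subset of its input."""
    tr, et = small_pair
    report = run_cascade(tr, et)
    for stage in report.stages:
        assert stage.surviving_features <= stage.input_features or \
            stage.name == "outlier_screen"


def test_cascade_deterministic(small_pair):
    tr, et = small_pair
    a = run_cascade(tr, et)
    b = run_cascade(tr, et)
    assert a.panels == b.panels
    assert [s.surviving_features for s in a.stages] == \
        [s.surviving_features for s in b.stages]


def test_relaxing_thresholds_never_shrinks_survivors(small_pair):
    tr, et = small_pair
    tight = CascadeConfig()
    loose = dataclasses.replace(
        tight, survival_alpha=0.2, fold_change_abs=0.1,
        response_auc_min=0.5, pfs_alpha=0.2, os_alpha=0.3,
    )
    rep_tight = run_cascade(tr, et, tight)
    rep_loose = run_cascade(tr, et, loose)
    for st, sl in zip(rep_tight.stages, rep_loose.stages):
        if st.name in ("survival_significance", "fold_change", "cohort_consistency"):
            assert st.surviving_features <= sl.surviving_features


def test_empty_candidate_region_is_not_an_error(small_pair):
    """An impossibly strict screen yields zero-count stages, no exception."""
    tr, et = small_pair
    report = run_cascade(tr, et, CascadeConfig(z_threshold=50.0))
    by_name = {(s.platform, s.name): s for s in report.stages}
    assert by_name[("RNA", "candidate_region")].count == 0
    assert report.panels["RNA"] == ()


def test_rna_only_cohort_completes(small_pair):
    tr, et = small_pair
    tr_rna_only = Cohort(clinical=tr.clinical, rna=tr.rna, rppa=None)
    et_rna_only = Cohort(clinical=et.clinical, rna=et.rna, rppa=None)
    report = run_cascade(tr_rna_only, et_rna_only)
    assert all(s.platform == RNA for s in report.stages)


class TestSurvivalFilter:
    def test_empty_feature_list(self, small_pair):
        tr, et = small_pair
        survivors, detail = survival_significance_filter(
            frozenset(), et, CascadeConfig()
        )
        assert survivors == frozenset()

    def test_null_features_rarely_survive(self):
        """With no planted effect and HR=1 the pass rate is near alpha^2
        plus the slack from the deliberate PFS/OS correlation (the joint
        two-endpoint null rejection for rho=0.7-coupled endpoints is about
        0.016)."""
        survived = total = 0
        for seed in (31, 32, 33):
            cfg = SimulationConfig(seed=seed, effect_shift=0.0,
                                   hazard_ratio_pd=1.0,
                                   n_rna_features=500, n_rppa_features=5,
                                   n_informative_rna=0, n_informative_rppa=0)
            _, et = generate_cohort_pair(cfg)
            survivors, _ = survival_significance_filter(
                frozenset(et.rna.feature_ids), et, CascadeConfig()
            )
            survived += len(survivors)
            total += 500
        assert survived / total < 0.03

    def test_hazard_linked_features_usually_survive(self):
        """Planted HR=3 features pass both endpoints in most seeds."""
        passes = total = 0
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, effect_shift=2.5, hazard_ratio_pd=3.0,
                                   n_rna_features=40, n_rppa_features=5,
                                   n_informative_rna=5, n_informative_rppa=1)
            _, et = generate_cohort_pair(cfg)
            planted = {f for f, v in truth_table(cfg).items()
                       if v["informative"] and v["platform"] == RNA}
            survivors, _ = survival_significance_filter(planted, et, CascadeConfig())
            passes += len(survivors)
            total += len(planted)
        assert passes / total >= 0.6


class TestFoldChangeFilter:
    def test_planted_shift_survives_and_flat_is_dropped(self, small_pair):
        tr, _ = small_pair
        planted = {
            f for f, v in truth_table(
                SimulationConfig(seed=7, n_cr=20, n_pd=6, n_et=120,
                                 n_rna_features=60, n_rppa_features=20,
                                 n_informative_rna=4, n_informative_rppa=2,
                                 effect_shift=2.0)
            ).items() if v["informative"] and v["platform"] == RNA
        }
        survivors, detail = fold_change_filter(
            frozenset(tr.rna.feature_ids), tr, CascadeConfig()
        )
        assert planted <= survivors

    def test_identical_group_means_dropped(self, tiny_cohort):
        # constant feature: all group means equal
        values = tiny_cohort.rna.values.copy()
        values[:, 0] = 1.0
        import crossres.cohort as cc

        rna = cc.ExpressionMatrix("RNA", tiny_cohort.rna.sample_ids,
                                  tiny_cohort.rna.feature_ids, values)
        cohort = cc.Cohort(clinical=tiny_cohort.clinical, rna=rna)
        survivors, _ = fold_change_filter({"G1"}, cohort, CascadeConfig())
        assert "G1" not in survivors

    def test_zero_threshold_is_vacuous(self, small_pair):
        tr, _ = small_pair
        features = frozenset(tr.rna.feature_ids)
        survivors, _ = fold_change_filter(
            features, tr, CascadeConfig(fold_change_abs=0.0)
        )
        assert survivors == features


class TestConsistencyFilter:
    def rule(self, iauc, tr_pfs, tr_os, et_pfs, et_os):
        r = CutoffRule("f", RNA, 0.0, GE, iauc)
        r = r.with_metric("TR", "PFS", 0.6, tr_pfs)
        r = r.with_metric("TR", "OS", 0.6, tr_os)
        r = r.with_metric("ET", "PFS", 0.6, et_pfs)
        r = r.with_metric("ET", "OS", 0.6, et_os)
        return r

    def test_strong_feature_kept(self):
        rules = {"f": self.rule(0.9, 0.2, 0.2, 0.01, 0.2)}
        kept, _ = cohort_consistency_filter({"f"}, rules, CascadeConfig())
        # TR criterion (response IAUC >= 0.6) and ET criterion (ET PFS <= 0.05
        # with ET OS <= 0.1? no -> via tr_pfs? no) ...
        assert kept == frozenset()  # ET arm needs a second condition too

    def test_fully_consistent_feature_kept(self):
        rules = {"f": self.rule(0.9, 0.01, 0.05, 0.01, 0.05)}
        kept, _ = cohort_consistency_filter({"f"}, rules, CascadeConfig())
        assert kept == {"f"}

    def test_failing_one_arm_dropped(self):
        rules = {"f": self.rule(0.9, 0.01, 0.01, 0.9, 0.9)}
        kept, detail = cohort_consistency_filter({"f"}, rules, CascadeConfig())
        assert kept == frozenset()
        assert any(detail["f"]["tr"].values())
        assert not any(detail["f"]["et"].values())

    def test_no_active_criteria_rejected(self):
        rules = {"f": self.rule(0.9, 0.01, 0.01, 0.01, 0.01)}
        with pytest.raises(ValueError, match="no active criteria"):
            cohort_consistency_filter(
                {"f"}, rules, CascadeConfig(tr_criteria=(), et_criteria=())
            )

    def test_missing_rule_rejected(self):
        with pytest.raises(KeyError):
            cohort_consistency_filter({"ghost"}, {}, CascadeConfig())


class TestPanelSelection:
    def test_single_candidate_returned(self, small_pair):
        tr, et = small_pair
        feature = tr.rna.feature_ids[0]
        rules = fit_rules({feature}, tr, et, CascadeConfig())
        panel, trajectory = cumulative_panel_selection(
            {feature}, rules, tr, CascadeConfig()
        )
        assert panel == (feature,)

    def test_perfect_feature_found_first(self, small_pair):
        """A feature equal to the response indicator tops the greedy order."""
        tr, et = small_pair
        labels = (tr.clinical["response"] == "PD").to_numpy(dtype=float)
        values = tr.rna.values.copy()
        values[:, 5] = labels
        import crossres.cohort as cc

        rna = cc.ExpressionMatrix(RNA, tr.rna.sample_ids, tr.rna.feature_ids, values)
        tr2 = cc.Cohort(clinical=tr.clinical, rna=rna, rppa=tr.rppa)
        perfect = tr.rna.feature_ids[5]
        candidates = set(tr.rna.feature_ids[:10])
        rules = fit_rules(candidates, tr2, et, CascadeConfig())
        panel, trajectory = cumulative_panel_selection(
            candidates, rules, tr2, CascadeConfig(panel_mode="greedy_stop")
        )
        assert panel[0] == perfect
        assert trajectory[0][1] == 1.0

    def test_greedy_stop_on_null_candidates(self):
        """All-noise candidates trigger the stopping rule with a recorded trace."""
        cfg = SimulationConfig(seed=41, n_cr=34, n_pd=10, n_et=30,
                               n_rna_features=30, n_rppa_features=5,
                               n_informative_rna=0, n_informative_rppa=0,
                               effect_shift=0.0)
        tr, et = generate_cohort_pair(cfg)
        candidates = set(tr.rna.feature_ids[:12])
        config = CascadeConfig(panel_mode="greedy_stop", panel_size_rna=12)
        rules = fit_rules(candidates, tr, et, config)
        panel, trajectory = cumulative_panel_selection(
            candidates, rules, tr, config
        )
        assert len(panel) < 12
        assert len(trajectory) == len(panel)
        aucs = [a for _, a in trajectory]
        assert aucs == sorted(aucs)  # greedy AUC trace is non-decreasing

    def test_empty_candidates_rejected(self, small_pair):
        tr, _ = small_pair
        with pytest.raises(ValueError, match="empty candidate"):
            cumulative_panel_selection(set(), {}, tr, CascadeConfig())


def test_end_to_end_recovery_on_easy_conditions():
    """With a strong planted signal the cascade recovers most markers."""
    recovered = total = 0
    for seed in range(3):
        cfg = SimulationConfig(seed=seed, effect_shift=3.0, hazard_ratio_pd=4.0,
                               n_rna_features=120, n_rppa_features=30,
                               n_informative_rna=6, n_informative_rppa=3)
        tr, et = generate_cohort_pair(cfg)
        planted = {f for f, v in truth_table(cfg).items()
                   if v["informative"] and v["platform"] == RNA}
        report = run_cascade(tr, et)
        recovered += len(set(report.panels[RNA]) & planted)
        total += len(planted)
    assert recovered / total >= 0.5
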