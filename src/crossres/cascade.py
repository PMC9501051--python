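"""Staged target-selection cascade with a per-stage audit trail.

RNA features pass through the full sequence

    outlier screen -> Venn candidate region -> survival-significance
    filter -> fold-change filter -> cross-cohort consistency filter ->
    cumulative panel selection

while RPPA features, whose candidate region is already small, go straight
from the screen to panel selection.  Every stage threshold lives in
:class:`CascadeConfig`; every stage's input and surviving feature sets are
recorded in the :class:`CascadeReport` so the ledger of counts at each
step is auditable.

Two under-specified points are made explicit and configurable:

* the survival-significance stage dichotomizes samples by the same
  |z| >= threshold outlier flag the screen uses (``survival_dichotomize
  = "z_flag"``); optimal-cutoff dichotomization is available instead;
* the consistency stage encodes the TR-arm and ET-arm criteria as
  explicit toggles over conjunctions of {response IAUC >= minimum,
  PFS p <= alpha, OS p <= secondary alpha} per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from crossres.cohort import (
    Cohort,
    REGIMEN_AI,
    RESPONSE_CR,
    RESPONSE_PD,
    RNA,
    RPPA,
)
from crossres.cutpoint import (
    CutoffRule,
    evaluate_rule_survival,
    optimal_cutoff,
    risk_indicators,
)
from crossres.screen import (
    candidate_region,
    flag_features,
    response_groups,
    venn_partition,
)
from crossres.stats import log_rank_test

#: TR-arm consistency criteria (feature kept if ANY enabled one holds)
TR_CRITERIA = ("response_auc", "tr_pfs_et_pfs", "tr_pfs_et_os", "tr_pfs_tr_os")
#: ET-arm consistency criteria
ET_CRITERIA = ("et_pfs_tr_pfs", "et_pfs_tr_os", "et_pfs_et_os")


@dataclass(frozen=True)
class CascadeConfig:
    z_threshold: float = 2.0
    min_fraction: float | None = None
    survival_alpha: float = 0.05
    fold_change_abs: float = 0.5
    response_auc_min: float = 0.6
    pfs_alpha: float = 0.05
    os_alpha: float = 0.10
    survival_dichotomize: str = "z_flag"  # or "optimal_cutoff"
    survival_cohort: str = "ET"  # cohort used by the survival filter
    tr_criteria: tuple = TR_CRITERIA
    et_criteria: tuple = ET_CRITERIA
    panel_size_rna: int = 10
    panel_size_rppa: int = 5
    panel_mode: str = "fixed"  # "fixed" fills the panel; "greedy_stop" stops early

    def validate(self) -> None:
        for name in ("survival_alpha", "pfs_alpha", "os_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.z_threshold <= 0 or self.fold_change_abs < 0:
            raise ValueError("thresholds must be positive")
        if self.survival_dichotomize not in ("z_flag", "optimal_cutoff"):
            raise ValueError("survival_dichotomize must be z_flag or optimal_cutoff")
        if self.panel_mode not in ("fixed", "greedy_stop"):
            raise ValueError("panel_mode must be fixed or greedy_stop")
        unknown = set(self.tr_criteria) - set(TR_CRITERIA)
        unknown |= set(self.et_criteria) - set(ET_CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")


@dataclass(frozen=True)
class CascadeStage:
    name: str
    platform: str
    input_features: frozenset
    surviving_features: frozenset
    criteria: str
    detail: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.surviving_features)


@dataclass(frozen=True)
class CascadeReport:
    stages: tuple  # ordered CascadeStage
    rules: dict  # platform -> {feature_id: CutoffRule}
    panels: dict  # platform -> ordered tuple of feature ids
    trajectories: dict  # platform -> list of (feature, cumulative response AUC)

    def stage_counts(self, platform: str | None = None) -> list:
        return [
            (s.name, s.count) for s in self.stages
            if platform is None or s.platform == platform
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "platform": s.platform,
                    "stage": s.name,
                    "n_in": len(s.input_features),
                    "n_out": s.count,
                    "criteria": s.criteria,
                }
                for s in self.stages
            ]
        )


def _feature_column(cohort: Cohort, platform: str, feature: str) -> np.ndarray:
    mat = cohort.matrix(platform)
    return mat.values[:, mat.feature_ids.index(feature)]


def _endpoint_arrays(cohort: Cohort, platform: str, endpoint: str):
    mat = cohort.matrix(platform)
    clin = cohort.clinical_indexed().loc[list(mat.sample_ids)]
    return (
        clin[f"{endpoint}_time"].to_numpy(dtype=float),
        clin[f"{endpoint}_event"].to_numpy(dtype=bool),
    )


def survival_significance_filter(
    features, cohort: Cohort, config: CascadeConfig, platform: str = RNA
):
    """Keep features whose outlier flag separates both PFS and OS.

    Samples are dichotomized by |z| >= ``z_threshold`` (or by the
    feature's optimal PFS-event cutoff when configured); a feature
    survives iff the log-rank p-value is below ``survival_alpha`` for
    both endpoints.  Features whose flag leaves a stratum empty are
    dropped with the reason recorded.
    """
    mat = cohort.matrix(platform)
    times_e, events_e = {}, {}
    for endpoint in ("pfs", "os"):
        times_e[endpoint], events_e[endpoint] = _endpoint_arrays(
            cohort, platform, endpoint
        )
    survivors = []
    detail = {}
    for feature in sorted(features):
        values = _feature_column(cohort, platform, feature)
        if config.survival_dichotomize == "z_flag":
            with np.errstate(invalid="ignore"):
                flag = np.abs(values) >= config.z_threshold
            flag = np.where(np.isnan(values), False, flag)
        else:
            try:
                rule = optimal_cutoff(values, events_e["pfs"], feature, platform)
            except ValueError:
                detail[feature] = "degenerate feature"
                continue
            flag = risk_indicators(values, rule).astype(bool)
        if flag.all() or not flag.any():
            detail[feature] = "empty stratum"
            continue
        ps = {}
        for endpoint in ("pfs", "os"):
            ps[endpoint] = log_rank_test(
                times_e[endpoint], events_e[endpoint], flag
            ).p_value
        detail[feature] = ps
        if all(p < config.survival_alpha for p in ps.values()):
            survivors.append(feature)
    return frozenset(survivors), detail


def fold_change_filter(features, tr_cohort: Cohort, config: CascadeConfig,
                       platform: str = RNA):
    """Keep features with a large PD-arm vs CR group-mean difference.

    On z-score-scale (log-scale) data the "fold change" is the difference
    of group means; the feature survives when either progressing arm
    (SERM/SERD-PD or AI-PD) differs from CR by more than the threshold in
    absolute value.
    """
    mat = tr_cohort.matrix(platform)
    clin = tr_cohort.clinical_indexed().loc[list(mat.sample_ids)]
    response = clin["response"].to_numpy()
    regimen = clin["regimen"].to_numpy()
    if (response == RESPONSE_PD).any() and pd.isna(regimen[response == RESPONSE_PD]).any():
        raise ValueError("PD samples lack regimen annotation")
    cr = response == RESPONSE_CR
    ai_pd = (response == RESPONSE_PD) & (regimen == REGIMEN_AI)
    ss_pd = (response == RESPONSE_PD) & (regimen != REGIMEN_AI)
    survivors = []
    detail = {}
    for feature in sorted(features):
        values = _feature_column(tr_cohort, platform, feature)
        mean_cr = np.nanmean(values[cr]) if cr.any() else np.nan
        deltas = {}
        for name, mask in (("ai", ai_pd), ("serm_serd", ss_pd)):
            deltas[name] = (
                float(np.nanmean(values[mask]) - mean_cr) if mask.any() else np.nan
            )
        detail[feature] = deltas
        if any(
            np.isfinite(d) and abs(d) > config.fold_change_abs
            for d in deltas.values()
        ):
            survivors.append(feature)
    return frozenset(survivors), detail


def fit_rules(features, tr_cohort: Cohort, et_cohort: Cohort | None,
              config: CascadeConfig, platform: str = RNA) -> dict:
    """Fit the optimal-cutoff rule per feature on the TR cohort and
    evaluate it against PFS/OS in both cohorts (derivation = TR,
    validation = ET)."""
    mat = tr_cohort.matrix(platform)
    response = (
        tr_cohort.clinical_indexed()
        .loc[list(mat.sample_ids), "response"]
        .to_numpy()
    )
    outcome = response == RESPONSE_PD
    rules = {}
    for feature in sorted(features):
        values = _feature_column(tr_cohort, platform, feature)
        try:
            rule = optimal_cutoff(values, outcome, feature, platform)
        except ValueError:
            continue
        for cohort_name, cohort in (("TR", tr_cohort), ("ET", et_cohort)):
            if cohort is None or cohort.matrix(platform) is None:
                continue
            for endpoint in ("PFS", "OS"):
                auc, p = evaluate_rule_survival(rule, cohort, endpoint)
                rule = rule.with_metric(cohort_name, endpoint, auc, p)
        rules[feature] = rule
    return rules


def _metric_p(rule: CutoffRule, cohort: str, endpoint: str) -> float:
    m = rule.metrics.get((cohort, endpoint))
    return float("nan") if m is None else m["p"]


def cohort_consistency_filter(features, rules: dict, config: CascadeConfig):
    """Keep features satisfying one TR-arm AND one ET-arm criterion.

    Criteria are conjunctions over the rule's response IAUC and its
    per-cohort PFS/OS log-rank p-values; which conjunctions are active is
    controlled by ``config.tr_criteria`` / ``config.et_criteria``.
    """
    config.validate()
    if not config.tr_criteria or not config.et_criteria:
        raise ValueError("no active criteria")
    pa, oa = config.pfs_alpha, config.os_alpha
    survivors = []
    detail = {}
    for feature in sorted(features):
        rule = rules.get(feature)
        if rule is None:
            raise KeyError(f"no fitted rule for feature {feature!r}")
        tr_pfs = _metric_p(rule, "TR", "PFS")
        tr_os = _metric_p(rule, "TR", "OS")
        et_pfs = _metric_p(rule, "ET", "PFS")
        et_os = _metric_p(rule, "ET", "OS")
        tr_tests = {
            "response_auc": rule.response_iauc >= config.response_auc_min,
            "tr_pfs_et_pfs": tr_pfs <= pa and et_pfs <= oa,
            "tr_pfs_et_os": tr_pfs <= pa and et_os <= oa,
            "tr_pfs_tr_os": tr_pfs <= pa and tr_os <= oa,
        }
        et_tests = {
            "et_pfs_tr_pfs": et_pfs <= pa and tr_pfs <= oa,
            "et_pfs_tr_os": et_pfs <= pa and tr_os <= oa,
            "et_pfs_et_os": et_pfs <= pa and et_os <= oa,
        }
        tr_ok = any(tr_tests[c] for c in config.tr_criteria)
        et_ok = any(et_tests[c] for c in config.et_criteria)
        detail[feature] = {"tr": tr_tests, "et": et_tests}
        if tr_ok and et_ok:
            survivors.append(feature)
    return frozenset(survivors), detail


def cumulative_panel_selection(
    candidates, rules: dict, tr_cohort: Cohort, config: CascadeConfig,
    platform: str = RNA, panel_size: int | None = None,
):
    """Greedy forward selection maximizing the cumulative-score response AUC.

    Starting from the empty panel, each step adds the candidate whose
    inclusion maximizes the ROC AUC of the cumulative risk score against
    the CR/PD response (ties: higher TR PFS AUC of the candidate's rule,
    then feature id).  In ``greedy_stop`` mode selection stops when no
    addition strictly improves the AUC; in ``fixed`` mode the panel is
    filled to ``panel_size``.  Returns the ordered panel and its AUC
    trajectory.
    """
    from crossres.risk import score_roc

    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if panel_size is None:
        panel_size = (config.panel_size_rna if platform == RNA
                      else config.panel_size_rppa)
    mat = tr_cohort.matrix(platform)
    clin = tr_cohort.clinical_indexed().loc[list(mat.sample_ids)]
    labels = (clin["response"] == RESPONSE_PD).to_numpy()

    indicators = {
        f: risk_indicators(_feature_column(tr_cohort, platform, f), rules[f])
        for f in candidates
    }
    panel, trajectory = [], []
    current = np.zeros(len(mat.sample_ids), dtype=int)
    current_auc = -np.inf
    remaining = list(candidates)
    while remaining and len(panel) < panel_size:
        best = None  # (auc, pfs_auc, feature)
        for f in remaining:
            auc = score_roc(current + indicators[f], labels).auc
            pfs_auc = rules[f].metrics.get(("TR", "PFS"), {}).get("auc", float("nan"))
            pfs_key = -np.inf if not np.isfinite(pfs_auc) else pfs_auc
            if (
                best is None
                or auc > best[0]
                or (auc == best[0] and pfs_key > best[1])
                or (auc == best[0] and pfs_key == best[1] and f < best[2])
            ):
                best = (auc, pfs_key, f)
        auc, _, chosen = best
        if config.panel_mode == "greedy_stop" and auc <= current_auc:
            break
        panel.append(chosen)
        trajectory.append((chosen, float(auc)))
        current = current + indicators[chosen]
        current_auc = auc
        remaining.remove(chosen)
    return tuple(panel), trajectory


def run_cascade(tr_cohort: Cohort, et_cohort: Cohort | None,
                config: CascadeConfig | None = None) -> CascadeReport:
    """Execute the full staged workflow for RNA (and RPPA when present)."""
    config = config or CascadeConfig()
    config.validate()
    stages = []
    rules_all, panels, trajectories = {}, {}, {}

    survival_cohort = (
        et_cohort if (config.survival_cohort == "ET" and et_cohort is not None)
        else tr_cohort
    )

    for platform in (RNA, RPPA):
        tr_mat = tr_cohort.matrix(platform)
        if tr_mat is None:
            continue
        groups = response_groups(tr_cohort)
        sets = flag_features(tr_mat, groups, config.z_threshold, config.min_fraction)
        partition = venn_partition(sets)
        candidates = candidate_region(partition)
        all_features = frozenset(tr_mat.feature_ids)
        stages.append(CascadeStage(
            "outlier_screen", platform, all_features,
            frozenset().union(*partition.regions.values()) if partition.regions else frozenset(),
            f"|z| >= {config.z_threshold} in >= "
            f"{'1 sample' if config.min_fraction is None else config.min_fraction}",
        ))
        stages.append(CascadeStage(
            "candidate_region", platform, stages[-1].surviving_features,
            candidates, "flagged in both AI-PD and SERM/SERD-PD arms",
        ))

        current = candidates
        if platform == RNA:
            if current:
                current, detail = survival_significance_filter(
                    current, survival_cohort, config, platform
                )
            else:
                detail = {}
            stages.append(CascadeStage(
                "survival_significance", platform, candidates, current,
                f"log-rank p < {config.survival_alpha} for both PFS and OS "
                f"({config.survival_dichotomize} dichotomization, "
                f"{config.survival_cohort} cohort)",
                {"p_values": detail},
            ))
            before = current
            if current:
                current, detail = fold_change_filter(current, tr_cohort, config, platform)
            else:
                detail = {}
            stages.append(CascadeStage(
                "fold_change", platform, before, current,
                f"|group-mean difference vs CR| > {config.fold_change_abs} "
                "in either progressing arm", {"deltas": detail},
            ))

        rules = fit_rules(current, tr_cohort, et_cohort, config, platform)
        rules_all[platform] = rules

        if platform == RNA:
            before = current
            if current:
                current, detail = cohort_consistency_filter(current, rules, config)
            else:
                detail = {}
            stages.append(CascadeStage(
                "cohort_consistency", platform, before, current,
                "any enabled TR-arm criterion AND any enabled ET-arm criterion",
                {"criteria": detail},
            ))

        before = current
        if current:
            panel, trajectory = cumulative_panel_selection(
                current, rules, tr_cohort, config, platform
            )
        else:
            panel, trajectory = (), []
        panels[platform] = panel
        trajectories[platform] = trajectory
        stages.append(CascadeStage(
            "panel_selection", platform, before, frozenset(panel),
            f"greedy forward response-AUC maximization ({config.panel_mode}, "
            f"max size {config.panel_size_rna if platform == RNA else config.panel_size_rppa})",
        ))

    return CascadeReport(
        stages=tuple(stages), rules=rules_all, panels=panels,
        trajectories=trajectories,
    )


def rules_to_frame(rules: dict, panel=None) -> pd.DataFrame:
    """Rule table mirroring the derivation/validation layout: one row per
    feature with its cut-off, direction, response IAUC and per-cohort
    PFS/OS AUC and log-rank p."""
    rows = []
    for feature, rule in sorted(rules.items()):
        row = {
            "feature": feature,
            "platform": rule.platform,
            "high_risk": f"{'>=' if rule.direction == 'ge' else '<='}{rule.cutoff:g}",
            "cutoff": rule.cutoff,
            "direction": rule.direction,
            "response_iauc": rule.response_iauc,
        }
        for cohort in ("TR", "ET"):
            for endpoint in ("PFS", "OS"):
                m = rule.metrics.get((cohort, endpoint), {})
                row[f"{cohort.lower()}_{endpoint.lower()}_auc"] = m.get("auc", float("nan"))
                row[f"{cohort.lower()}_{endpoint.lower()}_p"] = m.get("p", float("nan"))
        if panel is not None:
            row["in_panel"] = feature in set(panel)
        rows.append(row)
    return pd.DataFrame(rows)
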