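"""Top-level modelling interface.

:class:`CrossResistanceModel` bundles the two cohorts with the cascade
configuration; ``fit()`` executes the full discovery pipeline and returns
a :class:`CrossResistanceResults` carrying the stage audit trail, the
per-feature cut-off rule tables, cumulative risk scores and their ROC
curves, PD-anchored risk groups with survival contrasts in both cohorts,
and the panel correlation matrix.  ``summary()`` renders the whole fit as
a text report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossres.cascade import CascadeConfig, CascadeReport, rules_to_frame, run_cascade
from crossres.cohort import Cohort, RESPONSE_PD, RNA, RPPA, read_cohort
from crossres.cutpoint import discrimination_band
from crossres.risk import (
    ANCHOR_MEAN,
    COMBINED,
    RiskGroups,
    RiskScoreTable,
    ROCCurve,
    SurvivalContrast,
    apply_threshold,
    cumulative_score,
    dichotomize_by_pd,
    scatter_table,
    score_roc,
    stratified_survival,
)
from crossres.stats import CorrelationMatrix, pearson_matrix


class CrossResistanceModel:
    """Cross-resistance panel discovery on a TR / ET cohort pair.

    Parameters
    ----------
    tr_cohort : Cohort
        Treatment-response cohort with CR/PD labels (the derivation arm).
    et_cohort : Cohort or None
        Endocrine-therapy cohort with survival endpoints only (the
        validation arm).  Without it, ET-dependent stages fall back to
        TR-only evaluation.
    config : CascadeConfig
        Stage thresholds and panel sizes.
    anchor : str
        PD-group anchor for the risk-score threshold ("mean" or "median").
    """

    def __init__(self, tr_cohort: Cohort, et_cohort: Cohort | None = None,
                 config: CascadeConfig | None = None, anchor: str = ANCHOR_MEAN):
        if (tr_cohort.clinical["response"] == RESPONSE_PD).sum() == 0:
            raise ValueError("TR cohort has no PD samples to anchor the model")
        self.tr_cohort = tr_cohort
        self.et_cohort = et_cohort
        self.config = config or CascadeConfig()
        self.anchor = anchor

    @classmethod
    def from_files(cls, tr_clinical, tr_rna, et_clinical=None, et_rna=None,
                   tr_rppa=None, et_rppa=None, **kwargs) -> "CrossResistanceModel":
        tr = read_cohort(tr_clinical, tr_rna, tr_rppa)
        et = read_cohort(et_clinical, et_rna, et_rppa) if et_clinical else None
        return cls(tr, et, **kwargs)

    def fit(self) -> "CrossResistanceResults":
        cascade = run_cascade(self.tr_cohort, self.et_cohort, self.config)
        panels = {p: panel for p, panel in cascade.panels.items() if panel}
        if not panels:
            raise ValueError("cascade selected no features on any platform")
        rules = {p: cascade.rules[p] for p in panels}

        scores_tr = cumulative_score(self.tr_cohort, rules, panels)
        scores_et = (
            cumulative_score(self.et_cohort, rules, panels)
            if self.et_cohort is not None else None
        )

        labels_tr = self.tr_cohort.response_of() == RESPONSE_PD
        pd_samples = labels_tr[labels_tr].index

        roc, groups_tr, groups_et = {}, {}, {}
        survival = {}
        platforms = list(panels)
        if len(panels) == 2:
            platforms.append(COMBINED)
        for platform in platforms:
            s_tr = scores_tr.platform_scores(platform)
            ok = s_tr.notna()
            if ok.sum() and labels_tr[ok].nunique() == 2:
                roc[platform] = score_roc(
                    s_tr[ok].to_numpy(), labels_tr[ok].to_numpy()
                )
            g_tr = dichotomize_by_pd(s_tr, pd_samples, self.anchor, platform)
            groups_tr[platform] = g_tr
            for endpoint in ("PFS", "OS"):
                survival[("TR", platform, endpoint)] = stratified_survival(
                    g_tr, self.tr_cohort, endpoint
                )
            if scores_et is not None:
                g_et = apply_threshold(scores_et.platform_scores(platform), g_tr)
                groups_et[platform] = g_et
                for endpoint in ("PFS", "OS"):
                    survival[("ET", platform, endpoint)] = stratified_survival(
                        g_et, self.et_cohort, endpoint
                    )

        scatter = (
            scatter_table(scores_tr, self.tr_cohort.response_of())
            if len(panels) == 2 else None
        )

        correlations = {}
        for platform, panel in panels.items():
            if len(panel) >= 2:
                correlations[platform] = pearson_matrix(
                    self.tr_cohort.matrix(platform), panel
                )

        return CrossResistanceResults(
            model=self, cascade=cascade, panels=panels, rules=rules,
            scores_tr=scores_tr, scores_et=scores_et, roc=roc,
            risk_groups_tr=groups_tr, risk_groups_et=groups_et,
            survival=survival, scatter=scatter, correlations=correlations,
        )


@dataclass(frozen=True)
class CrossResistanceResults:
    """Fitted pipeline state: estimates, diagnostics and report builders."""

    model: CrossResistanceModel
    cascade: CascadeReport
    panels: dict
    rules: dict
    scores_tr: RiskScoreTable
    scores_et: RiskScoreTable | None
    roc: dict  # platform -> ROCCurve (TR response discrimination)
    risk_groups_tr: dict  # platform -> RiskGroups
    risk_groups_et: dict
    survival: dict  # (cohort, platform, endpoint) -> SurvivalContrast
    scatter: pd.DataFrame | None
    correlations: dict = field(default_factory=dict)

    def rule_table(self, platform: str) -> pd.DataFrame:
        return rules_to_frame(self.rules[platform], self.panels.get(platform))

    def stage_counts(self, platform: str = RNA) -> list:
        return self.cascade.stage_counts(platform)

    def summary(self) -> str:
        from crossres.report import format_p

        lines = ["Cross-resistance panel discovery", "=" * 40]
        lines.append("\nCascade stages (surviving feature counts):")
        for stage in self.cascade.stages:
            lines.append(
                f"  [{stage.platform}] {stage.name:<24} "
                f"{len(stage.input_features):>5} -> {stage.count:>5}"
            )
        for platform, panel in self.panels.items():
            lines.append(f"\n{platform} panel ({len(panel)} features): "
                         + ", ".join(panel))
        lines.append("\nResponse discrimination of the cumulative risk score:")
        for platform, curve in self.roc.items():
            band = discrimination_band(min(max(curve.auc, 0.0), 1.0))
            lines.append(
                f"  {platform:<9} AUC = {curve.auc:.3f} "
                f"(p = {format_p(curve.p_value)}, {band} discrimination)"
            )
        lines.append("\nPD-anchored risk thresholds (score >= threshold is high risk):")
        for platform, groups in self.risk_groups_tr.items():
            lines.append(
                f"  {platform:<9} >= {groups.threshold} ({groups.anchor} anchor)"
            )
        lines.append("\nSurvival stratification (log-rank p, high vs low risk):")
        for (cohort, platform, endpoint), contrast in sorted(self.survival.items()):
            p = (format_p(contrast.logrank.p_value)
                 if contrast.logrank is not None else "NA")
            lines.append(
                f"  {cohort} {platform:<9} {endpoint:<4} p = {p:<7} "
                f"(n high/low = {contrast.n_high}/{contrast.n_low})"
            )
        return "\n".join(lines)
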