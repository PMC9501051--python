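"""Cumulative risk scores, score-level ROC, PD-anchored dichotomization,
survival stratification and the RNA x RPPA scatter classification.

A sample's cumulative risk score is the integer count of panel features
for which it falls on the high-risk side of the feature's cut-off rule;
the combined score adds the RNA and RPPA scores where both platforms are
measured.  Risk groups are anchored in the resistant reference group: the
high/low split is at the mean (or median) cumulative score of the PD
samples, with fractional anchors rounded up (scores are integers, so
"score >= mean" is equivalent to "score >= ceil(mean)").  Thresholds
derived on the TR cohort are reused verbatim on the ET cohort — no
refitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from crossres.cohort import Cohort, RNA, RPPA
from crossres.cutpoint import risk_indicators
from crossres.stats import KMCurve, LogRankResult, km_estimate, log_rank_test

ANCHOR_MEAN = "mean"
ANCHOR_MEDIAN = "median"

COMBINED = "COMBINED"


@dataclass(frozen=True)
class RiskScoreTable:
    """Per-sample integer scores per platform plus the combined score."""

    scores: pd.DataFrame = field(repr=False)  # index sample_id
    panels: dict = field(default_factory=dict)  # platform -> ordered features

    def platform_scores(self, platform: str) -> pd.Series:
        col = {RNA: "rna_score", RPPA: "rppa_score", COMBINED: "combined_score"}[platform]
        return self.scores[col]


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    p_value: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class RiskGroups:
    threshold: int
    anchor: str
    platform: str
    assignment: pd.Series = field(repr=False)  # sample_id -> "high" / "low"

    def mask(self, sample_ids) -> np.ndarray:
        return self.assignment.reindex(list(sample_ids)).to_numpy() == "high"


def cumulative_score(cohort: Cohort, rules_by_platform: dict,
                     panels: dict | None = None) -> RiskScoreTable:
    """Sum the per-feature risk indicators over each platform's panel.

    ``rules_by_platform`` maps platform to ``{feature: CutoffRule}``;
    ``panels`` optionally restricts/orders the features used (defaults to
    every rule).  Samples outside the RPPA matrix get a missing RPPA and
    combined score.  Missing expression values contribute 0.
    """
    panels = panels or {
        p: tuple(sorted(rules)) for p, rules in rules_by_platform.items()
    }
    frame = pd.DataFrame(index=list(cohort.sample_ids))
    frame.index.name = "sample_id"
    used = {}
    for platform, col in ((RNA, "rna_score"), (RPPA, "rppa_score")):
        rules = rules_by_platform.get(platform)
        panel = tuple(panels.get(platform, ()))
        mat = cohort.matrix(platform)
        if not rules or not panel or mat is None:
            frame[col] = np.nan
            continue
        if not all(f in rules for f in panel):
            raise ValueError(f"panel features missing from {platform} rules")
        used[platform] = panel
        total = np.zeros(len(mat.sample_ids), dtype=int)
        for feature in panel:
            col_idx = mat.feature_ids.index(feature)
            total += risk_indicators(mat.values[:, col_idx], rules[feature])
        frame[col] = pd.Series(total, index=list(mat.sample_ids)).reindex(frame.index)
    if not used:
        raise ValueError("empty panel: no platform has rules to score")
    frame["combined_score"] = frame["rna_score"] + frame["rppa_score"]
    return RiskScoreTable(scores=frame, panels=used)


def score_roc(scores, labels) -> ROCCurve:
    """Empirical ROC of a (typically integer) score against a binary label.

    The AUC is the tie-corrected rank (Mann-Whitney) formulation; the
    p-value tests AUC = 0.5 through the normal approximation of the
    Mann-Whitney statistic with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes are required")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)

    ranks = sps.rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    n = scores.size
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var_u = n_pos * n_neg / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        p = 1.0
    else:
        z = (u - n_pos * n_neg / 2.0) / math.sqrt(var_u)
        p = 2.0 * float(sps.norm.sf(abs(z)))

    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[labels] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~labels] < t).mean() for t in thresholds])
    return ROCCurve(thresholds, sens, spec, float(auc), min(p, 1.0), n_pos, n_neg)


def dichotomize_by_pd(scores: pd.Series, pd_samples, anchor: str = ANCHOR_MEAN,
                      platform: str = "") -> RiskGroups:
    """High/low split at the PD-group mean or median score (ceiling).

    ``scores`` is a per-sample Series; ``pd_samples`` the resistant
    reference group whose score distribution anchors the threshold.  A
    sample is high-risk iff its score >= threshold.
    """
    pd_samples = [s for s in pd_samples]
    if not pd_samples:
        raise ValueError("empty PD reference group")
    ref = scores.reindex(pd_samples).dropna()
    if ref.empty:
        raise ValueError("no scores for the PD reference group")
    if anchor == ANCHOR_MEAN:
        raw = float(ref.mean())
    elif anchor == ANCHOR_MEDIAN:
        raw = float(ref.median())
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    threshold = int(math.ceil(raw))
    assignment = pd.Series(
        np.where(scores >= threshold, "high", "low"), index=scores.index
    ).mask(scores.isna())
    return RiskGroups(threshold=threshold, anchor=anchor, platform=platform,
                      assignment=assignment)


def apply_threshold(scores: pd.Series, groups: RiskGroups) -> RiskGroups:
    """Reuse a previously derived threshold on another cohort's scores."""
    assignment = pd.Series(
        np.where(scores >= groups.threshold, "high", "low"), index=scores.index
    ).mask(scores.isna())
    return RiskGroups(threshold=groups.threshold, anchor=groups.anchor,
                      platform=groups.platform, assignment=assignment)


@dataclass(frozen=True)
class SurvivalContrast:
    endpoint: str
    km_high: KMCurve | None
    km_low: KMCurve | None
    logrank: LogRankResult | None
    n_high: int
    n_low: int


def stratified_survival(groups: RiskGroups, cohort: Cohort,
                        endpoint: str) -> SurvivalContrast:
    """KM curves per risk group plus the log-rank contrast.

    With an empty group the contrast is recorded as missing rather than
    raising, so degraded runs still produce a report.
    """
    endpoint = endpoint.upper()
    clin = cohort.clinical_indexed()
    assignment = groups.assignment.reindex(clin.index).dropna()
    clin = clin.loc[assignment.index]
    times = clin[f"{endpoint.lower()}_time"].to_numpy(dtype=float)
    events = clin[f"{endpoint.lower()}_event"].to_numpy(dtype=bool)
    high = assignment.to_numpy() == "high"
    n_high, n_low = int(high.sum()), int((~high).sum())
    km_h = km_estimate(times[high], events[high]) if n_high else None
    km_l = km_estimate(times[~high], events[~high]) if n_low else None
    lr = log_rank_test(times, events, high) if n_high and n_low else None
    return SurvivalContrast(endpoint, km_h, km_l, lr, n_high, n_low)


def scatter_table(score_table: RiskScoreTable, labels: pd.Series) -> pd.DataFrame:
    """Plot-ready (sample, rna_score, rppa_score, label) rows.

    Samples without an RPPA score are excluded; the excluded count is
    attached as ``frame.attrs["n_excluded"]``.
    """
    frame = score_table.scores.copy()
    frame["label"] = labels.reindex(frame.index)
    ok = frame["rna_score"].notna() & frame["rppa_score"].notna()
    out = frame.loc[ok, ["rna_score", "rppa_score", "label"]].reset_index()
    out.attrs["n_excluded"] = int((~ok).sum())
    return out
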