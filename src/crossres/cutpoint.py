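"""Per-feature optimal cut-off search and single-cutoff ROC scoring.

Each observed expression value is evaluated as a candidate cut-off under
both orientations (value >= c marks high risk, or value <= c does).  For
every candidate the study population is dichotomized and the single-cutoff
AUC

    AUC = TP / (2 (TP + FN)) + TN / (2 (FP + TN))

— the balanced accuracy, i.e. (sensitivity + specificity) / 2 — is
computed from the confusion counts, where "positive" means the unfavored
outcome (PD, progression, or death).  The maximizing (cut-off, direction)
pair defines the feature's high-risk rule and its individual AUC (IAUC).
Because both orientations are searched, IAUC >= 0.5 by construction.  Note
the maximization makes the IAUC optimistically biased upward in small
samples; it approaches 0.5 under the null only as n grows.

Ties in the maximization are broken deterministically: higher sensitivity
first, then the cut-off farther from the median value, then ">=" before
"<=".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

GE = "ge"  # value >= cutoff is high risk
LE = "le"  # value <= cutoff is high risk

BAND_NONE = "none"
BAND_ACCEPTABLE = "acceptable"
BAND_EXCELLENT = "excellent"
BAND_OUTSTANDING = "outstanding"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class CutoffRule:
    """A feature's high-risk rule plus its per-endpoint evaluation.

    ``metrics`` holds AUC and log-rank p per (cohort, endpoint), e.g.
    ``{("TR", "PFS"): {"auc": 0.76, "p": 0.005}, ...}``, filled in by
    :func:`evaluate_rule_survival` callers.
    """

    feature_id: str
    platform: str
    cutoff: float
    direction: str  # GE or LE
    response_iauc: float
    metrics: dict = field(default_factory=dict)

    def describe(self) -> str:
        sym = ">=" if self.direction == GE else "<="
        return f"{self.feature_id} {sym}{self.cutoff:g}"

    def with_metric(self, cohort: str, endpoint: str, auc, p) -> "CutoffRule":
        metrics = dict(self.metrics)
        metrics[(cohort, endpoint)] = {"auc": auc, "p": p}
        return replace(self, metrics=metrics)


def auc_single_cutoff(counts) -> float:
    """The single-cutoff AUC: TP/(2(TP+FN)) + TN/(2(FP+TN))."""
    if isinstance(counts, ConfusionCounts):
        tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    else:
        tp, fn, tn, fp = counts
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome classes must be nonempty")
    return tp / (2.0 * (tp + fn)) + tn / (2.0 * (fp + tn))


def optimal_cutoff(
    values,
    outcome,
    feature_id: str = "",
    platform: str = "",
) -> CutoffRule:
    """Search every observed value under both directions for the best rule.

    ``outcome`` is the binary unfavored flag (1 = PD / event).  Samples
    with missing expression are excluded from the search.  Raises if only
    one outcome class is present or the feature is constant.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=bool)
    ok = ~np.isnan(values)
    values, outcome = values[ok], outcome[ok]
    n_pos = int(outcome.sum())
    n_neg = int(values.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes are required")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise ValueError("constant feature: no cut-off can dichotomize")

    # suffix/prefix outcome counts over the sorted distinct values
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    pos_sorted = outcome[order].astype(np.int64)
    starts = np.searchsorted(v_sorted, uniq, side="left")
    pos_per_val = np.add.reduceat(pos_sorted, starts)
    n_per_val = np.diff(np.append(starts, v_sorted.size))
    pos_le = np.cumsum(pos_per_val)               # positives with value <= u
    n_le = np.cumsum(n_per_val)
    pos_ge = n_pos - pos_le + pos_per_val          # positives with value >= u
    n_ge = values.size - n_le + n_per_val

    median = float(np.median(values))
    aucs, senses = [], []
    for tp_vec, n_vec in ((pos_ge, n_ge), (pos_le, n_le)):
        tp = tp_vec.astype(float)
        fp = n_vec - tp
        tn = n_neg - fp
        aucs.append(tp / (2.0 * n_pos) + tn / (2.0 * n_neg))
        senses.append(tp / n_pos)
    auc = np.concatenate(aucs)
    sens = np.concatenate(senses)
    dist = np.tile(np.abs(uniq - median), 2)
    pref = np.concatenate([np.ones(uniq.size), np.zeros(uniq.size)])  # ge first
    # lexicographic max: AUC, then sensitivity, then |cutoff - median|,
    # then ">=" before "<="; np.lexsort is stable with the last key primary
    best = np.lexsort((pref, dist, sens, auc))[-1]
    direction = GE if best < uniq.size else LE
    cutoff = float(uniq[best % uniq.size])
    return CutoffRule(
        feature_id=feature_id, platform=platform,
        cutoff=cutoff, direction=direction, response_iauc=float(auc[best]),
    )


def risk_indicator(value: float, rule: CutoffRule) -> int:
    """1 iff the value falls on the rule's high-risk side (inclusive).

    Missing values score 0 (low risk) by convention, so cumulative scores
    stay comparable across samples.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0
    if rule.direction == GE:
        return int(value >= rule.cutoff)
    return int(value <= rule.cutoff)


def risk_indicators(values, rule: CutoffRule) -> np.ndarray:
    """Vectorized :func:`risk_indicator`; NaN maps to 0."""
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if rule.direction == GE:
            high = values >= rule.cutoff
        else:
            high = values <= rule.cutoff
    return np.where(np.isnan(values), 0, high.astype(int))


def discrimination_band(auc: float) -> str:
    """Conventional discrimination label; boundaries go to the higher band."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC {auc} outside [0, 1]")
    if auc >= 0.9:
        return BAND_OUTSTANDING
    if auc >= 0.8:
        return BAND_EXCELLENT
    if auc >= 0.7:
        return BAND_ACCEPTABLE
    return BAND_NONE


def evaluate_rule_survival(rule: CutoffRule, cohort, endpoint: str):
    """Evaluate a rule against a survival endpoint ("PFS" or "OS").

    Dichotomizes the cohort by the rule, scores the single-cutoff AUC
    against the endpoint's event flag, and runs the log-rank test between
    the risk groups.  Returns ``(auc, p)``; either is NaN when undefined
    (single event class, or an empty risk group).
    """
    from crossres.stats import log_rank_test

    endpoint = endpoint.upper()
    if endpoint not in ("PFS", "OS"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    matrix = cohort.matrix(rule.platform)
    if matrix is None:
        return float("nan"), float("nan")
    col = matrix.feature_ids.index(rule.feature_id)
    high = risk_indicators(matrix.values[:, col], rule)
    clin = cohort.clinical_indexed().loc[list(matrix.sample_ids)]
    times = clin[f"{endpoint.lower()}_time"].to_numpy(dtype=float)
    events = clin[f"{endpoint.lower()}_event"].to_numpy(dtype=bool)

    n_event = int(events.sum())
    if 0 < n_event < events.size:
        tp = int((high.astype(bool) & events).sum())
        fp = int((high.astype(bool) & ~events).sum())
        fn = n_event - tp
        tn = events.size - n_event - fp
        auc = auc_single_cutoff((tp, fn, tn, fp))
    else:
        auc = float("nan")
    if 0 < int(high.sum()) < high.size:
        p = log_rank_test(times, events, high).p_value
    else:
        p = float("nan")
    return float(auc), float(p)
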