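"""Report tables, pipeline orchestration and deterministic output bundles.

Every file the pipeline writes starts with a comment header carrying the
seed and a hash of the configuration, so any report value can be traced
back to the exact run that produced it.  Display rounding (three
decimals, "<0.001" floor) happens only here; machine-readable outputs
keep raw p-values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from crossres.cascade import CascadeConfig
from crossres.cohort import (
    Cohort,
    REGIMEN_AI,
    RESPONSE_CR,
    RESPONSE_PD,
    RNA,
    RPPA,
    read_cohort,
    write_cohort,
)
from crossres.risk import ANCHOR_MEAN
from crossres.simulate import (
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    generate_cohort_pair,
)
from crossres.stats import fisher_exact_2x2, kruskal_wallis, wilcoxon_rank_sum


def format_p(p: float) -> str:
    """Display rounding used in the report tables: 3 decimals, "<0.001"."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "NA"
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


def _median_range(x) -> str:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return "NA"
    return f"{np.median(x):.2f} ({x.min():.2f}-{x.max():.2f})"


def _count_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)" if n else "0 (0.0%)"


def baseline_table(cohort: Cohort) -> pd.DataFrame:
    """Baseline-characteristics table for a TR cohort (CR vs PD).

    Binary characteristics are tested with Fisher's exact test on the
    CR/PD 2x2 table; age with the Wilcoxon rank-sum test.  The PD
    subgroup columns (AI vs SERM/SERD first-line regimen) carry a
    Kruskal-Wallis p for age across CR/AI-PD/SERM-SERD-PD and a Fisher p
    where the comparison is 2x2.
    """
    clin = cohort.clinical
    cr = clin["response"] == RESPONSE_CR
    pdm = clin["response"] == RESPONSE_PD
    ai_pd = pdm & (clin["regimen"] == REGIMEN_AI)
    ss_pd = pdm & (clin["regimen"] != REGIMEN_AI)
    n, n_cr, n_pd = len(clin), int(cr.sum()), int(pdm.sum())

    rows = []
    age = clin["age_years"].to_numpy(dtype=float)
    p_age = wilcoxon_rank_sum(age[cr], age[pdm]).p_value if n_cr and n_pd else np.nan
    p_age3 = (
        kruskal_wallis([age[cr], age[ai_pd], age[ss_pd]]).p_value
        if cr.any() and ai_pd.any() and ss_pd.any() else np.nan
    )
    rows.append({
        "characteristic": "age_years", "level": "median (range)",
        "overall": _median_range(age), "cr": _median_range(age[cr]),
        "pd": _median_range(age[pdm]), "p": p_age, "p_display": format_p(p_age),
        "test": "wilcoxon", "pd_ai": _median_range(age[ai_pd]),
        "pd_serm_serd": _median_range(age[ss_pd]), "p_subgroup": p_age3,
    })

    binary_characteristics = [
        ("t_stage", "T3_4"), ("n_stage", "N1_3"), ("m_stage", "M1"),
        ("stage", "III_IV"),
    ]
    for colname, level in binary_characteristics:
        flag = clin[colname] == level
        rows.append(_binary_row(colname, level, flag, cr, pdm, ai_pd, ss_pd))
    for regimen in ("AI", "SERM", "SERD"):
        flag = clin["regimen"] == regimen
        rows.append(_binary_row("regimen", regimen, flag, cr, pdm, ai_pd, ss_pd))
    for colname, label in (("pfs_event", "progressed"), ("os_event", "died")):
        flag = clin[colname].astype(bool)
        rows.append(_binary_row(colname, label, flag, cr, pdm, ai_pd, ss_pd))
    return pd.DataFrame(rows)


def _binary_row(name, level, flag, cr, pdm, ai_pd, ss_pd):
    n = len(flag)
    a = int((flag & cr).sum())
    b = int((~flag & cr).sum())
    c = int((flag & pdm).sum())
    d = int((~flag & pdm).sum())
    p = fisher_exact_2x2(a, b, c, d).p_value
    p_sub = fisher_exact_2x2(
        int((flag & ai_pd).sum()), int((~flag & ai_pd).sum()),
        int((flag & ss_pd).sum()), int((~flag & ss_pd).sum()),
    ).p_value
    return {
        "characteristic": name, "level": level,
        "overall": _count_pct(int(flag.sum()), n),
        "cr": _count_pct(a, a + b), "pd": _count_pct(c, c + d),
        "p": p, "p_display": format_p(p), "test": "fisher",
        "pd_ai": _count_pct(int((flag & ai_pd).sum()), int(ai_pd.sum())),
        "pd_serm_serd": _count_pct(int((flag & ss_pd).sum()), int(ss_pd.sum())),
        "p_subgroup": p_sub,
    }


def expression_summary_table(cohort: Cohort, features, platform: str = RNA) -> pd.DataFrame:
    """Median (range) per response group with the Wilcoxon rank-sum p."""
    mat = cohort.matrix(platform)
    clin = cohort.clinical_indexed().loc[list(mat.sample_ids)]
    cr = (clin["response"] == RESPONSE_CR).to_numpy()
    pdm = (clin["response"] == RESPONSE_PD).to_numpy()
    rows = []
    for feature in features:
        x = mat.values[:, mat.feature_ids.index(feature)]
        x_cr, x_pd = x[cr & ~np.isnan(x)], x[pdm & ~np.isnan(x)]
        p = (wilcoxon_rank_sum(x_cr, x_pd).p_value
             if x_cr.size and x_pd.size else np.nan)
        rows.append({
            "feature": feature, "platform": platform,
            "overall": _median_range(x[~np.isnan(x)]),
            "cr": _median_range(x_cr), "pd": _median_range(x_pd),
            "p": p, "p_display": format_p(p),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "crossres_out"
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    tr_clinical: str | None = None
    tr_rna: str | None = None
    tr_rppa: str | None = None
    et_clinical: str | None = None
    et_rna: str | None = None
    et_rppa: str | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    anchor: str = ANCHOR_MEAN

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed, "anchor": self.anchor,
            "cascade": asdict(self.cascade),
            "simulation": (config_to_dict(self.simulation)
                           if self.simulation else None),
            "paths": [self.tr_clinical, self.tr_rna, self.tr_rppa,
                      self.et_clinical, self.et_rna, self.et_rppa],
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        casc = raw.pop("cascade", None)
        cfg = cls(
            **raw,
            simulation=config_from_dict(sim) if sim else None,
            cascade=CascadeConfig(**{
                **(casc or {}),
                **({"tr_criteria": tuple(casc["tr_criteria"])} if casc and "tr_criteria" in casc else {}),
                **({"et_criteria": tuple(casc["et_criteria"])} if casc and "et_criteria" in casc else {}),
            }),
        )
        return cfg


def _write_tsv(frame: pd.DataFrame, path: str, header: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, sep="\t", index=index, na_rep="NA")


def load_cohorts(config: PipelineConfig):
    """Simulate or read the (TR, ET) cohorts per the configuration."""
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        return generate_cohort_pair(sim)
    tr = read_cohort(config.tr_clinical, config.tr_rna, config.tr_rppa)
    et = (read_cohort(config.et_clinical, config.et_rna, config.et_rppa)
          if config.et_clinical else None)
    return tr, et


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/read -> fit -> write the full report bundle.

    Returns ``{name: path}`` of everything written.  Rerunning with an
    identical configuration produces byte-identical files.
    """
    from crossres.model import CrossResistanceModel

    os.makedirs(config.outdir, exist_ok=True)
    header = f"# crossres seed={config.seed} config={config.config_hash()}\n"
    paths = {}

    tr, et = load_cohorts(config)
    if config.simulation is not None:
        paths.update({f"tr_{k}": v for k, v in
                      write_cohort(tr, config.outdir, "tr").items()})
        if et is not None:
            paths.update({f"et_{k}": v for k, v in
                          write_cohort(et, config.outdir, "et").items()})

    model = CrossResistanceModel(tr, et, config.cascade, config.anchor)
    results = model.fit()

    def emit(name, frame, index=False):
        path = os.path.join(config.outdir, name)
        _write_tsv(frame, path, header, index=index)
        paths[name] = path

    emit("cascade_stages.tsv", results.cascade.to_frame())
    for platform in results.panels:
        emit(f"rules_{platform.lower()}.tsv", results.rule_table(platform))
    emit("scores_tr.tsv", results.scores_tr.scores, index=True)
    if results.scores_et is not None:
        emit("scores_et.tsv", results.scores_et.scores, index=True)
    roc_rows = []
    for platform, curve in results.roc.items():
        for t, se, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            roc_rows.append({
                "platform": platform, "threshold": t,
                "sensitivity": se, "specificity": sp,
                "auc": curve.auc, "p": curve.p_value,
            })
    if roc_rows:
        emit("roc_tr.tsv", pd.DataFrame(roc_rows))
    km_rows = []
    for (cohort_name, platform, endpoint), contrast in sorted(results.survival.items()):
        for label, km in (("high", contrast.km_high), ("low", contrast.km_low)):
            if km is None:
                continue
            for t, s, r in zip(km.event_times, km.survival, km.at_risk):
                km_rows.append({
                    "cohort": cohort_name, "platform": platform,
                    "endpoint": endpoint, "risk_group": label,
                    "time": t, "survival": s, "at_risk": r,
                    "logrank_p": (contrast.logrank.p_value
                                  if contrast.logrank else np.nan),
                })
    if km_rows:
        emit("survival_km.tsv", pd.DataFrame(km_rows))
    if results.scatter is not None:
        emit("scatter_tr.tsv", results.scatter)
    emit("baseline_tr.tsv", baseline_table(tr))
    for platform, panel in results.panels.items():
        emit(f"expression_summary_{platform.lower()}.tsv",
             expression_summary_table(tr, panel, platform))
    for platform, corr in results.correlations.items():
        emit(f"correlation_{platform.lower()}.tsv",
             pd.DataFrame(corr.r, index=list(corr.feature_ids),
                          columns=list(corr.feature_ids)), index=True)

    summary_path = os.path.join(config.outdir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write(header + results.summary() + "\n")
    paths["summary.txt"] = summary_path

    machine = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_counts": {
            platform: results.stage_counts(platform)
            for platform in results.panels
        },
        "panels": {p: list(panel) for p, panel in results.panels.items()},
        "response_auc": {p: c.auc for p, c in results.roc.items()},
        "risk_thresholds": {
            p: g.threshold for p, g in results.risk_groups_tr.items()
        },
        "logrank_p": {
            f"{c}_{p}_{e}": (v.logrank.p_value if v.logrank else None)
            for (c, p, e), v in sorted(results.survival.items())
        },
    }
    json_path = os.path.join(config.outdir, "report.json")
    with open(json_path, "w") as fh:
        json.dump(machine, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["report.json"] = json_path
    return paths
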