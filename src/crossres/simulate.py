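"""Synthetic two-cohort generator with planted resistance markers.

Emulates the statistical structure the pipeline assumes: a small
treatment-response (TR) cohort with CR/PD labels, a large endocrine-therapy
(ET) cohort whose resistance status is latent, z-score-scale expression
with block-correlated features, planted informative features shifted in
resistant samples, and censored progression/death times with a hazard
multiplier for resistant subjects.

Feature marginals are standard normal (the pipeline consumes z-scores, so
no count-level simulation is attempted).  Within-block dependence is an
equicorrelated Gaussian; informative features are placed two per block so
the correlation-matrix stage of the analysis has structure to find.

Disease course: progression and death times are each exponential with
hazards ``baseline_hazard * hazard_ratio_pd**resistant`` and
``os_hazard * hazard_ratio_pd**resistant``; the two times are coupled
through a Gaussian copula (``endpoint_rho``) so the PFS and OS endpoints
are correlated the way real cohorts' endpoints are while keeping both
marginals exponential.  A single exponential follow-up (censoring) time
per subject is applied to both endpoints, with its rate calibrated so the
expected progression-censoring fraction in non-resistant subjects equals
``censor_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from crossres.cohort import (
    ARM_ET,
    ARM_TR,
    CLINICAL_COLUMNS,
    Cohort,
    ExpressionMatrix,
    REGIMEN_AI,
    REGIMEN_SERD,
    REGIMEN_SERM,
    RESPONSE_CR,
    RESPONSE_PD,
    RESPONSE_UNKNOWN,
    RNA,
    RPPA,
)

# per-group clinical category probabilities (T3-4, N1-3, M1, stage III-IV)
_CLINICAL_PROBS = {
    "CR": {"t34": 0.12, "n13": 0.50, "m1": 0.00, "stage34": 0.21},
    "PD": {"t34": 0.20, "n13": 0.70, "m1": 0.20, "stage34": 0.60},
    "ET": {"t34": 0.165, "n13": 0.523, "m1": 0.01, "stage34": 0.258},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-cohort study.

    Defaults mirror the emulated study: TR cohort of 34 CR + 10 PD with
    the PD group split evenly between AI and SERM/SERD first-line
    regimens, an ET cohort of 449, an RPPA subset covering 32/44 of TR
    samples, and a latent ET-arm resistance prevalence of 0.15.
    """

    seed: int = 0
    n_cr: int = 34
    n_pd: int = 10
    n_et: int = 449
    n_rna_features: int = 500
    n_rppa_features: int = 100
    n_informative_rna: int = 10
    n_informative_rppa: int = 5
    effect_shift: float = 1.5
    block_size: int = 10
    block_rho: float = 0.5
    arm_mix: tuple = ((REGIMEN_AI, 0.50), (REGIMEN_SERM, 0.455), (REGIMEN_SERD, 0.045))
    baseline_hazard: float = 1.0 / 1500.0  # progression hazard per day
    hazard_ratio_pd: float = 2.5
    os_hazard: float = 1.0 / 1800.0  # death hazard per day
    endpoint_rho: float = 0.7  # Gaussian-copula correlation of PFS/OS times
    censor_rate: float = 0.3
    rppa_subset_fraction: float = 32.0 / 44.0
    et_rppa_fraction: float = 370.0 / 449.0
    et_resistance_prevalence: float = 0.15

    def validate(self) -> None:
        counts = {
            "n_cr": self.n_cr, "n_pd": self.n_pd, "n_et": self.n_et,
            "n_rna_features": self.n_rna_features,
            "n_rppa_features": self.n_rppa_features,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_informative_rna > self.n_rna_features:
            raise ValueError("n_informative_rna exceeds n_rna_features")
        if self.n_informative_rppa > self.n_rppa_features:
            raise ValueError("n_informative_rppa exceeds n_rppa_features")
        if not -1.0 <= self.block_rho <= 1.0:
            raise ValueError("block_rho must be in [-1, 1]")
        for name in ("censor_rate", "rppa_subset_fraction", "et_rppa_fraction",
                     "et_resistance_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(p for _, p in self.arm_mix) - 1.0) > 1e-9:
            raise ValueError("arm_mix probabilities must sum to 1")
        if self.hazard_ratio_pd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Exact planted truth (test oracle, not part of the data model)."""

    features: dict  # feature_id -> {"informative", "delta", "platform"}
    et_resistant: pd.Series = field(repr=False)  # sample_id -> bool


def _feature_ids(config: SimulationConfig) -> dict:
    rna = [f"G{i + 1:04d}" for i in range(config.n_rna_features)]
    rppa = [f"P{i + 1:04d}" for i in range(config.n_rppa_features)]
    return {RNA: rna, RPPA: rppa}


def _informative_indices(n_features: int, n_informative: int, block_size: int):
    """Spread informative features two per correlation block."""
    n_blocks = max(1, math.ceil(n_features / block_size))
    per_block = 2
    idx = []
    for i in range(n_informative):
        block = (i // per_block) % n_blocks
        offset = i % per_block + (i // (per_block * n_blocks)) * per_block
        idx.append(block * block_size + offset)
    if len(set(idx)) < n_informative or (idx and max(idx) >= n_features):
        # dense fallback for tiny feature spaces
        idx = list(range(n_informative))
    return sorted(idx)


def truth_table(config: SimulationConfig) -> dict:
    """Planted truth per feature id: ``{informative, delta, platform}``.

    Deterministic in the configuration; used by tests as the oracle for
    recovery studies.
    """
    config.validate()
    ids = _feature_ids(config)
    table = {}
    for platform, n_inf in ((RNA, config.n_informative_rna),
                            (RPPA, config.n_informative_rppa)):
        names = ids[platform]
        inf = set(_informative_indices(len(names), n_inf, config.block_size))
        for j, name in enumerate(names):
            informative = j in inf
            table[name] = {
                "informative": informative,
                "delta": config.effect_shift if informative else 0.0,
                "platform": platform,
            }
    return table


def _block_correlated(rng, n_samples, n_features, block_size, rho):
    """Standard-normal matrix with equicorrelated blocks of consecutive features."""
    x = np.empty((n_samples, n_features))
    for start in range(0, n_features, block_size):
        width = min(block_size, n_features - start)
        cov = np.full((width, width), rho)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        x[:, start:start + width] = rng.standard_normal((n_samples, width)) @ chol.T
    return x


def _expression(rng, config, platform, resistant: np.ndarray) -> np.ndarray:
    n_features = (config.n_rna_features if platform == RNA
                  else config.n_rppa_features)
    n_inf = (config.n_informative_rna if platform == RNA
             else config.n_informative_rppa)
    x = _block_correlated(rng, resistant.size, n_features,
                          config.block_size, config.block_rho)
    inf = _informative_indices(n_features, n_inf, config.block_size)
    x[np.ix_(resistant.astype(bool), inf)] += config.effect_shift
    return x


def _survival(rng, config, resistant: np.ndarray):
    from scipy.stats import norm

    n = resistant.size
    hr = np.where(resistant, config.hazard_ratio_pd, 1.0)
    # exponential marginals with a Gaussian copula between the endpoints
    rho = config.endpoint_rho
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n)
    u1 = norm.cdf(z1)
    u2 = norm.cdf(z2)
    t_prog = -np.log1p(-u1) / (config.baseline_hazard * hr)
    t_death = -np.log1p(-u2) / (config.os_hazard * hr)
    if config.censor_rate <= 0.0:
        censor = np.full(n, np.inf)
    elif config.censor_rate >= 1.0:
        censor = np.zeros(n)
    else:
        # P(censor first) = lc / (lc + l) for competing exponentials
        lc = config.baseline_hazard * config.censor_rate / (1.0 - config.censor_rate)
        censor = rng.exponential(1.0 / lc, size=n)
    pfs_time = np.minimum(t_prog, censor)
    pfs_event = t_prog <= censor
    os_time = np.minimum(t_death, censor)
    os_event = t_death <= censor
    return pfs_time, pfs_event, os_time, os_event


def _clinical_categories(rng, group: str, n: int) -> dict:
    p = _CLINICAL_PROBS[group]
    return {
        "t_stage": np.where(rng.random(n) < p["t34"], "T3_4", "T1_2"),
        "n_stage": np.where(rng.random(n) < p["n13"], "N1_3", "N0"),
        "m_stage": np.where(rng.random(n) < p["m1"], "M1", "M0"),
        "stage": np.where(rng.random(n) < p["stage34"], "III_IV", "I_II"),
    }


def _draw_regimens(rng, config, n):
    names = [a for a, _ in config.arm_mix]
    probs = np.array([p for _, p in config.arm_mix])
    return rng.choice(names, size=n, p=probs / probs.sum())


def _pd_regimens(rng, config, n_pd):
    """PD regimens: even AI vs SERM/SERD split when n_pd is even."""
    mix = dict(config.arm_mix)
    p_serm = mix.get(REGIMEN_SERM, 0.0)
    p_serd = mix.get(REGIMEN_SERD, 0.0)
    denom = p_serm + p_serd
    p_serd_given_ss = p_serd / denom if denom > 0 else 0.0
    if n_pd % 2 == 0:
        n_ai = n_pd // 2
    else:
        n_ai = int(rng.integers(n_pd // 2, n_pd // 2 + 2))
    n_ss = n_pd - n_ai
    ss = np.where(rng.random(n_ss) < p_serd_given_ss, REGIMEN_SERD, REGIMEN_SERM)
    regimens = np.concatenate([np.full(n_ai, REGIMEN_AI), ss])
    return rng.permutation(regimens)


def generate_cohort_pair(config: SimulationConfig, return_truth: bool = False):
    """Generate the (TR, ET) cohort pair; optionally also the planted truth.

    All draws come from a single generator seeded with ``config.seed``, so
    the same configuration always produces identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = _feature_ids(config)

    # --- TR cohort -------------------------------------------------------
    n_tr = config.n_cr + config.n_pd
    tr_ids = [f"TR-{i + 1:04d}" for i in range(n_tr)]
    response = np.array([RESPONSE_CR] * config.n_cr + [RESPONSE_PD] * config.n_pd)
    resistant_tr = response == RESPONSE_PD
    regimen = np.empty(n_tr, dtype=object)
    regimen[~resistant_tr] = _draw_regimens(rng, config, config.n_cr)
    regimen[resistant_tr] = _pd_regimens(rng, config, config.n_pd)

    age_tr = np.clip(rng.normal(58.0, 12.0, n_tr), 30.0, 90.0).round(0)
    cats = {}
    for key in ("t_stage", "n_stage", "m_stage", "stage"):
        cats[key] = np.empty(n_tr, dtype=object)
    for grp, mask in (("CR", ~resistant_tr), ("PD", resistant_tr)):
        drawn = _clinical_categories(rng, grp, int(mask.sum()))
        for key, vals in drawn.items():
            cats[key][mask] = vals
    pfs_t, pfs_e, os_t, os_e = _survival(rng, config, resistant_tr)

    tr_clin = pd.DataFrame({
        "sample_id": tr_ids,
        "cohort_arm": ARM_TR,
        "response": response,
        "regimen": regimen,
        "age_years": age_tr,
        **cats,
        "pfs_time": np.round(pfs_t, 1),
        "pfs_event": pfs_e,
        "os_time": np.round(os_t, 1),
        "os_event": os_e,
    })[CLINICAL_COLUMNS]

    tr_rna = ExpressionMatrix(
        RNA, tuple(tr_ids), tuple(ids[RNA]),
        _expression(rng, config, RNA, resistant_tr),
    )
    # stratified RPPA subset: preserve the CR/PD balance of the full cohort
    n_rppa = int(round(config.rppa_subset_fraction * n_tr))
    n_rppa_cr = int(round(n_rppa * config.n_cr / n_tr))
    n_rppa_pd = n_rppa - n_rppa_cr
    cr_pick = rng.choice(np.where(~resistant_tr)[0], size=min(n_rppa_cr, config.n_cr),
                         replace=False)
    pd_pick = rng.choice(np.where(resistant_tr)[0], size=min(n_rppa_pd, config.n_pd),
                         replace=False)
    rppa_rows = np.sort(np.concatenate([cr_pick, pd_pick]))
    rppa_values = _expression(rng, config, RPPA, resistant_tr)[rppa_rows]
    tr_rppa = ExpressionMatrix(
        RPPA, tuple(tr_ids[i] for i in rppa_rows), tuple(ids[RPPA]), rppa_values,
    ) if config.n_rppa_features > 0 and n_rppa > 0 else None

    tr = Cohort(clinical=tr_clin, rna=tr_rna, rppa=tr_rppa)

    # --- ET cohort -------------------------------------------------------
    et_ids = [f"ET-{i + 1:04d}" for i in range(config.n_et)]
    resistant_et = rng.random(config.n_et) < config.et_resistance_prevalence
    et_cats = _clinical_categories(rng, "ET", config.n_et)
    pfs_t, pfs_e, os_t, os_e = _survival(rng, config, resistant_et)
    et_clin = pd.DataFrame({
        "sample_id": et_ids,
        "cohort_arm": ARM_ET,
        "response": RESPONSE_UNKNOWN,
        "regimen": _draw_regimens(rng, config, config.n_et),
        "age_years": np.clip(rng.normal(60.0, 11.0, config.n_et), 30.0, 90.0).round(0),
        **et_cats,
        "pfs_time": np.round(pfs_t, 1),
        "pfs_event": pfs_e,
        "os_time": np.round(os_t, 1),
        "os_event": os_e,
    })[CLINICAL_COLUMNS]

    et_rna = ExpressionMatrix(
        RNA, tuple(et_ids), tuple(ids[RNA]),
        _expression(rng, config, RNA, resistant_et),
    )
    n_et_rppa = int(round(config.et_rppa_fraction * config.n_et))
    et_rppa = None
    if tr_rppa is not None and n_et_rppa > 0:
        rows = np.sort(rng.choice(config.n_et, size=n_et_rppa, replace=False))
        et_rppa = ExpressionMatrix(
            RPPA, tuple(et_ids[i] for i in rows), tuple(ids[RPPA]),
            _expression(rng, config, RPPA, resistant_et)[rows],
        )
    et = Cohort(clinical=et_clin, rna=et_rna, rppa=et_rppa)

    if not return_truth:
        return tr, et
    truth = SimTruth(
        features=truth_table(config),
        et_resistant=pd.Series(resistant_et, index=et_ids),
    )
    return tr, et, truth


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["arm_mix"] = [list(pair) for pair in config.arm_mix]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "arm_mix" in d:
        d["arm_mix"] = tuple((str(a), float(p)) for a, p in d["arm_mix"])
    return SimulationConfig(**d)
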