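import numpy as np
import pandas as pd
import pytest

from crossres.cohort import CLINICAL_COLUMNS, Cohort, ExpressionMatrix
from crossres.simulate import SimulationConfig, generate_cohort_pair


def tiny_clinical(n, arm="TR", n_pd=2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        is_pd = arm == "TR" and i < n_pd
        rows.append({
            "sample_id": f"S{i + 1:03d}",
            "cohort_arm": arm,
            "response": ("PD" if is_pd else "CR") if arm == "TR" else "unknown",
            "regimen": ["AI", "SERM", "SERD"][i % 3],
            "age_years": float(50 + i),
            "t_stage": "T1_2" if i % 2 else "T3_4",
            "n_stage": "N0" if i % 2 else "N1_3",
            "m_stage": "M0",
            "stage": "I_II" if i % 2 else "III_IV",
            "pfs_time": float(rng.integers(100, 2000)),
            "pfs_event": bool(rng.random() < 0.5),
            "os_time": float(rng.integers(100, 3000)),
            "os_event": bool(rng.random() < 0.3),
        })
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


@pytest.fixture
def tiny_cohort():
    """Five-sample TR cohort with a 4-feature RNA matrix and a 3-sample RPPA."""
    clin = tiny_clinical(5)
    rng = np.random.default_rng(42)
    rna = ExpressionMatrix(
        "RNA", tuple(clin["sample_id"]), ("G1", "G2", "G3", "G4"),
        rng.standard_normal((5, 4)),
    )
    rppa_vals = rng.standard_normal((3, 2))
    rppa_vals[0, 1] = np.nan
    rppa = ExpressionMatrix(
        "RPPA", tuple(clin["sample_id"][:3]), ("P1", "P2"), rppa_vals,
    )
    return Cohort(clinical=clin, rna=rna, rppa=rppa)


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=7, n_cr=20, n_pd=6, n_et=120, n_rna_features=60,
        n_rppa_features=20, n_informative_rna=4, n_informative_rppa=2,
        effect_shift=2.0,
    )


@pytest.fixture(scope="session")
def small_pair(small_sim_config):
    return generate_cohort_pair(small_sim_config)


@pytest.fixture(scope="session")
def default_pair():
    """One cohort pair at the study's default conditions."""
    return generate_cohort_pair(SimulationConfig(seed=11))
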