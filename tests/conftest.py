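import numpy as np
import pandas as pd
import pytest

from treeletcox import BlockSpec, HazardSpec, generate_cohort, generate_panel


@pytest.fixture(scope="session")
def block_panel() -> pd.DataFrame:
    """Subcohort-sized panel with the default seven-block structure."""
    return generate_panel(3000, seed=42)


@pytest.fixture(scope="session")
def random_panels() -> list[np.ndarray]:
    """Unstructured random 32-channel matrices for basis-exactness checks."""
    rng = np.random.default_rng(2024)
    out = []
    for _ in range(3):
        a = rng.normal(size=(32, 32))
        cov = a @ a.T / 32 + np.eye(32)
        chol = np.linalg.cholesky(cov)
        out.append(rng.standard_normal((300, 32)) @ chol.T)
    return out


def planted_quintile_cohort(n: int, seed: int, hr_q5: float = 0.60):
    """Cohort whose hazard carries a linear-in-quintile planted effect.

    Returns (cohort, score series); the per-quintile true log HR is
    log(hr_q5) * (q - 1) / 4, i.e. Q5 vs Q1 equals ``hr_q5``.
    """
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    ranks = pd.Series(score).rank(pct=True).to_numpy()
    q = np.minimum((ranks * 5).astype(int) + 1, 5)
    eta = np.log(hr_q5) * (q - 1) / 4
    cohort = generate_cohort(
        n,
        HazardSpec(log_hr_per_factor=(0.0,)),
        None,
        seed=int(rng.integers(2**31)),
        extra_log_hazard=eta,
        covariates=False,
    )
    return cohort, pd.Series(score, index=cohort.index)
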