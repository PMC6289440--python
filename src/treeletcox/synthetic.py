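"""Synthetic cohort generator for the fatty-acid pattern analysis.

Emulates the statistical structure the downstream analysis assumes: a
32-channel fatty-acid panel with a block correlation pattern, Gompertz-type
AF event times on the age scale with delayed entry, baseline covariates with
realistic marginals, and the case-cohort subsampler with Barlow-style
weights.

All randomness flows from one integer seed through spawned
``numpy.random.Generator`` streams, so an identical seed reproduces an
identical cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import BLOCKS, CHANNELS, CHANNEL_IDS, UNASSIGNED

__all__ = [
    "BlockSpec",
    "ChannelMoments",
    "HazardSpec",
    "generate_panel",
    "generate_cohort",
    "sample_case_cohort",
    "calibrate_baseline_scale",
    "true_block_scores",
]

SMOKING_LEVELS = ("never", "former", "<15", "15-25", ">25")
SCHOOL_LEVELS = ("<=7", "8-10", ">=10")
COMORBIDITY_FLAGS = (
    "hypercholesterolemia",
    "hypertension",
    "angina",
    "heart_failure",
    "prior_mi",
    "diabetes",
    "renal_disease",
)

COHORT_COLUMNS = (
    "subject_id",
    "sex",
    "entry_age",
    "exit_age",
    "event",
    "subcohort",
    "weight",
    "smoking",
    "school",
    "alcohol",
    "bmi",
    "waist",
) + COMORBIDITY_FLAGS

# Marginal covariate distributions by sex (subcohort frequencies of the
# source population; schooling levels completed from the >=10-years fraction).
_COVARIATE_MARGINALS = {
    "male": {
        "smoking": (0.268, 0.352, 0.112, 0.165, 0.105),
        "school": (0.33, 0.42, 0.25),
        "alcohol_mu_sigma": (np.log(19.7), (np.log(79.5) - np.log(19.7)) / 1.645),
        "bmi_mean_sd": (26.4, (33.0 - 22.2) / 3.29),
        "waist_mean_sd": (96.0, (114.0 - 83.0) / 3.29),
        "flags": {
            "hypercholesterolemia": 0.095,
            "hypertension": 0.153,
            "angina": 0.039,
            "heart_failure": 0.002,
            "prior_mi": 0.030,
            "diabetes": 0.026,
            "renal_disease": 0.016,
        },
    },
    "female": {
        "smoking": (0.448, 0.224, 0.159, 0.145, 0.023),
        "school": (0.35, 0.45, 0.20),
        "alcohol_mu_sigma": (np.log(9.6), (np.log(41.4) - np.log(9.6)) / 1.645),
        "bmi_mean_sd": (24.7, (34.2 - 19.8) / 3.29),
        "waist_mean_sd": (80.0, (105.0 - 67.0) / 3.29),
        "flags": {
            "hypercholesterolemia": 0.059,
            "hypertension": 0.168,
            "angina": 0.021,
            "heart_failure": 0.001,
            "prior_mi": 0.003,
            "diabetes": 0.013,
            "renal_disease": 0.019,
        },
    },
}

_P_MALE = 27178 / 57053  # men / enrolled participants


@dataclass(frozen=True)
class BlockSpec:
    """Block-structured correlation pattern for the fatty-acid panel.

    Channels inside one block share correlation ``within_rho``; every other
    pair of channels (across blocks or involving an unassigned channel)
    shares ``between_rho``. Positive definiteness of the implied matrix is
    verified at construction.
    """

    blocks: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        (label, members) for label, members in BLOCKS.items()
    )
    within_rho: float = 0.6
    between_rho: float = 0.05
    unassigned: tuple[str, ...] = UNASSIGNED
    channel_ids: tuple[str, ...] = CHANNEL_IDS

    def __post_init__(self) -> None:
        seen: list[str] = []
        for _, members in self.blocks:
            seen.extend(members)
        seen.extend(self.unassigned)
        if sorted(seen) != sorted(self.channel_ids):
            raise ValueError(
                "every channel must appear in exactly one block or in `unassigned`"
            )
        if abs(self.between_rho) > abs(self.within_rho):
            raise ValueError("|between_rho| must not exceed |within_rho|")
        if not -1 < self.within_rho < 1:
            raise ValueError("within_rho must lie in (-1, 1)")
        if not -1 < self.between_rho < 1:
            raise ValueError("between_rho must lie in (-1, 1)")
        corr = self.correlation_matrix()
        lam_min = float(np.linalg.eigvalsh(corr)[0])
        if lam_min <= 1e-10:
            raise ValueError(
                f"implied correlation matrix is not positive definite "
                f"(smallest eigenvalue {lam_min:.3e})"
            )

    def block_labels(self) -> dict[str, str | None]:
        """Channel id -> block label (None for unassigned channels)."""
        out: dict[str, str | None] = {c: None for c in self.channel_ids}
        for label, members in self.blocks:
            for c in members:
                out[c] = label
        return out

    def correlation_matrix(self) -> np.ndarray:
        """Implied p x p correlation matrix in panel channel order."""
        p = len(self.channel_ids)
        idx = {c: k for k, c in enumerate(self.channel_ids)}
        corr = np.full((p, p), self.between_rho)
        for _, members in self.blocks:
            ii = [idx[c] for c in members]
            corr[np.ix_(ii, ii)] = self.within_rho
        np.fill_diagonal(corr, 1.0)
        return corr


@dataclass(frozen=True)
class ChannelMoments:
    """Per-channel marginal mean and SD, in % of total fatty acids."""

    means: tuple[float, ...] = tuple(c.mean for c in CHANNELS)
    sds: tuple[float, ...] = tuple(c.sd for c in CHANNELS)
    channel_ids: tuple[str, ...] = CHANNEL_IDS

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if len(means) != len(self.channel_ids) or len(sds) != len(self.channel_ids):
            raise ValueError("means/sds must match channel count")
        if not np.all(np.isfinite(means)):
            raise ValueError("means must be finite")
        if np.any(sds <= 0):
            bad = [self.channel_ids[i] for i in np.flatnonzero(sds <= 0)]
            raise ValueError(f"sd must be > 0 for every channel; offending: {bad}")


# Baseline hazard calibrated (deterministic quadrature, see
# `calibrate_baseline_scale`) so the null event fraction over 17 years of
# follow-up with U(50, 64) entry matches 4710/57053.
_DEFAULT_BASELINE_SCALE = 1.5580e-3


@dataclass(frozen=True)
class HazardSpec:
    """Gompertz-type AF hazard on the age scale.

    hazard(a | s) = baseline_scale * exp(age_slope * (a - 50)) * exp(beta' s)

    with ``s`` the subject's factor-score vector and ``beta`` the per-unit
    log hazard ratios. Censoring is administrative at
    ``entry_age + admin_followup_years``.
    """

    baseline_scale: float = _DEFAULT_BASELINE_SCALE  # events / person-year at age 50
    age_slope: float = 0.07                          # log-hazard increase per year
    log_hr_per_factor: tuple[float, ...] = (0.0, 0.0, 0.0, np.log(0.85), 0.0, 0.0, 0.0)
    admin_followup_years: float = 17.0
    entry_age_range: tuple[float, float] = (50.0, 64.0)

    def __post_init__(self) -> None:
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be > 0")
        if self.admin_followup_years <= 0:
            raise ValueError("admin_followup_years must be > 0")
        lo, hi = self.entry_age_range
        if not (18 < lo < hi < 100):
            raise ValueError("entry_age_range must lie within (18, 100)")


def calibrate_baseline_scale(
    target_fraction: float,
    age_slope: float = 0.07,
    admin_followup_years: float = 17.0,
    entry_age_range: tuple[float, float] = (50.0, 64.0),
) -> float:
    """Baseline scale whose null expected event fraction equals ``target_fraction``.

    Solves E_a0[1 - exp(-Lambda(a0, a0+T))] = target by bisection, where the
    expectation over uniform entry ages is evaluated by fixed-order
    Gauss-Legendre quadrature. Deterministic.
    """
    from scipy.optimize import brentq

    lo, hi = entry_age_range
    nodes, wts = np.polynomial.legendre.leggauss(64)
    a0 = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    wts = wts / wts.sum()
    k = age_slope

    def frac(b: float) -> float:
        if k == 0:
            lam = b * admin_followup_years * np.ones_like(a0)
        else:
            lam = (b / k) * (
                np.exp(k * (a0 + admin_followup_years - 50.0)) - np.exp(k * (a0 - 50.0))
            )
        return float(np.sum(wts * (1.0 - np.exp(-lam))))

    return float(brentq(lambda b: frac(b) - target_fraction, 1e-9, 1.0, xtol=1e-14))


def generate_panel(
    n: int,
    moments: ChannelMoments | None = None,
    blocks: BlockSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw an n x 32 fatty-acid panel (% of total fatty acids).

    Values are multivariate normal with the block correlation structure and
    the per-channel moments, floored at 0 (percentages cannot be negative).
    Compositional closure to 100% is deliberately not enforced: the analysis
    standardizes to correlations, which the closure constraint perturbs only
    marginally at these SDs.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    moments = moments or ChannelMoments()
    blocks = blocks or BlockSpec()
    if moments.channel_ids != blocks.channel_ids:
        raise ValueError("moments and blocks disagree on channel ids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = blocks.correlation_matrix()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(moments.channel_ids))) @ chol.T
    x = np.asarray(moments.means) + z * np.asarray(moments.sds)
    np.maximum(x, 0.0, out=x)
    return pd.DataFrame(x, columns=list(moments.channel_ids))


def true_block_scores(
    panel: pd.DataFrame,
    moments: ChannelMoments | None = None,
    blocks: BlockSpec | None = None,
) -> np.ndarray:
    """Generating pattern scores: normalized block sums of z-scored channels.

    Score k = (1/sqrt(|block k|)) * sum of z-values over block k, the ideal
    (population) version of what the treelet factors estimate. Used to wire
    pattern effects into the simulated hazard.
    """
    moments = moments or ChannelMoments()
    blocks = blocks or BlockSpec()
    z = (panel[list(moments.channel_ids)].to_numpy() - np.asarray(moments.means)) / (
        np.asarray(moments.sds)
    )
    idx = {c: k for k, c in enumerate(moments.channel_ids)}
    cols = []
    for _, members in blocks.blocks:
        ii = [idx[c] for c in members]
        cols.append(z[:, ii].sum(axis=1) / np.sqrt(len(ii)))
    return np.column_stack(cols)


def _draw_covariates(rng: np.random.Generator, sex: np.ndarray) -> pd.DataFrame:
    """Baseline covariates with sex-specific marginals, drawn independently."""
    n = len(sex)
    out = pd.DataFrame(index=np.arange(n))
    smoking = np.empty(n, dtype=object)
    school = np.empty(n, dtype=object)
    alcohol = np.empty(n)
    bmi = np.empty(n)
    waist = np.empty(n)
    flags = {f: np.zeros(n, dtype=np.int64) for f in COMORBIDITY_FLAGS}
    for label in ("male", "female"):
        m = sex == label
        k = int(m.sum())
        if k == 0:
            continue
        marg = _COVARIATE_MARGINALS[label]
        p_smk = np.asarray(marg["smoking"], dtype=float)
        smoking[m] = rng.choice(SMOKING_LEVELS, size=k, p=p_smk / p_smk.sum())
        p_sch = np.asarray(marg["school"], dtype=float)
        school[m] = rng.choice(SCHOOL_LEVELS, size=k, p=p_sch / p_sch.sum())
        mu, sig = marg["alcohol_mu_sigma"]
        alcohol[m] = rng.lognormal(mu, sig, size=k)
        bm, bs = marg["bmi_mean_sd"]
        bmi[m] = np.clip(rng.normal(bm, bs, size=k), 15.0, None)
        wm, ws = marg["waist_mean_sd"]
        waist[m] = np.clip(rng.normal(wm, ws, size=k), 50.0, None)
        for f, pf in marg["flags"].items():
            flags[f][m] = rng.random(k) < pf
    out["smoking"] = smoking
    out["school"] = school
    out["alcohol"] = alcohol
    out["bmi"] = bmi
    out["waist"] = waist
    for f in COMORBIDITY_FLAGS:
        out[f] = flags[f]
    return out


def generate_cohort(
    n: int,
    hazard: HazardSpec | None = None,
    scores: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    extra_log_hazard: np.ndarray | None = None,
    covariates: bool = True,
) -> pd.DataFrame:
    """Simulate survival outcomes and covariates for ``n`` subjects.

    Entry ages are uniform on ``hazard.entry_age_range``; event ages are
    drawn by exact inversion of the Gompertz cumulative hazard on the age
    scale (so delayed entry is respected by construction), and censoring is
    administrative at ``entry_age + admin_followup_years``.

    Parameters
    ----------
    scores
        n x m factor-score matrix multiplied against
        ``hazard.log_hr_per_factor`` (trailing factors without a
        coefficient, or coefficients without a score column, are ignored
        pairwise-consistently: the shorter of the two defines the product).
        None means no pattern effect.
    extra_log_hazard
        Optional additional per-subject log-hazard offset (e.g. planted
        quintile effects or covariate confounding built by the caller).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    hazard = hazard or HazardSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_entry, r_sex, r_event, r_cov = rng.spawn(4)

    lo, hi = hazard.entry_age_range
    entry_age = r_entry.uniform(lo, hi, size=n)
    sex = np.where(r_sex.random(n) < _P_MALE, "male", "female")

    eta = np.zeros(n)
    if scores is not None:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[0] != n:
            raise ValueError("scores row count must equal n")
        beta = np.asarray(hazard.log_hr_per_factor, dtype=float)
        m = min(scores.shape[1], len(beta))
        eta += scores[:, :m] @ beta[:m]
    if extra_log_hazard is not None:
        extra_log_hazard = np.asarray(extra_log_hazard, dtype=float)
        if extra_log_hazard.shape != (n,):
            raise ValueError("extra_log_hazard must have shape (n,)")
        eta += extra_log_hazard

    # Invert Lambda(entry -> a) = E ~ Exp(1) for the event age a.
    k = hazard.age_slope
    rate = hazard.baseline_scale * np.exp(eta)
    e = r_event.exponential(size=n)
    if k == 0:
        event_age = entry_age + e / rate
    else:
        event_age = 50.0 + np.log(np.exp(k * (entry_age - 50.0)) + k * e / rate) / k
    censor_age = entry_age + hazard.admin_followup_years
    event = (event_age <= censor_age).astype(np.int64)
    exit_age = np.minimum(event_age, censor_age)

    df = pd.DataFrame(
        {
            "subject_id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "entry_age": entry_age,
            "exit_age": exit_age,
            "event": event,
            "subcohort": np.zeros(n, dtype=np.int64),
            "weight": np.ones(n),
        }
    )
    if covariates:
        df = pd.concat([df, _draw_covariates(r_cov, sex)], axis=1)
    return df


def sample_case_cohort(
    cohort: pd.DataFrame,
    subcohort_size: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Case-cohort sample: all cases plus a simple random subcohort.

    Every case (inside or outside the subcohort) receives weight 1; subcohort
    non-cases receive (non-cases in cohort) / (non-cases in subcohort), so the
    weighted non-case count equals the full-cohort non-case count exactly.
    Non-cases outside the subcohort are dropped.
    """
    if subcohort_size <= 0 or subcohort_size > len(cohort):
        raise ValueError("subcohort_size must be in 1..len(cohort)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub_idx = rng.choice(len(cohort), size=subcohort_size, replace=False)
    in_sub = np.zeros(len(cohort), dtype=bool)
    in_sub[sub_idx] = True

    event = cohort["event"].to_numpy().astype(bool)
    n_noncases_cohort = int((~event).sum())
    n_noncases_sub = int((in_sub & ~event).sum())
    if n_noncases_sub == 0:
        raise ValueError(
            "subcohort contains no non-cases; the sampling weight is undefined"
        )

    keep = event | in_sub
    out = cohort.loc[keep].copy()
    out["subcohort"] = in_sub[keep].astype(np.int64)
    w = np.ones(keep.sum())
    noncase_keep = ~event[keep]
    w[noncase_keep] = n_noncases_cohort / n_noncases_sub
    out["weight"] = w
    return out.reset_index(drop=True)
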