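"""Sex-stratified case-cohort Cox analysis of factor-score quintiles.

Implements the exposure and adjustment conventions of the analysis:

* factor scores split into quintiles by sex, cut points estimated on the
  subcohort (the cohort-representative sample) and applied to everyone
  analyzed, including cases outside the subcohort;
* weighted Cox regression on the age scale with delayed entry; under the
  Barlow convention non-subcohort cases enter the risk set only just before
  their own event age (entry = event age - eps) with weight 1, while
  subcohort members are at risk from their entry age with their assigned
  weight (Prentice-style full-history entry for non-subcohort cases is a
  switch);
* a covariate ladder: Model 1 adjusts for baseline age in sex-specific
  quintiles (age is also the time axis; the indicator adjustment keeps the
  age at which exposure was measured comparable); Model 1A adds smoking and
  schooling as categoricals and alcohol, BMI and waist as restricted cubic
  splines with five knots; Model 2 adds seven comorbidity indicators;
* robust sandwich variance, Efron ties, quintile 1 as reference, and a
  trend test replacing the quintile indicators by the quintile index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cox import CoxResult, fit_cox
from .synthetic import COMORBIDITY_FLAGS, SCHOOL_LEVELS, SMOKING_LEVELS

__all__ = [
    "QuintileExposure",
    "assign_quintiles",
    "rcs_basis",
    "MODEL_LEVELS",
    "CoxFit",
    "fit_weighted_cox",
    "trend_test",
    "model_ladder",
    "CaseCohortCox",
]

MODEL_LEVELS = ("model1", "model1a", "model2")

_MODEL1A_COVARIATES = ("smoking", "school", "alcohol", "bmi", "waist")


@dataclass(frozen=True)
class QuintileExposure:
    """Per-subject quintile index with sex-specific reference cut points."""

    factor: str
    quintile: pd.Series           # int in 1..5, indexed like the analysis frame
    cut_points: dict[str, np.ndarray]  # sex -> 4 strictly increasing reals

    def indicator_frame(self) -> pd.DataFrame:
        """Dummy columns q2..q5 (quintile 1 = reference)."""
        out = pd.DataFrame(index=self.quintile.index)
        for q in range(2, 6):
            out[f"q{q}"] = (self.quintile == q).astype(float)
        return out


def _quintile_cuts(values: np.ndarray) -> np.ndarray:
    """20/40/60/80 percentiles by linear interpolation; must be distinct."""
    if len(np.unique(values)) < 5:
        raise ValueError(
            "fewer than 5 distinct reference scores; quintiles are undefined"
        )
    cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8], method="linear")
    if np.any(np.diff(cuts) <= 0):
        raise ValueError("quintile cut points are not strictly increasing")
    return cuts


def assign_quintiles(
    scores: pd.Series,
    sex: pd.Series,
    reference: pd.Series | np.ndarray,
    factor: str = "",
) -> QuintileExposure:
    """Quintile exposure from sex-specific subcohort cut points.

    ``reference`` is a boolean mask selecting the reference (subcohort)
    subjects. Cut points are the 20/40/60/80 linear-interpolation percentiles
    of the reference scores within each sex; every subject is then assigned
    by those cut points with boundary values going to the lower quintile.
    """
    reference = np.asarray(reference, dtype=bool)
    q = pd.Series(np.zeros(len(scores), dtype=np.int64), index=scores.index)
    cut_points: dict[str, np.ndarray] = {}
    for label in pd.unique(sex):
        m = (sex == label).to_numpy()
        ref_scores = scores.to_numpy()[m & reference]
        if len(ref_scores) == 0:
            raise ValueError(f"no reference subjects for sex {label!r}")
        cuts = _quintile_cuts(ref_scores)
        cut_points[str(label)] = cuts
        # score > cut pushes upward; equality stays below (left-closed bins)
        q.loc[m] = 1 + (scores.to_numpy()[m][:, None] > cuts[None, :]).sum(axis=1)
    return QuintileExposure(factor=factor, quintile=q, cut_points=cut_points)


def rcs_basis(
    x: np.ndarray,
    knots: np.ndarray | None = None,
    knot_percentiles: tuple[float, ...] = (5.0, 27.5, 50.0, 72.5, 95.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis (Harrell truncated-power form).

    With k knots t_1 < ... < t_k the basis has k - 1 columns: the linear term
    plus k - 2 nonlinear terms

        f_j(x) = [ (x - t_j)_+^3
                   - (x - t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
                   + (x - t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ]
                 / (t_k - t_1)^2

    which is linear beyond the boundary knots by construction. Returns
    (basis, knots). Default knots sit at the 5/27.5/50/72.5/95 percentiles.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if len(np.unique(x)) < 5:
            raise ValueError("need at least 5 distinct values to place 5 knots")
        knots = np.percentile(x, list(knot_percentiles))
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "knots are not distinct; use fewer knots or a wider sample"
        )
    k = len(knots)
    norm = (knots[-1] - knots[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.maximum(x - knots[j], 0.0) ** 3
            - np.maximum(x - knots[-2], 0.0) ** 3
            * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + np.maximum(x - knots[-1], 0.0) ** 3
            * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols), knots


def _categorical_dummies(
    values: pd.Series, levels: tuple[str, ...], prefix: str
) -> pd.DataFrame:
    unknown = set(values.unique()) - set(levels)
    if unknown:
        raise ValueError(f"{prefix}: unexpected level(s) {sorted(unknown)}")
    out = pd.DataFrame(index=values.index)
    for lev in levels[1:]:  # first level is the reference
        out[f"{prefix}[{lev}]"] = (values == lev).astype(float)
    return out


def build_design(
    records: pd.DataFrame,
    model: str,
    age_quintile_cuts: np.ndarray | None = None,
    spline_knots: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Adjustment-covariate design matrix for one model level.

    Baseline-age quintile cuts and spline knots are estimated on the given
    (sex-specific, complete-case) analysis sample unless supplied; the
    estimated values are returned for provenance/reuse.
    """
    if model not in MODEL_LEVELS:
        raise ValueError(f"model must be one of {MODEL_LEVELS}")
    cols: list[pd.DataFrame] = []
    meta: dict = {}

    age = records["entry_age"].to_numpy()
    if age_quintile_cuts is None:
        age_quintile_cuts = np.quantile(age, [0.2, 0.4, 0.6, 0.8], method="linear")
    meta["age_quintile_cuts"] = age_quintile_cuts
    age_q = 1 + (age[:, None] > age_quintile_cuts[None, :]).sum(axis=1)
    age_dum = pd.DataFrame(index=records.index)
    for q in range(2, 6):
        age_dum[f"age_q{q}"] = (age_q == q).astype(float)
    cols.append(age_dum)

    if model in ("model1a", "model2"):
        missing = [c for c in _MODEL1A_COVARIATES if c not in records.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        cols.append(_categorical_dummies(records["smoking"], SMOKING_LEVELS, "smoking"))
        cols.append(_categorical_dummies(records["school"], SCHOOL_LEVELS, "school"))
        meta["spline_knots"] = {}
        for var in ("alcohol", "bmi", "waist"):
            given = None if spline_knots is None else spline_knots.get(var)
            basis, knots = rcs_basis(records[var].to_numpy(), knots=given)
            meta["spline_knots"][var] = knots
            spl = pd.DataFrame(
                basis,
                index=records.index,
                columns=[f"{var}_rcs{j}" for j in range(basis.shape[1])],
            )
            cols.append(spl)
    if model == "model2":
        missing = [c for c in COMORBIDITY_FLAGS if c not in records.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        flags = records[list(COMORBIDITY_FLAGS)].astype(float)
        cols.append(flags)
    return pd.concat(cols, axis=1), meta


def complete_cases(records: pd.DataFrame, model: str = "model2") -> pd.DataFrame:
    """Drop records with missing values in any covariate the ladder uses."""
    needed = ["entry_age", "exit_age", "event", "weight", "sex"]
    if model in ("model1a", "model2"):
        needed += list(_MODEL1A_COVARIATES)
    if model == "model2":
        needed += list(COMORBIDITY_FLAGS)
    present = [c for c in needed if c in records.columns]
    return records.dropna(subset=present)


def barlow_entry(records: pd.DataFrame, eps: float = 1e-5) -> np.ndarray:
    """Risk-set entry ages under the Barlow case-cohort convention.

    Subcohort members are at risk from their entry age; cases outside the
    subcohort enter only on (event age - eps, event age].
    """
    entry = records["entry_age"].to_numpy(dtype=float).copy()
    outside_case = (
        (records["event"].to_numpy() == 1)
        & (records["subcohort"].to_numpy() == 0)
    )
    entry[outside_case] = records["exit_age"].to_numpy()[outside_case] - eps
    return entry


@dataclass(frozen=True)
class CoxFit:
    """Per-quintile hazard ratios from one weighted Cox fit."""

    factor: str
    sex: str
    model: str
    result: CoxResult
    hr: dict[int, float]               # quintile -> HR (quintile 1 == 1)
    ci: dict[int, tuple[float, float]]  # quintile -> robust 95% CI
    trend_p: float | None
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for q in range(1, 6):
            if q == 1:
                rows.append({"quintile": q, "hr": 1.0, "lo": np.nan, "hi": np.nan})
            else:
                lo, hi = self.ci[q]
                rows.append({"quintile": q, "hr": self.hr[q], "lo": lo, "hi": hi})
        out = pd.DataFrame(rows)
        out["factor"] = self.factor
        out["sex"] = self.sex
        out["model"] = self.model
        return out


def _exposure_design(
    records: pd.DataFrame, exposure: QuintileExposure, trend: bool
) -> pd.DataFrame:
    q = exposure.quintile.loc[records.index]
    if trend:
        return pd.DataFrame({"trend": q.astype(float)}, index=records.index)
    frame = QuintileExposure(exposure.factor, q, exposure.cut_points).indicator_frame()
    return frame


def fit_weighted_cox(
    records: pd.DataFrame,
    exposure: QuintileExposure,
    model: str = "model1a",
    weight_scheme: str = "barlow",
    eps: float = 1e-5,
    ties: str = "efron",
    trend: bool = False,
    age_quintile_cuts: np.ndarray | None = None,
    spline_knots: dict[str, np.ndarray] | None = None,
) -> CoxFit:
    """Weighted Cox fit of quintile exposure + adjustment ladder on one sex.

    ``records`` must already be restricted to one sex and to complete cases;
    the quintile exposure must cover every record. Variance is the robust
    sandwich; quintile 1 is the reference.
    """
    if weight_scheme not in ("barlow", "prentice"):
        raise ValueError("weight_scheme must be 'barlow' or 'prentice'")
    if records["weight"].isna().any():
        raise ValueError("weights must be present for every record")
    missing_q = exposure.quintile.reindex(records.index).isna()
    if missing_q.any():
        raise ValueError("exposure not assigned for every record")

    xq = _exposure_design(records, exposure, trend)
    xadj, _ = build_design(
        records, model, age_quintile_cuts=age_quintile_cuts, spline_knots=spline_knots
    )
    design = pd.concat([xq, xadj], axis=1)

    if not trend:
        q = exposure.quintile.loc[records.index]
        ev = records["event"].to_numpy() == 1
        for quint in range(1, 6):
            if not np.any(ev & (q == quint).to_numpy()):
                warnings.warn(
                    f"no events in quintile {quint}; its estimate is unstable "
                    "and the CI will be wide",
                    stacklevel=2,
                )

    if weight_scheme == "barlow":
        entry = barlow_entry(records, eps=eps)
    else:
        entry = records["entry_age"].to_numpy(dtype=float)
    result = fit_cox(
        design.to_numpy(),
        entry,
        records["exit_age"].to_numpy(dtype=float),
        records["event"].to_numpy(),
        weights=records["weight"].to_numpy(dtype=float),
        names=tuple(design.columns),
        ties=ties,
    )

    hr: dict[int, float] = {1: 1.0}
    ci: dict[int, tuple[float, float]] = {}
    if not trend:
        hrs = result.hazard_ratios()
        cis = result.confidence_intervals()
        for q in range(2, 6):
            j = list(design.columns).index(f"q{q}")
            hr[q] = float(hrs[j])
            ci[q] = (float(cis[j, 0]), float(cis[j, 1]))
    sexes = records["sex"].unique()
    return CoxFit(
        factor=exposure.factor,
        sex=str(sexes[0]) if len(sexes) == 1 else "mixed",
        model=model,
        result=result,
        hr=hr,
        ci=ci,
        trend_p=float(result.wald_p()[0]) if trend else None,
        n=len(records),
        n_events=int(records["event"].sum()),
    )


def trend_test(
    records: pd.DataFrame,
    exposure: QuintileExposure,
    model: str = "model1a",
    **kwargs,
) -> float:
    """Wald p-value for the quintile index (1..5) entered as one covariate."""
    fit = fit_weighted_cox(records, exposure, model, trend=True, **kwargs)
    return float(fit.trend_p)


def model_ladder(
    records: pd.DataFrame,
    exposure: QuintileExposure,
    models: tuple[str, ...] = MODEL_LEVELS,
    with_trend: bool = True,
    **kwargs,
) -> dict[str, CoxFit]:
    """Fit the Model 1 / 1A / 2 ladder on one fixed complete-case record set.

    Complete-case filtering uses the union of all requested models'
    covariates, so every model is fitted to exactly the same subjects.
    """
    strictest = "model2" if "model2" in models else (
        "model1a" if "model1a" in models else "model1"
    )
    kept = complete_cases(records, strictest)
    fits: dict[str, CoxFit] = {}
    for model in models:
        fit = fit_weighted_cox(kept, exposure, model, **kwargs)
        if with_trend:
            p = trend_test(kept, exposure, model, **kwargs)
            fit = CoxFit(
                factor=fit.factor, sex=fit.sex, model=fit.model, result=fit.result,
                hr=fit.hr, ci=fit.ci, trend_p=p, n=fit.n, n_events=fit.n_events,
            )
        fits[model] = fit
    return fits


class CaseCohortCox(BaseEstimator):
    """Sex-stratified case-cohort Cox ladder as a fit-shaped estimator.

    Parameters mirror :func:`fit_weighted_cox`; ``fit`` takes the analysis
    records (one sex) and a factor-score Series, derives subcohort quintile
    cut points, and fits the requested model levels.

    Attributes (after ``fit``)
    --------------------------
    exposure_ : QuintileExposure
    fits_ : dict model level -> CoxFit (with trend p filled in)
    """

    def __init__(
        self,
        models: tuple[str, ...] = MODEL_LEVELS,
        weight_scheme: str = "barlow",
        eps: float = 1e-5,
        ties: str = "efron",
    ):
        self.models = models
        self.weight_scheme = weight_scheme
        self.eps = eps
        self.ties = ties

    def fit(self, records: pd.DataFrame, scores: pd.Series, factor: str = ""):
        exposure = assign_quintiles(
            scores.loc[records.index],
            records["sex"],
            records["subcohort"].to_numpy() == 1,
            factor=factor,
        )
        self.exposure_ = exposure
        self.fits_ = model_ladder(
            records,
            exposure,
            models=self.models,
            weight_scheme=self.weight_scheme,
            eps=self.eps,
            ties=self.ties,
        )
        return self

    def summary(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "fits_")
        return pd.concat([f.summary() for f in self.fits_.values()], ignore_index=True)
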