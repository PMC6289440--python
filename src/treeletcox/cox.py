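"""Weighted Cox partial likelihood with delayed entry and robust variance.

Newton solver for the weighted Cox proportional-hazards model on a general
counting-process layout: each subject is at risk on (entry, exit] with a
nonnegative weight, so left truncation (age as the analysis time scale with
delayed entry) and case-cohort weighting are both expressed directly.

Risk sets are never materialized: for any time t the at-risk set
{i : entry_i < t <= exit_i} equals {exit_i >= t} minus {entry_i >= t}
(since entry < exit), so all risk sums are differences of suffix cumulative
sums over two sorted orders, giving O(n log n + n p + K p^2) per Newton step
(K = number of distinct event times). Ties are handled by the Efron
approximation (Breslow optionally); tie groups are corrected explicitly,
which costs nothing when event times are continuous.

The robust (sandwich) covariance aggregates per-subject weighted score
residuals, the standard estimator for weighted partial likelihoods such as
the Barlow case-cohort fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxResult", "ConvergenceError", "fit_cox"]


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; log-likelihood trace: {trace}")
        self.trace = trace


@dataclass(frozen=True)
class CoxResult:
    """Fitted weighted Cox model."""

    names: tuple[str, ...]
    coef: np.ndarray
    cov_naive: np.ndarray
    cov_robust: np.ndarray
    loglik: float
    n_iter: int
    n: int
    n_events: int

    @property
    def se_naive(self) -> np.ndarray:
        # aliased covariates have no information; their SE is NaN
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_naive))

    @property
    def se_robust(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_robust))

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def confidence_intervals(self, z: float = 1.959963984540054) -> np.ndarray:
        """exp(coef -/+ z * robust SE), rows = covariates, cols = (lo, hi)."""
        se = self.se_robust
        return np.exp(np.column_stack([self.coef - z * se, self.coef + z * se]))

    def wald_p(self) -> np.ndarray:
        """Two-sided Wald p-values from the robust SE."""
        from scipy.stats import norm

        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.coef / self.se_robust
        return 2.0 * norm.sf(np.abs(z))


class _RiskSetIndex:
    """Precomputed sort orders and event-time bookkeeping (beta-independent)."""

    def __init__(self, entry, exit, event, weights):
        self.n = len(exit)
        self.exit_order = np.argsort(exit, kind="stable")
        self.entry_order = np.argsort(entry, kind="stable")
        self.exit_sorted = exit[self.exit_order]
        self.entry_sorted = entry[self.entry_order]

        ev = event.astype(bool)
        self.event_idx = np.flatnonzero(ev)
        t_event = exit[self.event_idx]
        order = np.argsort(t_event, kind="stable")
        self.event_idx = self.event_idx[order]
        t_sorted = t_event[order]
        self.t_unique, self.group_start, self.group_count = np.unique(
            t_sorted, return_index=True, return_counts=True
        )
        self.group_of_event = np.repeat(
            np.arange(len(self.t_unique)), self.group_count
        )
        # weighted event count per distinct time
        self.dw = np.add.reduceat(weights[self.event_idx], self.group_start)
        # positions of each distinct event time in the two sorted arrays
        self.pos_exit = np.searchsorted(self.exit_sorted, self.t_unique, side="left")
        self.pos_entry = np.searchsorted(self.entry_sorted, self.t_unique, side="left")
        # per subject: how many distinct event times are <= exit / <= entry
        self.cnt_exit = np.searchsorted(self.t_unique, exit, side="right")
        self.cnt_entry = np.searchsorted(self.t_unique, entry, side="right")
        self.tied_groups = np.flatnonzero(self.group_count > 1)


def _suffix_sums(values_sorted: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """sum(values_sorted[pos:]) for each pos, via a reversed cumulative sum."""
    csum = np.concatenate(
        [np.cumsum(values_sorted[::-1], axis=0)[::-1],
         np.zeros((1,) + values_sorted.shape[1:])]
    )
    return csum[pos]


def _efron_terms(idx, X, r, entry, exit, R0, R1, k):
    """Risk sums restricted to tied group k (explicit, rare path)."""
    t = idx.t_unique[k]
    at_risk = (entry < t) & (exit >= t)
    events = idx.event_idx[idx.group_of_event == k]
    d = idx.group_count[k]
    D0 = r[events].sum()
    D1 = r[events] @ X[events]
    Xr = X[at_risk]
    rr = r[at_risk]
    R2 = Xr.T @ (rr[:, None] * Xr)
    D2 = X[events].T @ (r[events, None] * X[events])
    return d, D0, D1, R2, D2


def fit_cox(
    X: np.ndarray,
    entry: np.ndarray,
    exit: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    names: tuple[str, ...] | None = None,
    ties: str = "efron",
    max_iter: int = 60,
    tol: float = 1e-12,
) -> CoxResult:
    """Fit the weighted Cox model by Newton-Raphson with step halving.

    Parameters
    ----------
    X : (n, p) covariate matrix (columns are internally centered).
    entry, exit : at-risk interval (entry < exit), e.g. ages.
    event : 0/1 indicator that `exit` is an event time.
    weights : nonnegative subject weights; None = unweighted.
    ties : "efron" (default) or "breslow".
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, p = X.shape
    entry = np.asarray(entry, dtype=float)
    exit = np.asarray(exit, dtype=float)
    event = np.asarray(event)
    if np.any(exit <= entry):
        raise ValueError("every subject needs exit > entry")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))

    center = X.mean(axis=0)
    Xc = X - center
    idx = _RiskSetIndex(entry, exit, event, w)
    if len(idx.event_idx) == 0:
        raise ValueError("no events in the data")
    ev = idx.event_idx
    # per-group weighted sums of event covariates (for the gradient)
    wx_events = np.add.reduceat(w[ev, None] * Xc[ev], idx.group_start, axis=0)
    sum_wx_events = wx_events.sum(axis=0)

    def evaluate(beta: np.ndarray, need_hessian: bool):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _evaluate(beta, need_hessian)

    def _evaluate(beta: np.ndarray, need_hessian: bool):
        eta = Xc @ beta
        r = w * np.exp(eta)
        rX = r[:, None] * Xc
        R0 = (
            _suffix_sums(r[idx.exit_order], idx.pos_exit)
            - _suffix_sums(r[idx.entry_order], idx.pos_entry)
        )
        R1 = (
            _suffix_sums(rX[idx.exit_order], idx.pos_exit)
            - _suffix_sums(rX[idx.entry_order], idx.pos_entry)
        )
        if not np.all(np.isfinite(R0)) or np.any(R0 <= 0):
            return -np.inf, None, None, None
        dw = idx.dw
        ll = float(w[ev] @ eta[ev] - dw @ np.log(R0))
        grad = hess = None
        # cumulative hazard increments for the Hessian/residual shortcuts
        dLam = dw / R0
        G0 = np.concatenate([[0.0], np.cumsum(dLam)])
        g0 = G0[idx.cnt_exit] - G0[idx.cnt_entry]
        grad = sum_wx_events - (r * g0) @ Xc
        if need_hessian:
            M = R1 / R0[:, None]
            hess = Xc.T @ ((r * g0)[:, None] * Xc) - (M * dw[:, None]).T @ M
        if ties == "efron":
            for k in idx.tied_groups:
                d, D0, D1, R2, D2 = _efron_terms(
                    idx, Xc, r, entry, exit, R0, R1, k
                )
                frac = np.arange(d) / d
                phi = R0[k] - frac * D0
                if np.any(phi <= 0):
                    return -np.inf, None, None, None
                S1 = R1[k][None, :] - frac[:, None] * D1[None, :]
                wk = dw[k] / d
                ll += float(dw[k] * np.log(R0[k]) - wk * np.log(phi).sum())
                grad += dw[k] * R1[k] / R0[k] - wk * (S1 / phi[:, None]).sum(axis=0)
                if need_hessian:
                    Mk = R1[k] / R0[k]
                    hess -= dw[k] * (R2 / R0[k] - np.outer(Mk, Mk))
                    for l in range(d):
                        S2l = R2 - frac[l] * D2
                        ml = S1[l] / phi[l]
                        hess += wk * (S2l / phi[l] - np.outer(ml, ml))
        return ll, grad, hess, (r, R0, R1, g0, G0, dLam)

    beta = np.zeros(p)
    ll, grad, hess, aux = evaluate(beta, True)
    if not np.isfinite(ll):
        raise ConvergenceError("invalid likelihood at the starting point", [])
    trace = [ll]
    n_iter = 0
    scale = 1.0 + abs(ll)
    for n_iter in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # Newton decrement: expected gain of the next step, in loglik units.
        decrement = 0.5 * float(grad @ delta)
        if decrement <= tol * scale:
            break
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * delta
            ll_new, grad_new, hess_new, aux_new = evaluate(beta_new, True)
            # accept roundoff-level non-improvement near the optimum
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * scale:
                break
            step *= 0.5
        else:
            raise ConvergenceError("step halving failed", trace)
        improved = ll_new - ll
        beta, ll, grad, hess, aux = beta_new, ll_new, grad_new, hess_new, aux_new
        trace.append(ll)
        if abs(improved) < tol * scale:
            break
    else:
        raise ConvergenceError("maximum iterations reached", trace)

    try:
        cov_naive = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn(
            "information matrix is singular (aliased or event-free covariate "
            "levels); using a pseudo-inverse, affected SEs are unreliable",
            stacklevel=2,
        )
        cov_naive = np.linalg.pinv(hess)
    resid = _score_residuals(Xc, entry, exit, w, idx, aux)
    meat = resid.T @ resid
    cov_robust = cov_naive @ meat @ cov_naive
    return CoxResult(
        names=names,
        coef=beta,
        cov_naive=cov_naive,
        cov_robust=cov_robust,
        loglik=ll,
        n_iter=n_iter,
        n=n,
        n_events=int(len(ev)),
    )


def _score_residuals(Xc, entry, exit, w, idx, aux):
    """Per-subject weighted score residuals U_i (Breslow form).

    U_i = delta_i w_i (x_i - xbar(T_i))
          - r_i [ x_i (G0(exit_i) - G0(entry_i)) - (G1(exit_i) - G1(entry_i)) ]

    where xbar(t) = R1/R0 at t, G0 is the cumulative weighted hazard and
    G1 its covariate-weighted analogue. Exact without ties; with the rare
    tied group it is the standard Breslow-form approximation.
    """
    r, R0, R1, g0, G0, dLam = aux
    n, p = Xc.shape
    U = -(r * g0)[:, None] * Xc
    G1 = np.concatenate(
        [np.zeros((1, p)), np.cumsum(dLam[:, None] * R1 / R0[:, None], axis=0)]
    )
    U += r[:, None] * (G1[idx.cnt_exit] - G1[idx.cnt_entry])
    ev = idx.event_idx
    xbar = (R1 / R0[:, None])[idx.group_of_event]
    U[ev] += w[ev, None] * (Xc[ev] - xbar)
    return U
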