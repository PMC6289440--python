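"""Treelet transform: hierarchical Jacobi rotations on a correlation matrix.

The treelet transform builds, from the sample correlation matrix of p
standardized variables, a sequence of p-1 pairwise Givens (Jacobi) rotations.
At each level the two most similar *active* coordinates are rotated so their
covariance becomes exactly zero; the rotated coordinate with the larger
variance stays active (the "sum" variable), the other is frozen as a
"difference" (detail) variable. The result is simultaneously a dendrogram
over the variables and, at every level, an orthonormal basis whose vectors
are sparse by construction: a basis vector is supported only on the
variables merged beneath it.

Factors are obtained by cutting the hierarchy at a level L and retaining the
m basis vectors with the largest coordinate variances; subject scores are
projections of the z-scored profile onto those loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "jacobi_angle",
    "Merge",
    "TreeletModel",
    "FactorSet",
    "StandardizationParams",
    "fit_treelet",
    "cut_basis",
    "standardize",
    "score_subjects",
    "TreeletTransform",
]


def jacobi_angle(c_ii: float, c_jj: float, c_ij: float) -> float:
    """Rotation angle zeroing the (i, j) covariance entry.

    Returns the quarter-angle branch theta in [-pi/4, pi/4] solving
    tan(2 theta) = 2 c_ij / (c_ii - c_jj); for c_ii == c_jj the limit
    sign(c_ij) * pi/4 is used.
    """
    delta = c_ii - c_jj
    if c_ij == 0.0:
        return 0.0
    if delta == 0.0:
        return float(np.sign(c_ij) * np.pi / 4)
    return float(0.5 * np.arctan(2.0 * c_ij / delta))


@dataclass(frozen=True)
class Merge:
    """One rotation in the treelet hierarchy (levels are 1-based)."""

    level: int
    i: int          # first coordinate of the rotated pair (i < j)
    j: int
    theta: float    # rotation angle
    sum_index: int  # coordinate that stays active afterwards
    diff_index: int


@dataclass(frozen=True)
class StandardizationParams:
    """Per-channel mean/SD estimated on a designated reference sample."""

    channel_ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            bad = [self.channel_ids[i] for i in np.flatnonzero(self.sds <= 0)]
            raise ValueError(f"zero-variance channel(s): {bad}")

    @classmethod
    def fit(cls, panel: pd.DataFrame) -> "StandardizationParams":
        x = panel.to_numpy(dtype=float)
        return cls(
            channel_ids=tuple(panel.columns),
            means=x.mean(axis=0),
            sds=x.std(axis=0, ddof=1),
        )


def standardize(panel: pd.DataFrame, params: StandardizationParams) -> np.ndarray:
    """z-score ``panel`` with reference-sample moments, columns in param order."""
    missing = [c for c in params.channel_ids if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing channels: {missing}")
    x = panel[list(params.channel_ids)].to_numpy(dtype=float)
    return (x - params.means) / params.sds


@dataclass(frozen=True)
class TreeletModel:
    """Fitted treelet hierarchy.

    ``basis_by_level[L]`` (L = 0..p-1) is the p x p orthonormal basis after L
    rotations (columns are basis vectors in original-variable space);
    ``variances_by_level[L]`` holds the p basis-coordinate variances. Level 0
    is the identity basis on the correlation matrix.
    """

    channel_ids: tuple[str, ...]
    merges: tuple[Merge, ...]
    basis_by_level: tuple[np.ndarray, ...]
    variances_by_level: tuple[np.ndarray, ...]

    @property
    def p(self) -> int:
        return len(self.channel_ids)

    def basis(self, level: int) -> np.ndarray:
        return self.basis_by_level[level]

    def variances(self, level: int) -> np.ndarray:
        return self.variances_by_level[level]


def _similarity(cov: np.ndarray, active: np.ndarray, signed: bool) -> np.ndarray:
    """Pairwise similarity of active coordinates; inactive rows/cols -> -inf."""
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    sim = corr if signed else np.abs(corr)
    sim = sim.copy()
    sim[~active, :] = -np.inf
    sim[:, ~active] = -np.inf
    np.fill_diagonal(sim, -np.inf)
    return sim


def fit_treelet(
    z: np.ndarray,
    channel_ids: tuple[str, ...] | None = None,
    signed_similarity: bool = False,
) -> TreeletModel:
    """Fit the full treelet hierarchy on a standardized n x p matrix.

    Pair selection maximizes the absolute current correlation between active
    coordinates (signed correlation optionally); ties break lexicographically
    on (i, j). Deterministic given the input.
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if p < 2:
        raise ValueError("need at least 2 channels")
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if channel_ids is None:
        channel_ids = tuple(f"x{k}" for k in range(p))
    sds = z.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [channel_ids[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance channel(s): {bad}")

    cov = np.corrcoef(z, rowvar=False)  # correlation of the (already z-scored) input
    basis = np.eye(p)
    active = np.ones(p, dtype=bool)
    merges: list[Merge] = []
    bases = [basis.copy()]
    variances = [np.diag(cov).copy()]

    for level in range(1, p):
        sim = _similarity(cov, active, signed_similarity)
        flat = int(np.argmax(sim))  # row-major argmax = lexicographic tie-break
        i, j = divmod(flat, p)
        if i > j:
            i, j = j, i
        theta = jacobi_angle(cov[i, i], cov[j, j], cov[i, j])
        co, si = np.cos(theta), np.sin(theta)

        # Rotate covariance rows/cols and the basis columns: the new i is the
        # sum-like coordinate co*e_i + si*e_j, the new j is -si*e_i + co*e_j.
        for mat in (cov,):
            ri, rj = mat[i, :].copy(), mat[j, :].copy()
            mat[i, :] = co * ri + si * rj
            mat[j, :] = -si * ri + co * rj
            ci, cj = mat[:, i].copy(), mat[:, j].copy()
            mat[:, i] = co * ci + si * cj
            mat[:, j] = -si * ci + co * cj
        cov[i, j] = cov[j, i] = 0.0  # exact by construction of theta
        bi, bj = basis[:, i].copy(), basis[:, j].copy()
        basis[:, i] = co * bi + si * bj
        basis[:, j] = -si * bi + co * bj

        if cov[i, i] > cov[j, j] or (cov[i, i] == cov[j, j] and i < j):
            sum_idx, diff_idx = i, j
        else:
            sum_idx, diff_idx = j, i
        active[diff_idx] = False
        merges.append(Merge(level, i, j, theta, sum_idx, diff_idx))
        bases.append(basis.copy())
        variances.append(np.diag(cov).copy())

    return TreeletModel(
        channel_ids=channel_ids,
        merges=tuple(merges),
        basis_by_level=tuple(bases),
        variances_by_level=tuple(variances),
    )


@dataclass(frozen=True)
class FactorSet:
    """Retained sparse factors at a fixed cut level.

    ``loadings`` is p x m (columns unit-norm, sign-normalized so the largest-
    magnitude entry is positive); ``explained_variance_pct`` entries are
    100 * variance / p for the m largest coordinate variances at the cut.
    """

    channel_ids: tuple[str, ...]
    cut_level: int
    loadings: np.ndarray
    explained_variance_pct: np.ndarray

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_pct(self) -> float:
        return float(self.explained_variance_pct.sum())

    def supports(self, tol: float = 1e-10) -> list[tuple[int, ...]]:
        """Indices of structurally nonzero entries of each loading."""
        return [
            tuple(np.flatnonzero(np.abs(self.loadings[:, k]) > tol))
            for k in range(self.m)
        ]


def cut_basis(model: TreeletModel, cut_level: int, m: int) -> FactorSet:
    """Retain the ``m`` largest-variance basis vectors at ``cut_level``.

    Ties in variance break toward the lower column index; each loading is
    flipped so its largest-magnitude entry is positive.
    """
    p = model.p
    if not 1 <= cut_level <= p - 1:
        raise ValueError(f"cut_level must be in 1..{p - 1}")
    if not 1 <= m <= p:
        raise ValueError(f"m must be in 1..{p}")
    variances = model.variances(cut_level)
    order = np.argsort(-variances, kind="stable")[:m]
    loadings = model.basis(cut_level)[:, order].copy()
    for k in range(m):
        lead = np.argmax(np.abs(loadings[:, k]))
        if loadings[lead, k] < 0:
            loadings[:, k] = -loadings[:, k]
    return FactorSet(
        channel_ids=model.channel_ids,
        cut_level=cut_level,
        loadings=loadings,
        explained_variance_pct=100.0 * variances[order] / p,
    )


def score_subjects(
    panel: pd.DataFrame,
    params: StandardizationParams,
    factors: FactorSet,
) -> pd.DataFrame:
    """Project z-scored profiles onto the retained loadings.

    Standardization always uses the reference-sample (subcohort) moments, so
    subjects outside the reference sample are scored on the same scale.
    """
    z = standardize(panel, params)
    scores = z @ factors.loadings
    return pd.DataFrame(
        scores,
        index=panel.index,
        columns=[f"TT{k + 1}" for k in range(factors.m)],
    )


class TreeletTransform(TransformerMixin, BaseEstimator):
    """Treelet-transform factor extraction as a scikit-learn transformer.

    Parameters
    ----------
    cut_level : int or None
        Dendrogram level at which to cut. None means p - 1 (the full
        hierarchy).
    n_factors : int or None
        Number of retained factors m. None means all p basis vectors.
    signed_similarity : bool
        Use signed instead of absolute correlation for pair selection.

    Attributes (after ``fit``)
    --------------------------
    params_ : StandardizationParams fitted on the training panel
    model_ : TreeletModel with the merge schedule and per-level bases
    factors_ : FactorSet at (cut_level, n_factors)
    loadings_ : (p, m) sparse loading matrix
    explained_variance_pct_ : per-factor explained variance, % of total
    """

    def __init__(
        self,
        cut_level: int | None = None,
        n_factors: int | None = None,
        signed_similarity: bool = False,
    ):
        self.cut_level = cut_level
        self.n_factors = n_factors
        self.signed_similarity = signed_similarity

    def fit(self, X, y=None):
        panel = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if panel.isna().any().any():
            raise ValueError("panel contains missing values; filter subjects first")
        self.params_ = StandardizationParams.fit(panel)
        z = standardize(panel, self.params_)
        self.model_ = fit_treelet(
            z, tuple(panel.columns.astype(str)), self.signed_similarity
        )
        p = self.model_.p
        cut = self.cut_level if self.cut_level is not None else p - 1
        m = self.n_factors if self.n_factors is not None else p
        self.factors_ = cut_basis(self.model_, cut, m)
        self.loadings_ = self.factors_.loadings
        self.explained_variance_pct_ = self.factors_.explained_variance_pct
        self.cumulative_explained_pct_ = self.factors_.cumulative_pct
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "factors_")
        panel = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
            np.asarray(X), columns=list(self.params_.channel_ids)
        )
        return score_subjects(panel, self.params_, self.factors_).to_numpy()

    def get_feature_names_out(self, input_features=None):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "factors_")
        return np.asarray([f"TT{k + 1}" for k in range(self.factors_.m)], dtype=object)
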