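"""Cross-validated selection of the treelet cut level and factor count.

The held-out score of a candidate (cut level L, factor count m) is the
fraction of held-out total variance captured by the m retained loadings:

    score(L, m) = (1/p) * sum_k Var_test(w_k' z)

with z standardized by the training-fold moments and w_k the training-fold
loadings. Scores are averaged over K folds.

Selection is two-stage:

* m: factors are added while the marginal held-out gain of the next factor
  exceeds ``(1 + gain_margin) / p``. A single standardized channel carries
  held-out variance 1/p, so the rule reads "keep a factor only while it
  explains materially more held-out variance than a raw channel would";
  ``gain_margin`` defaults to 0.1.
* cut level: the smallest level whose score (at the chosen m) lies within a
  relative plateau tolerance ``tau`` (default 1%) of the maximum over
  levels — as much variance as possible at as low a cut as possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treelet import StandardizationParams, cut_basis, fit_treelet, standardize

__all__ = ["CVResult", "cross_validate"]


@dataclass(frozen=True)
class CVResult:
    """Cross-validation grid and the selected (cut level, m)."""

    cut_levels: tuple[int, ...]
    m_values: tuple[int, ...]
    scores: np.ndarray  # (len(cut_levels), len(m_values)) fold-averaged
    folds: int
    chosen_cut_level: int
    chosen_m: int

    def score_curve(self, m: int) -> pd.Series:
        """Score vs cut level at a fixed m, for plotting."""
        col = self.m_values.index(m)
        return pd.Series(self.scores[:, col], index=list(self.cut_levels), name=f"m={m}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(list(self.cut_levels), name="cut_level"),
            columns=[f"m={m}" for m in self.m_values],
        )


def _fold_scores(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cut_levels: tuple[int, ...],
    m_values: tuple[int, ...],
    signed_similarity: bool,
) -> np.ndarray:
    params = StandardizationParams.fit(train)
    model = fit_treelet(
        standardize(train, params), tuple(train.columns.astype(str)), signed_similarity
    )
    z_test = standardize(test, params)
    p = model.p
    out = np.empty((len(cut_levels), len(m_values)))
    for a, level in enumerate(cut_levels):
        variances = model.variances(level)
        order = np.argsort(-variances, kind="stable")
        proj = z_test @ model.basis(level)[:, order]  # test coords, variance-ranked
        v = proj.var(axis=0, ddof=1)
        cum = np.concatenate([[0.0], np.cumsum(v)])
        for b, m in enumerate(m_values):
            out[a, b] = cum[min(m, p)] / p
    return out


def cross_validate(
    panel: pd.DataFrame,
    K: int = 5,
    cut_levels: list[int] | None = None,
    m_values: list[int] | None = None,
    seed: int | np.random.Generator = 0,
    tau: float = 0.01,
    gain_margin: float = 0.1,
    signed_similarity: bool = False,
) -> CVResult:
    """K-fold cross-validation over a (cut level, m) grid.

    Folds are random splits of subjects; each fold's treelet and
    standardization are fitted on the training subjects only. Folds with a
    zero-variance training channel are skipped with a warning; if every fold
    is skipped an error is raised.
    """
    n, p = panel.shape
    if K < 2:
        raise ValueError("K must be >= 2")
    if n < 2 * K:
        raise ValueError("need at least 2 subjects per fold")
    cut_levels = tuple(cut_levels) if cut_levels else tuple(range(1, p))
    m_values = tuple(m_values) if m_values else tuple(range(1, min(p, 12) + 1))
    if any(not 1 <= l <= p - 1 for l in cut_levels):
        raise ValueError("cut levels must lie in 1..p-1")
    if any(not 1 <= m <= p for m in m_values):
        raise ValueError("m values must lie in 1..p")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, K)

    acc = np.zeros((len(cut_levels), len(m_values)))
    used = 0
    for k in range(K):
        test_idx = fold_ids[k]
        train_idx = np.concatenate([fold_ids[j] for j in range(K) if j != k])
        try:
            acc += _fold_scores(
                panel.iloc[train_idx],
                panel.iloc[test_idx],
                cut_levels,
                m_values,
                signed_similarity,
            )
            used += 1
        except ValueError as err:
            if "zero-variance" in str(err):
                warnings.warn(f"fold {k} skipped: {err}", stacklevel=2)
            else:
                raise
    if used == 0:
        raise ValueError("all cross-validation folds were skipped")
    scores = acc / used

    # m from the best-over-levels curve; gain of one raw channel is 1/p.
    best_over_levels = scores.max(axis=0)
    chosen_m = m_values[-1]
    for k in range(len(m_values) - 1):
        step = m_values[k + 1] - m_values[k]
        gain = (best_over_levels[k + 1] - best_over_levels[k]) / step
        if gain < (1.0 + gain_margin) / p:
            chosen_m = m_values[k]
            break

    # cut level: smallest level on the plateau of the chosen-m curve.
    col = m_values.index(chosen_m)
    curve = scores[:, col]
    cutoff = curve.max() * (1.0 - tau)
    chosen_cut = cut_levels[int(np.argmax(curve >= cutoff))]

    return CVResult(
        cut_levels=cut_levels,
        m_values=m_values,
        scores=scores,
        folds=used,
        chosen_cut_level=chosen_cut,
        chosen_m=chosen_m,
    )
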