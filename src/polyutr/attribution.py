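"""Shapley-value attribution for the abundance model.

The value function follows the interventional (marginal-replacement)
convention: v(S) is the mean model output over background rows with the
features in coalition S replaced by the explained sample's values.  An
exact enumerator covers small feature counts; a seeded permutation-
sampling estimator with Monte-Carlo standard errors scales to the full
15-feature model.  Summaries mirror the usual model-explanation plots:
mean-|phi| feature ranking and per-feature dependence (value vs phi, rank
correlation, and windowed contrasts such as mean phi for tract distances
inside 10..30 nt vs outside).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MAX_EXACT_FEATURES = 20


@dataclass
class ShapMatrix:
    """Per-sample, per-feature attributions plus the background base value."""

    phi: np.ndarray            # (n, m)
    base_value: float
    X: np.ndarray              # (n, m) explained feature values
    feature_names: tuple[str, ...]
    standard_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.phi.shape != self.X.shape:
            raise ValueError("phi and X shapes differ")
        if self.phi.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))


def exact_shapley(
    model_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values of one sample by full coalition enumeration.

    phi_j = sum over coalitions S not containing j of
    |S|!(m-|S|-1)!/m! * [v(S + {j}) - v(S)], with v the interventional
    value function.  Feasible for m <= 20.
    """
    x = np.asarray(x, dtype=float).ravel()
    background = _as_matrix(background)
    m = x.size
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{m} features need 2^{m} coalitions; use sampled_shapley instead"
        )
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    n_masks = 1 << m
    b = background.shape[0]
    # evaluate v(S) for every coalition in one batched model call
    hybrids = np.empty((n_masks, b, m))
    member = np.zeros((n_masks, m), dtype=bool)
    for mask in range(n_masks):
        for j in range(m):
            member[mask, j] = bool(mask >> j & 1)
        hybrids[mask] = np.where(member[mask], x, background)
    v = np.asarray(
        model_fn(hybrids.reshape(n_masks * b, m)), dtype=float
    ).reshape(n_masks, b).mean(axis=1)

    fact_w = np.array(
        [1.0 / (comb(m - 1, s) * m) for s in range(m)]
    )  # |S|!(m-|S|-1)!/m! grouped by |S|
    sizes = member.sum(axis=1)
    phi = np.zeros(m)
    for mask in range(n_masks):
        s = sizes[mask]
        for j in range(m):
            if not member[mask, j]:
                phi[j] += fact_w[s] * (v[mask | (1 << j)] - v[mask])
    return phi, float(v[0])


def sampled_shapley(
    model_fn: Callable[[np.ndarray], np.ndarray],
    X,
    background,
    n_permutations: int = 100,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> ShapMatrix:
    """Permutation-sampling Shapley estimates for a batch of samples.

    For each sample, features are inserted in ``n_permutations`` random
    orders; the telescoping marginal gains average (over permutations and
    background rows) to the Shapley values.  Per-feature Monte-Carlo
    standard errors come from the spread across permutations.  Seeded and
    fully deterministic.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    X = _as_matrix(X)
    background = _as_matrix(background)
    n, m = X.shape
    b = background.shape[0]
    rng = np.random.default_rng(seed)
    base_value = float(np.mean(model_fn(background)))

    phi = np.empty((n, m))
    se = np.empty((n, m))
    for i in range(n):
        perms = np.array([rng.permutation(m) for _ in range(n_permutations)])
        # state[p, r, :]: background row r with the first t features of
        # permutation p switched to x; evaluated after each insertion
        state = np.broadcast_to(background, (n_permutations, b, m)).copy()
        prev = np.broadcast_to(
            np.asarray(model_fn(background), dtype=float), (n_permutations, b)
        ).copy()
        contrib = np.empty((n_permutations, m))
        for t in range(m):
            cols = perms[:, t]
            state[np.arange(n_permutations), :, cols] = X[i, cols][:, None]
            cur = np.asarray(
                model_fn(state.reshape(n_permutations * b, m)), dtype=float
            ).reshape(n_permutations, b)
            gain = (cur - prev).mean(axis=1)
            contrib[np.arange(n_permutations), cols] = gain
            prev = cur
        phi[i] = contrib.mean(axis=0)
        se[i] = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)

    names = tuple(feature_names) if feature_names else tuple(
        f"x{j}" for j in range(m)
    )
    return ShapMatrix(
        phi=phi, base_value=base_value, X=X, feature_names=names, standard_errors=se
    )


def mean_abs_ranking(shap: ShapMatrix) -> pd.DataFrame:
    """Features ordered by mean |phi| (descending, ties in canonical order)."""
    means = np.abs(shap.phi).mean(axis=0)
    df = pd.DataFrame(
        {"feature": list(shap.feature_names), "mean_abs_phi": means}
    )
    df = df.sort_values("mean_abs_phi", ascending=False, kind="stable").reset_index(
        drop=True
    )
    df.index = df.index + 1
    df.index.name = "rank"
    return df


@dataclass
class DependenceSummary:
    feature: str
    values: np.ndarray
    phi: np.ndarray
    spearman_rho: float
    window: tuple[float, float] | None = None
    mean_phi_in_window: float | None = None
    mean_phi_outside: float | None = None


def dependence(
    shap: ShapMatrix,
    feature: str,
    window: tuple[float, float] | None = None,
) -> DependenceSummary:
    """Value-phi dependence for one feature.

    Reports the paired points, the Spearman rank correlation between
    feature value and phi, and -- when ``window=(lo, hi)`` is given -- the
    mean phi for values inside the inclusive window vs outside it.
    """
    if feature not in shap.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = shap.feature_names.index(feature)
    vals = shap.X[:, j]
    phi = shap.phi[:, j]
    if np.all(phi == phi[0]) or np.unique(vals).size == 1:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(vals, phi)[0])
    summary = DependenceSummary(feature=feature, values=vals, phi=phi, spearman_rho=rho)
    if window is not None:
        lo, hi = window
        inside = (vals >= lo) & (vals <= hi)
        summary.window = (lo, hi)
        summary.mean_phi_in_window = (
            float(phi[inside].mean()) if inside.any() else 0.0
        )
        summary.mean_phi_outside = (
            float(phi[~inside].mean()) if (~inside).any() else 0.0
        )
    return summary


def threshold_mean_phi(shap: ShapMatrix, feature: str, greater_than: float) -> float:
    """Mean phi over samples whose feature value exceeds a threshold."""
    j = shap.feature_names.index(feature)
    mask = shap.X[:, j] > greater_than
    return float(shap.phi[mask, j].mean()) if mask.any() else 0.0
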