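"""Per-replicate variable selection: lasso with an unpenalized forced block.

The candidate set (ascribed characteristics + natural talents) is subject to
L1 selection while the 10 genetic principal components stay in every model
unpenalized.  Zero penalty on the forced block is implemented exactly via
Frisch-Waugh-Lovell: outcome and candidates are residualized on the forced
columns (with intercept) and the lasso runs on the residuals — for any
lambda this solves

    min_{a,b}  ||y - F a - X b||^2 / (2n)  +  lambda ||b||_1

with the forced coefficients ``a`` unrestricted.

``double_lasso_select`` adds, in the post-double-selection spirit, one
auxiliary lasso per forced column (forced column regressed on the
candidates); the final selected set is the union over all equations, which
protects the fixed principal components against omitted-variable bias from
single-equation selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


class SelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class LassoConfig:
    """Penalized-selection settings.

    ``lambda_rule``: ``cv_min`` (penalty minimizing mean k-fold CV error,
    default) or ``cv_1se`` (largest penalty within one standard error of the
    minimum).  ``mode``: ``double`` (outcome lasso + auxiliary lasso per
    forced column, union), ``single`` (outcome lasso only) or ``none``
    (selection disabled — every candidate kept; used for saturated
    oracle checks).
    """

    lambda_rule: str = "cv_min"
    k_folds: int = 10
    n_lambda: int = 60
    lambda_min_ratio: float = 1e-3
    max_iter: int = 50_000
    tol: float = 1e-4
    mode: str = "double"

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("cv_min", "cv_1se"):
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.mode not in ("double", "single", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one (double-)lasso selection round."""

    selected_ascribed: tuple[str, ...]
    selected_talents: tuple[str, ...]
    forced: tuple[str, ...]
    lambda_used: Mapping[str, float] = field(default_factory=dict)
    mode: str = "double"

    @property
    def selected(self) -> tuple[str, ...]:
        return self.selected_ascribed + self.selected_talents


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D")
    return X, [f"x{j}" for j in range(X.shape[1])]


def _residualize(M: np.ndarray, F: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of M on [1, F] (least squares)."""
    n = M.shape[0]
    if F is None or F.size == 0:
        return M - M.mean(axis=0, keepdims=True)
    A = np.column_stack([np.ones(n), F])
    coef, *_ = np.linalg.lstsq(A, M, rcond=None)
    return M - A @ coef


def _drop_duplicate_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Collapse exactly duplicated candidate columns (lasso solutions are
    non-unique under duplication)."""
    seen: dict[bytes, str] = {}
    keep: list[int] = []
    for j, name in enumerate(names):
        key = X[:, j].tobytes()
        if key in seen:
            warnings.warn(
                f"candidate column {name!r} duplicates {seen[key]!r}; collapsed",
                UserWarning,
                stacklevel=3,
            )
            continue
        seen[key] = name
        keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def _lambda_grid(Xr: np.ndarray, yr: np.ndarray, config: LassoConfig) -> np.ndarray | None:
    n = len(yr)
    lam_max = np.max(np.abs(Xr.T @ yr)) / n if Xr.size else 0.0
    # a lambda_max at rounding-error scale means no detectable association
    scale = float(np.sqrt(yr @ yr / n)) * float(np.sqrt(np.max(np.sum(Xr**2, axis=0)) / n)) if Xr.size else 0.0
    if lam_max <= max(1e-10 * scale, 1e-300):
        return None
    return lam_max * np.logspace(0, np.log10(config.lambda_min_ratio), config.n_lambda)


def fit_lasso(
    y,
    candidates,
    forced=None,
    *,
    alpha: float,
    config: LassoConfig = LassoConfig(),
) -> pd.Series:
    """Candidate coefficients of the forced-unpenalized lasso at a fixed
    penalty (exposed for diagnostics and cross-checks)."""
    X, names = _as_matrix(candidates)
    F = None if forced is None else _as_matrix(forced)[0]
    yr = _residualize(np.asarray(y, dtype=float).reshape(-1, 1), F).ravel()
    Xr = _residualize(X, F)
    model = Lasso(alpha=alpha, max_iter=config.max_iter, tol=config.tol,
                  fit_intercept=False)
    model.fit(Xr, yr)
    return pd.Series(model.coef_, index=names)


def lasso_select(
    y,
    candidates,
    forced=None,
    config: LassoConfig = LassoConfig(),
    seed: int = 0,
) -> list[str]:
    """Names of candidate columns with nonzero lasso coefficient at the
    CV-chosen penalty; forced columns are never penalized (and are included
    in every downstream fit by construction, not through this return).

    Deterministic given ``seed`` (CV fold assignment).
    """
    y = np.asarray(y, dtype=float).ravel()
    X, names = _as_matrix(candidates)
    if X.shape[1] == 0:
        return []
    F = None if forced is None else _as_matrix(forced)[0]
    n_forced = 0 if F is None else F.shape[1]
    n = len(y)
    if n <= n_forced + 1:
        raise SelectionError(
            f"n={n} too small for {n_forced} forced columns"
        )
    X, names = _drop_duplicate_columns(X, names)

    yr = _residualize(y.reshape(-1, 1), F).ravel()
    Xr = _residualize(X, F)
    if float(yr @ yr) / n < 1e-14:
        return []
    grid = _lambda_grid(Xr, yr, config)
    if grid is None:
        return []

    cv = KFold(n_splits=min(config.k_folds, n), shuffle=True,
               random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LassoCV(alphas=grid, cv=cv, max_iter=config.max_iter,
                            tol=config.tol, fit_intercept=False)
            model.fit(Xr, yr)
        except ConvergenceWarning as exc:  # pragma: no cover - solver guard
            raise SelectionError(f"lasso failed to converge: {exc}") from exc

    alpha = float(model.alpha_)
    coef = model.coef_
    if config.lambda_rule == "cv_1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        alphas = model.alphas_  # descending
        i_min = int(np.argmin(mse))
        ok = np.where(mse <= mse[i_min] + se[i_min])[0]
        i_1se = int(ok.min())  # largest alpha within one SE
        alpha = float(alphas[i_1se])
        refit = Lasso(alpha=alpha, max_iter=config.max_iter, tol=config.tol,
                      fit_intercept=False)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            refit.fit(Xr, yr)
        coef = refit.coef_

    selected = [names[j] for j in range(len(names)) if coef[j] != 0.0]
    lasso_select.last_lambda = alpha  # introspection hook
    return selected


def double_lasso_select(
    y,
    candidates,
    forced=None,
    config: LassoConfig = LassoConfig(),
    seed: int = 0,
    roles: Mapping[str, str] | None = None,
) -> SelectionResult:
    """Union selection: outcome equation plus one auxiliary lasso per
    forced column (forced column regressed on the candidates).

    ``roles`` maps candidate names to "ascribed" / "pgi" / "skill" for the
    partition in the result; unmapped candidates count as ascribed.
    """
    X, names = _as_matrix(candidates)
    cand = pd.DataFrame(X, columns=names)
    Fmat: pd.DataFrame | None
    if forced is None:
        Fmat = None
        forced_names: list[str] = []
    else:
        Fm, forced_names = _as_matrix(forced)
        Fmat = pd.DataFrame(Fm, columns=forced_names)
    overlap = set(names) & set(forced_names)
    if overlap:
        raise SelectionError(f"columns both candidate and forced: {sorted(overlap)}")

    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in ss.spawn(1 + len(forced_names))]

    lambda_used: dict[str, float] = {}
    if config.mode == "none":
        union = list(names)
    else:
        union_set = set(
            lasso_select(y, cand, Fmat, config, child_seeds[0])
        )
        lambda_used["outcome"] = getattr(lasso_select, "last_lambda", np.nan)
        if config.mode == "double" and Fmat is not None:
            for k, fcol in enumerate(forced_names):
                sel = lasso_select(
                    Fmat[fcol].to_numpy(), cand, None, config, child_seeds[1 + k]
                )
                lambda_used[fcol] = getattr(lasso_select, "last_lambda", np.nan)
                union_set.update(sel)
        union = [c for c in names if c in union_set]

    roles = roles or {}
    talents = tuple(c for c in union if roles.get(c) in ("pgi", "skill"))
    ascribed = tuple(c for c in union if roles.get(c) not in ("pgi", "skill"))
    return SelectionResult(
        selected_ascribed=ascribed,
        selected_talents=talents,
        forced=tuple(forced_names),
        lambda_used=lambda_used,
        mode=config.mode,
    )
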