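"""Two-model R2 decomposition and the bagging loop.

For one sample (or bootstrap resample):

* Model A — selected ascribed + selected talents + forced genetic PCs.
  Its total R2 is **radical** inequality of opportunity.
* Reduced model — selected talents only.  radical minus this talents-only
  R2 is the semipartial R2 of the ascribed set: **conditional liberal**
  inequality of opportunity.
* Model B — selected ascribed + forced PCs.  Its total R2 is
  **unconditional liberal** inequality of opportunity.

``bag_iop`` repeats the whole procedure (selection included) on B bootstrap
resamples of individuals and aggregates means, SDs, and percentile 95% CIs
over the draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import AnalysisFrame
from .selection import LassoConfig, SelectionResult, double_lasso_select

_NEG_TOL = 1e-10


class DecompositionError(RuntimeError):
    pass


def ols_r2(y, X) -> float:
    """Unadjusted coefficient of determination of an OLS fit with intercept.

    ``X`` carries no intercept column; a rank-deficient design is fit by the
    minimum-norm solution (R2 is still well defined).  An empty design has
    R2 = 0 by convention.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise DecompositionError(f"n={n} too small for p={p} predictors + intercept")
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst == 0.0:
        raise DecompositionError("outcome has zero variance")
    if p == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ coef
    r2 = 1.0 - float(resid @ resid) / sst
    return float(min(max(r2, 0.0), 1.0))


def semipartial_r2(y, X_full, X_reduced) -> float:
    """Unique contribution of the columns present in ``X_full`` but not in
    ``X_reduced``: R2(full) - R2(reduced), nonnegative under nesting.

    Inputs must be DataFrames (nesting is checked by column names).  A
    difference within -1e-10 of zero is clipped to 0 with a warning; a
    larger negative difference signals a wiring bug and raises.
    """
    if not isinstance(X_full, pd.DataFrame) or not isinstance(X_reduced, pd.DataFrame):
        raise TypeError("semipartial_r2 expects DataFrames to verify nesting")
    extra = set(X_reduced.columns) - set(X_full.columns)
    if extra:
        raise DecompositionError(f"reduced design not nested in full: {sorted(extra)}")
    diff = ols_r2(y, X_full) - ols_r2(y, X_reduced)
    if diff < -_NEG_TOL:
        raise DecompositionError(
            f"negative semipartial R2 ({diff:.3e}) on nested designs"
        )
    if diff < 0.0:
        warnings.warn("semipartial R2 within numerical tolerance of 0; clipped",
                      UserWarning, stacklevel=2)
        diff = 0.0
    return float(diff)


@dataclass(frozen=True)
class IopDraw:
    """Decomposition on one sample / bootstrap replicate."""

    replicate_index: int
    r2_radical: float
    r2_liberal_conditional: float
    r2_liberal_unconditional: float
    r2_talents_only: float
    selection: SelectionResult

    def __post_init__(self) -> None:
        for name in ("r2_radical", "r2_liberal_conditional",
                     "r2_liberal_unconditional", "r2_talents_only"):
            v = getattr(self, name)
            if not -_NEG_TOL <= v <= 1 + _NEG_TOL:
                raise DecompositionError(f"{name}={v} outside [0, 1]")
        if self.r2_radical < self.r2_talents_only - _NEG_TOL:
            raise DecompositionError("radical R2 below talents-only R2")
        if self.r2_radical < self.r2_liberal_unconditional - 1e-8:
            raise DecompositionError("radical R2 below unconditional liberal R2")
        ident = self.r2_radical - self.r2_talents_only
        if abs(ident - self.r2_liberal_conditional) > 1e-12:
            raise DecompositionError("semipartial identity violated")


@dataclass(frozen=True)
class BagSpec:
    """Bootstrap-aggregation specification (resample size = n, with
    replacement)."""

    B: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class QuantityEstimate:
    point: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class IopEstimate:
    """Bagged estimate: per-quantity mean / SD / percentile 95% CI over
    draws, plus the radical-vs-conditional-liberal difference."""

    quantities: Mapping[str, QuantityEstimate]
    difference: float
    difference_se: float
    difference_p_raw: float
    difference_p_holm: float | None = None
    B: int = 0
    se_undefined: bool = False
    n_failed_replicates: int = 0

    def __getitem__(self, key: str) -> QuantityEstimate:
        return self.quantities[key]


def iop_one_sample(
    frame: AnalysisFrame,
    talent_measure: str,
    outcome: str,
    config: LassoConfig = LassoConfig(),
    seed: int = 0,
    replicate_index: int = 0,
    include_pcs_in_reduced: bool = False,
) -> IopDraw:
    """Run selection and the two-model decomposition on one frame.

    The reduced model for the semipartial excludes the genetic PCs by
    default — they belong to the ascribed set, so their share counts toward
    the ascribed unique contribution (``include_pcs_in_reduced=True`` keeps
    them in the reduced model as a sensitivity setting).
    """
    if talent_measure not in ("pgi", "skill"):
        raise ValueError("talent_measure must be 'pgi' or 'skill'")
    data = frame.data
    if outcome not in data.columns:
        raise KeyError(f"outcome {outcome!r} not in frame")
    rm = frame.rolemap
    ascribed = frame.columns_for("ascribed")
    talents = frame.columns_for(talent_measure)
    pcs = frame.columns_for("pc")

    y = data[outcome].to_numpy()
    candidates = data[ascribed + talents]
    forced = data[pcs] if pcs else None
    roles = {c: rm.mapping[c] for c in ascribed + talents}
    sel = double_lasso_select(y, candidates, forced, config, seed, roles)

    sel_asc = [c for c in ascribed if c in sel.selected_ascribed]
    sel_tal = [c for c in talents if c in sel.selected_talents]

    X_full = data[sel_asc + sel_tal + pcs]
    r2_radical = ols_r2(y, X_full)

    reduced_cols = sel_tal + (pcs if include_pcs_in_reduced else [])
    X_reduced = data[reduced_cols]
    # the guarded difference (raises on impossible negatives) ...
    semi = semipartial_r2(y, X_full, X_reduced)
    r2_talents = ols_r2(y, X_reduced)
    # ... and the exact identity for the stored values
    r2_cond = r2_radical - r2_talents
    if abs(r2_cond - semi) > 1e-12:
        # only reachable via the clip-at-zero branch; keep the identity exact
        r2_cond = semi
        r2_talents = r2_radical - semi

    X_b = data[sel_asc + pcs]
    r2_uncond = ols_r2(y, X_b)

    return IopDraw(
        replicate_index=replicate_index,
        r2_radical=r2_radical,
        r2_liberal_conditional=r2_cond,
        r2_liberal_unconditional=r2_uncond,
        r2_talents_only=r2_talents,
        selection=sel,
    )


def _aggregate(draws: Sequence[IopDraw]) -> IopEstimate:
    from .inference import paired_t  # local import avoids a cycle

    B = len(draws)
    arrays = {
        "radical": np.array([d.r2_radical for d in draws]),
        "liberal_conditional": np.array([d.r2_liberal_conditional for d in draws]),
        "liberal_unconditional": np.array([d.r2_liberal_unconditional for d in draws]),
        "talents_only": np.array([d.r2_talents_only for d in draws]),
    }
    se_undefined = B < 2
    quantities = {}
    for name, v in arrays.items():
        se = 0.0 if se_undefined else float(np.std(v, ddof=1))
        lo, hi = np.percentile(v, [2.5, 97.5])  # linear-interpolation quantiles
        quantities[name] = QuantityEstimate(float(np.mean(v)), se, float(lo), float(hi))

    difference = quantities["radical"].point - quantities["liberal_conditional"].point
    if se_undefined:
        diff_se, p_raw = 0.0, float("nan")
    else:
        d = arrays["radical"] - arrays["liberal_conditional"]
        diff_se = float(np.std(d, ddof=1))
        p_raw = paired_t(arrays["radical"], arrays["liberal_conditional"]).p
    return IopEstimate(
        quantities=quantities,
        difference=difference,
        difference_se=diff_se,
        difference_p_raw=p_raw,
        B=B,
        se_undefined=se_undefined,
    )


def bag_iop(
    frame: AnalysisFrame,
    talent_measure: str,
    outcome: str,
    config: LassoConfig = LassoConfig(),
    bag: BagSpec = BagSpec(),
    include_pcs_in_reduced: bool = False,
) -> tuple[list[IopDraw], IopEstimate]:
    """Bootstrap-aggregate the decomposition over ``bag.B`` resamples.

    Each replicate draws n individuals with replacement from a seeded child
    stream, reruns selection and both models, and contributes one
    :class:`IopDraw`.  Replicate failures (degenerate resamples) are logged
    and redrawn from reserve streams; more than 1% failures aborts.
    Deterministic given ``bag.master_seed`` and independent of execution
    order (each replicate owns a pre-spawned seed).
    """
    n = frame.n
    B = bag.B
    n_reserve = max(8, B // 20)
    children = np.random.SeedSequence(bag.master_seed).spawn(B + n_reserve)
    reserve = list(children[B:])
    max_failures = max(1, int(np.ceil(0.01 * B)))

    draws: list[IopDraw] = []
    n_failed = 0
    for b in range(B):
        child = children[b]
        while True:
            rng = np.random.default_rng(child)
            idx = rng.integers(0, n, size=n)
            sub = frame.data.iloc[idx].reset_index(drop=True)
            sel_seed = int(child.generate_state(1)[0] % (2**31))
            try:
                if (sub.std(ddof=0) == 0).any():
                    raise DecompositionError("zero-variance column in resample")
                rep = AnalysisFrame(data=sub, rolemap=frame.rolemap)
                draw = iop_one_sample(
                    rep, talent_measure, outcome, config, sel_seed,
                    replicate_index=b,
                    include_pcs_in_reduced=include_pcs_in_reduced,
                )
            except (DecompositionError, RuntimeError) as exc:
                n_failed += 1
                if n_failed > max_failures or not reserve:
                    raise DecompositionError(
                        f"{n_failed} replicate failures (last: {exc})"
                    ) from exc
                child = reserve.pop(0)
                continue
            draws.append(draw)
            break

    est = _aggregate(draws)
    est = replace(est, n_failed_replicates=n_failed)
    return draws, est


def draws_to_frame(draws: Sequence[IopDraw]) -> pd.DataFrame:
    """Tabular view of per-replicate results (for CSV export)."""
    return pd.DataFrame(
        {
            "replicate": [d.replicate_index for d in draws],
            "r2_radical": [d.r2_radical for d in draws],
            "r2_liberal_conditional": [d.r2_liberal_conditional for d in draws],
            "r2_liberal_unconditional": [d.r2_liberal_unconditional for d in draws],
            "r2_talents_only": [d.r2_talents_only for d in draws],
            "n_selected_ascribed": [len(d.selection.selected_ascribed) for d in draws],
            "n_selected_talents": [len(d.selection.selected_talents) for d in draws],
        }
    )
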