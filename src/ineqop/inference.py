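"""Paired comparisons of radical vs. conditional-liberal IOp and the
publication-style results table.

Per cell (talent measure x outcome) the radical and conditional-liberal
bootstrap draws are compared with a classical paired t-test (df = B-1);
p-values are Holm-adjusted across all cells of a run's table.  Note the
deliberate fidelity choice: the t-test is applied to bootstrap replicates
exactly as published practice does, even though replicates are resamples of
one dataset rather than independent observations — see the methods note.
An alternative flag bases significance on the bootstrap percentile CI of
the difference excluding zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .decomposition import IopEstimate


class PairedTResult(NamedTuple):
    t: float
    p: float
    degenerate: bool = False


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t-test on aligned draw vectors.

    Zero-variance differences: all-zero differences give p = 1 (no evidence
    of any difference); a constant nonzero difference gives p = 0 with the
    degenerate flag set.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired_t needs two aligned vectors of length >= 2")
    d = a - b
    if np.all(d == 0.0):
        return PairedTResult(0.0, 1.0, False)
    sd = d.std(ddof=1)
    # constant nonzero difference (sd at rounding-error scale): the test
    # statistic diverges; report p = 0 and flag the degeneracy
    if sd <= 1e-12 * np.max(np.abs(d)):
        return PairedTResult(float(np.sign(d.mean()) * np.inf), 0.0, True)
    t, p = stats.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), False)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float).ravel()
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class ComparisonCell:
    """One table cell: paired draw vectors for a talent measure x outcome."""

    talent_measure: str
    outcome: str
    radical_draws: np.ndarray
    liberal_draws: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radical_draws, dtype=float).ravel()
        l = np.asarray(self.liberal_draws, dtype=float).ravel()
        if r.shape != l.shape:
            raise ValueError("radical and liberal draws must align by replicate")
        object.__setattr__(self, "radical_draws", r)
        object.__setattr__(self, "liberal_draws", l)

    @property
    def key(self) -> tuple[str, str]:
        return (self.talent_measure, self.outcome)


@dataclass(frozen=True)
class ComparisonFamily:
    """All cells sharing one Holm correction (one table)."""

    cells: tuple[ComparisonCell, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        lengths = {len(c.radical_draws) for c in self.cells}
        if len(lengths) > 1:
            raise ValueError(f"cells have unequal draw counts: {sorted(lengths)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class IopTable:
    """Assembled results: full precision + display formatting."""

    data: pd.DataFrame
    alpha: float

    def display(self) -> pd.DataFrame:
        """Rows formatted like published tables: estimate (SE) columns and
        a starred difference; values rounded half-even to 2 decimals."""

        def r2s(x: float) -> str:
            return f"{_round_half_even(x):.2f}"

        rows = []
        for _, r in self.data.iterrows():
            rows.append(
                {
                    "Natural talents": r["talent_measure"],
                    "Outcome": r["outcome"],
                    "Radical": r2s(r["radical"]),
                    "(SE)": f"({r2s(r['radical_se'])})",
                    "Liberal": r2s(r["liberal_conditional"]),
                    "(SE) ": f"({r2s(r['liberal_conditional_se'])})",
                    "Difference": r2s(r["difference"])
                    + ("*" if r["significant"] else ""),
                }
            )
        return pd.DataFrame(rows)


def _round_half_even(x: float, ndigits: int = 2) -> float:
    return float(np.round(x, ndigits))


def assemble_table(
    estimates: Mapping[tuple[str, str], IopEstimate],
    family: ComparisonFamily,
    significance: str = "paired_t",
) -> IopTable:
    """Build the results table for one run.

    ``estimates`` is keyed by (talent_measure, outcome); every family cell
    must have one.  The difference column is radical minus conditional
    liberal; the star marks Holm-adjusted p < alpha (``significance=
    "ci_overlap"`` stars cells whose bootstrap percentile CI of the
    difference excludes zero instead).
    """
    if significance not in ("paired_t", "ci_overlap"):
        raise ValueError(f"unknown significance rule {significance!r}")
    missing = [c.key for c in family.cells if c.key not in estimates]
    if missing:
        raise KeyError(f"estimates missing for cells: {missing}")

    raw_p = []
    for cell in family.cells:
        raw_p.append(paired_t(cell.radical_draws, cell.liberal_draws).p)
    adj_p = holm_adjust(raw_p)

    rows = []
    for cell, p_raw, p_adj in zip(family.cells, raw_p, adj_p):
        est = estimates[cell.key]
        d = cell.radical_draws - cell.liberal_draws
        ci_lo, ci_hi = np.percentile(d, [2.5, 97.5])
        if significance == "paired_t":
            sig = bool(p_adj < family.alpha)
        else:
            sig = bool(ci_lo > 0 or ci_hi < 0)
        rows.append(
            {
                "talent_measure": cell.talent_measure,
                "outcome": cell.outcome,
                "radical": est["radical"].point,
                "radical_se": est["radical"].se,
                "liberal_conditional": est["liberal_conditional"].point,
                "liberal_conditional_se": est["liberal_conditional"].se,
                "liberal_unconditional": est["liberal_unconditional"].point,
                "liberal_unconditional_se": est["liberal_unconditional"].se,
                "difference": est["radical"].point - est["liberal_conditional"].point,
                "difference_ci_low": float(ci_lo),
                "difference_ci_high": float(ci_hi),
                "p_raw": float(p_raw),
                "p_holm": float(p_adj),
                "significant": sig,
            }
        )
    return IopTable(data=pd.DataFrame(rows), alpha=family.alpha)


def figure_data(
    estimates: Mapping[tuple[str, str], IopEstimate]
) -> pd.DataFrame:
    """Per-cell bar heights and bootstrap 95% CI bounds (the quantities a
    grouped bar chart with error bars needs)."""
    rows = []
    for (tm, outcome), est in estimates.items():
        for q in ("radical", "liberal_conditional", "liberal_unconditional"):
            qe = est[q]
            rows.append(
                {
                    "talent_measure": tm,
                    "outcome": outcome,
                    "quantity": q,
                    "estimate": qe.point,
                    "ci_low": qe.ci_low,
                    "ci_high": qe.ci_high,
                }
            )
    return pd.DataFrame(rows)
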