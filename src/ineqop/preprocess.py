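"""Turn long-format multi-wave survey data into the standardized analysis frame.

The estimator consumes one row per individual with every design column
centered and scaled.  This module applies, in order:

1. ``collapse_waves`` — outcomes and skills are observed repeatedly; each is
   collapsed to the maximum non-missing value across waves.  Time-invariant
   columns (ascribed characteristics, polygenic indices, genetic principal
   components) are validated to be constant within individual.
2. ``filter_sample`` — working-age restriction (age at the first outcome
   measurement), id exclusions, and complete-case filtering, with a count
   report per criterion.
3. ``encode_categoricals`` — reference-level dummy coding; dummies inherit
   the role of their source column.
4. ``standardize`` — every numeric column to mean 0, SD 1 (ddof=1), so R2 is
   comparable across models.

``prepare`` chains the four steps and accumulates a provenance log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_ROLES = frozenset(
    {"outcome", "ascribed", "pgi", "skill", "pc", "id", "wave", "age"}
)
#: roles whose columns may vary across waves (collapsed by max)
WAVE_VARYING_ROLES = frozenset({"outcome", "skill"})
#: roles that enter the design or the outcome of the estimator
ANALYSIS_ROLES = frozenset({"outcome", "ascribed", "pgi", "skill", "pc"})


class RoleMapError(ValueError):
    pass


class PreprocessError(ValueError):
    pass


class EmptySampleError(PreprocessError):
    """All rows were removed by the sample filters; nothing left to fit."""


@dataclass(frozen=True)
class RoleMap:
    """Assignment of data columns to analysis roles.

    Parameters
    ----------
    mapping
        column name -> role, role in :data:`VALID_ROLES`.
    talent_measure
        which role plays "natural talents" in a run: ``"pgi"`` (polygenic
        indices, fixed at conception) or ``"skill"`` (cognitive and Big-5
        measures observed later in life).
    """

    mapping: Mapping[str, str]
    talent_measure: str = "pgi"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))
        bad = {c: r for c, r in self.mapping.items() if r not in VALID_ROLES}
        if bad:
            raise RoleMapError(f"unknown roles: {bad}")
        if self.talent_measure not in ("pgi", "skill"):
            raise RoleMapError(
                f"talent_measure must be 'pgi' or 'skill', got {self.talent_measure!r}"
            )
        if len(self.cols_for("id")) != 1:
            raise RoleMapError("exactly one id column is required")
        if len(self.cols_for("wave")) > 1:
            raise RoleMapError("at most one wave column is allowed")
        if len(self.cols_for("age")) > 1:
            raise RoleMapError("at most one age column is allowed")
        if not self.cols_for("outcome"):
            raise RoleMapError("at least one outcome column is required")

    def cols_for(self, role: str) -> list[str]:
        return [c for c, r in self.mapping.items() if r == role]

    @property
    def id_col(self) -> str:
        return self.cols_for("id")[0]

    @property
    def wave_col(self) -> str | None:
        cols = self.cols_for("wave")
        return cols[0] if cols else None

    @property
    def age_col(self) -> str | None:
        cols = self.cols_for("age")
        return cols[0] if cols else None

    @property
    def outcome_cols(self) -> list[str]:
        return self.cols_for("outcome")

    @property
    def talent_cols(self) -> list[str]:
        return self.cols_for(self.talent_measure)

    def analysis_cols(self) -> list[str]:
        """Columns that enter the candidate set or serve as outcomes."""
        return [c for c, r in self.mapping.items() if r in ANALYSIS_ROLES]

    def replace_column(self, old: str, new_cols: Sequence[str]) -> "RoleMap":
        """Role map with ``old`` replaced by ``new_cols`` of the same role."""
        role = self.mapping[old]
        mapping = {c: r for c, r in self.mapping.items() if c != old}
        for c in new_cols:
            if c in mapping:
                raise RoleMapError(f"column {c!r} already mapped")
            mapping[c] = role
        return RoleMap(mapping, self.talent_measure)

    def drop_columns(self, cols: Iterable[str]) -> "RoleMap":
        cols = set(cols)
        return RoleMap(
            {c: r for c, r in self.mapping.items() if c not in cols},
            self.talent_measure,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"talent_measure": self.talent_measure, "roles": dict(self.mapping)},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        unknown = set(raw) - {"talent_measure", "roles"}
        if unknown:
            raise RoleMapError(f"unknown role-map keys: {sorted(unknown)}")
        return cls(raw["roles"], raw.get("talent_measure", "pgi"))


@dataclass(frozen=True)
class FilterCriteria:
    """Sample restrictions, applied in field order."""

    exclude_ids: tuple = ()
    age_range: tuple[float, float] | None = None
    required_columns: tuple[str, ...] | None = None


@dataclass
class AnalysisFrame:
    """One row per individual, all numeric, standardized; ready to fit.

    ``data`` is indexed by individual id.  ``scaling`` records the mean/SD
    removed from each column so raw-scale values can be recovered.
    """

    data: pd.DataFrame
    rolemap: RoleMap
    scaling: pd.DataFrame | None = None
    provenance: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)

    def columns_for(self, role: str) -> list[str]:
        return [c for c in self.rolemap.cols_for(role) if c in self.data.columns]


def load_table(path, rolemap: RoleMap) -> pd.DataFrame:
    """Read a CSV/TSV cohort table; empty strings are missing values."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, keep_default_na=True)
    missing = [c for c in rolemap.mapping if c not in df.columns]
    if missing:
        raise PreprocessError(f"columns in role map absent from data: {missing}")
    return df


def collapse_waves(long_table: pd.DataFrame, rolemap: RoleMap) -> pd.DataFrame:
    """Collapse per-individual-per-wave rows to one row per individual.

    Wave-varying columns (outcomes, skills) take the maximum non-missing
    value across waves.  Time-invariant columns must be constant within an
    individual (missing entries excepted).  The age column, if present, is
    resolved to the age at the earliest wave with any non-missing outcome.
    Idempotent: on a table without a wave column it validates uniqueness of
    ids and passes through.
    """
    idc = rolemap.id_col
    if idc not in long_table.columns:
        raise PreprocessError(f"id column {idc!r} not in table")
    wave = rolemap.wave_col
    if wave is None or wave not in long_table.columns:
        if long_table[idc].duplicated().any():
            raise PreprocessError("duplicate ids in single-wave table")
        return long_table.reset_index(drop=True).copy()

    df = long_table.sort_values([idc, wave], kind="mergesort")
    varying = [
        c
        for c in df.columns
        if rolemap.mapping.get(c) in WAVE_VARYING_ROLES
    ]
    invariant = [
        c
        for c in df.columns
        if c not in varying and c not in (idc, wave) and c != rolemap.age_col
    ]

    g = df.groupby(idc, sort=True)
    conflicts = []
    for c in invariant:
        nun = g[c].nunique(dropna=True)
        if (nun > 1).any():
            conflicts.extend(nun.index[nun > 1].tolist())
    if conflicts:
        ids = sorted(set(conflicts))
        raise PreprocessError(
            f"time-invariant columns differ across waves for ids: {ids[:10]}"
            + ("..." if len(ids) > 10 else "")
        )

    pieces = {}
    for c in varying:
        pieces[c] = g[c].max()
    for c in invariant:
        pieces[c] = g[c].first()  # first non-null

    agec = rolemap.age_col
    if agec is not None and agec in df.columns:
        outs = [c for c in rolemap.outcome_cols if c in df.columns]
        has_out = df[outs].notna().any(axis=1) if outs else pd.Series(True, index=df.index)
        first = (
            df[has_out]
            .groupby(idc, sort=True)[agec]
            .first()
        )
        pieces[agec] = first  # NaN where no outcome ever observed

    out = pd.DataFrame(pieces)
    out = out.reindex(columns=[c for c in long_table.columns if c not in (idc, wave)])
    out.insert(0, idc, out.index)
    return out.reset_index(drop=True)


def filter_sample(
    table: pd.DataFrame,
    criteria: FilterCriteria,
    rolemap: RoleMap | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply sample restrictions; return the kept rows and a count report.

    Criteria are applied in order: id exclusions, age range (inclusive on
    both ends, on the age-at-first-outcome column), complete cases on
    ``required_columns``.  Raises :class:`EmptySampleError` if nothing
    survives.
    """
    df = table
    report: list[dict] = [{"criterion": "input", "rows": len(df), "removed": 0}]

    if criteria.exclude_ids:
        if rolemap is None:
            raise PreprocessError("exclude_ids requires a role map")
        keep = ~df[rolemap.id_col].isin(set(criteria.exclude_ids))
        report.append(
            {"criterion": "exclude_ids", "rows": int(keep.sum()),
             "removed": int((~keep).sum())}
        )
        df = df[keep]

    if criteria.age_range is not None:
        if rolemap is None or rolemap.age_col is None or rolemap.age_col not in df.columns:
            raise PreprocessError("age_range filter requires an age column")
        lo, hi = criteria.age_range
        age = df[rolemap.age_col]
        keep = age.ge(lo) & age.le(hi)
        report.append(
            {"criterion": f"age_range[{lo},{hi}]", "rows": int(keep.sum()),
             "removed": int((~keep).sum())}
        )
        df = df[keep]

    if criteria.required_columns is not None:
        cols = [c for c in criteria.required_columns if c in df.columns]
        missing = set(criteria.required_columns) - set(cols)
        if missing:
            raise PreprocessError(f"required columns absent: {sorted(missing)}")
        keep = df[cols].notna().all(axis=1)
        report.append(
            {"criterion": "complete_case", "rows": int(keep.sum()),
             "removed": int((~keep).sum())}
        )
        df = df[keep]

    if len(df) == 0:
        raise EmptySampleError(f"no rows survive the sample filters: {report}")
    return df.reset_index(drop=True), report


def encode_categoricals(
    table: pd.DataFrame, rolemap: RoleMap
) -> tuple[pd.DataFrame, RoleMap]:
    """Dummy-code non-numeric columns; dummies inherit the source role.

    Reference level = first observed level alphabetically; dummy names are
    ``"col=level"``.  A column with a single observed level carries no
    information and is dropped with a warning.  Missingness is preserved
    (dummies are NaN where the source is NaN).
    """
    df = table.copy()
    rm = rolemap
    idc = rolemap.id_col
    for col in list(df.columns):
        if col == idc or rm.mapping.get(col) not in ANALYSIS_ROLES:
            continue
        if pd.api.types.is_numeric_dtype(df[col]):
            continue
        levels = sorted(df[col].dropna().unique().tolist())
        if len(levels) < 2:
            warnings.warn(
                f"categorical column {col!r} has a single observed level; dropped",
                UserWarning,
                stacklevel=2,
            )
            df = df.drop(columns=[col])
            rm = rm.drop_columns([col])
            continue
        new_cols = []
        isna = df[col].isna()
        for lvl in levels[1:]:
            name = f"{col}={lvl}"
            dummy = (df[col] == lvl).astype(float)
            dummy[isna] = np.nan
            df[name] = dummy
            new_cols.append(name)
        df = df.drop(columns=[col])
        rm = rm.replace_column(col, new_cols)
    return df, rm


def standardize(table: pd.DataFrame, rolemap: RoleMap) -> AnalysisFrame:
    """Center and scale every analysis column to mean 0, SD 1 (ddof=1)."""
    idc = rolemap.id_col
    if len(table) < 2:
        raise PreprocessError("need at least 2 rows to standardize")
    df = table.set_index(idc) if idc in table.columns else table.copy()
    cols = [c for c in df.columns if rolemap.mapping.get(c) in ANALYSIS_ROLES]
    df = df[cols].astype(float)

    with_na = [c for c in cols if df[c].isna().any()]
    if with_na:
        raise PreprocessError(
            f"missing values remain after filtering in columns: {with_na}"
        )
    mean = df.mean()
    sd = df.std(ddof=1)
    zero = sd.index[sd == 0.0].tolist()
    if zero:
        raise PreprocessError(f"zero-variance columns cannot be standardized: {zero}")
    out = (df - mean) / sd
    scaling = pd.DataFrame({"mean": mean, "sd": sd})
    return AnalysisFrame(data=out, rolemap=rolemap, scaling=scaling)


def prepare(
    long_table: pd.DataFrame,
    rolemap: RoleMap,
    criteria: FilterCriteria | None = None,
    log_columns: Sequence[str] = (),
) -> AnalysisFrame:
    """Collapse, filter, encode, and standardize in one pass.

    Complete-case filtering defaults to the union of all analysis columns
    (one frame, one N, shared by every outcome).  ``log_columns`` are
    natural-log transformed (values must be positive) before scaling —
    intended for right-skewed outcomes such as gross income.
    """
    collapsed = collapse_waves(long_table, rolemap)
    crit = criteria or FilterCriteria()
    if crit.required_columns is None:
        crit = FilterCriteria(
            exclude_ids=crit.exclude_ids,
            age_range=crit.age_range,
            required_columns=tuple(
                c for c in rolemap.analysis_cols() if c in collapsed.columns
            ),
        )
    filtered, report = filter_sample(collapsed, crit, rolemap)
    for col in log_columns:
        vals = filtered[col]
        if (vals <= 0).any():
            raise PreprocessError(f"log transform of {col!r}: non-positive values")
        filtered = filtered.assign(**{col: np.log(vals)})
    encoded, rm = encode_categoricals(filtered, rolemap)
    frame = standardize(encoded, rm)
    frame.provenance = report + [
        {"criterion": f"log[{c}]", "rows": frame.n, "removed": 0} for c in log_columns
    ]
    return frame
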