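"""Synthetic cohorts with analytically known population R2 decompositions.

The real study data (restricted-access longitudinal surveys with genotyped
respondents) cannot ship with the package, so this module generates cohorts
with the same statistical skeleton:

* ascribed characteristics — birth year, sex, migration background, paternal
  education, parental occupational status;
* 10 genetic principal components (population-stratification axes);
* ~7 polygenic indices (PGIs), correlated among themselves and with the
  parental-background variables (genetic nurture / assortative mating leave
  exactly this footprint in real cohorts);
* cognitive + Big-5 skill measures, partially caused by PGIs and ascribed
  characteristics;
* three life outcomes (years of education, occupational status, gross
  monthly income) that are noisy linear functions of all blocks, observed
  over several waves with transient measurement noise and sporadic
  missingness.

Because every structural equation is linear-Gaussian (categoricals enter
through exactly-known indicator moments), the population R2 of the best
linear predictor from any subset of variables has a closed form
(:func:`population_r2`), which makes the whole estimator stack testable
against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .preprocess import RoleMap

__all__ = [
    "AscribedVar",
    "SynthParams",
    "GroundTruth",
    "OutcomeTruth",
    "build_covariance",
    "population_r2",
    "ground_truth_decomposition",
    "simulate_cohort",
    "default_params",
]


class SynthParamsError(ValueError):
    pass


@dataclass(frozen=True)
class AscribedVar:
    """One ascribed characteristic: continuous (standard normal latent) or
    categorical (thresholded independent latent normal)."""

    name: str
    kind: str = "continuous"  # "continuous" | "categorical"
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SynthParamsError(f"unknown kind {self.kind!r} for {self.name}")
        if self.kind == "categorical":
            if len(self.levels) < 2 or len(self.levels) != len(self.probs):
                raise SynthParamsError(
                    f"categorical {self.name}: need >=2 levels with matching probs"
                )
            if any(p <= 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
                raise SynthParamsError(
                    f"categorical {self.name}: probs must be positive and sum to 1"
                )

    def dummy_names(self) -> list[str]:
        """Reference-coded dummy names, matching the preprocessing encoder
        (reference = first level alphabetically)."""
        return [f"{self.name}={lvl}" for lvl in sorted(self.levels)[1:]]


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

_PGI_NAMES = (
    "pgi_ea",            # educational attainment
    "pgi_cog",           # cognitive performance
    "pgi_math_ability",  # self-reported maths ability
    "pgi_math_class",    # highest maths class taken
    "pgi_depression",
    "pgi_wellbeing",
    "pgi_neuroticism",
)

_SKILL_NAMES = (
    "skill_cognition",
    "skill_openness",
    "skill_conscientiousness",
    "skill_extraversion",
    "skill_agreeableness",
    "skill_neuroticism",
)

_DEFAULT_ASCRIBED = (
    AscribedVar("year_of_birth"),
    AscribedVar("paternal_education"),
    AscribedVar("parental_occupation"),
    AscribedVar("sex", "categorical", ("female", "male"), (0.5, 0.5)),
    AscribedVar(
        "migration_background",
        "categorical",
        ("majority", "migrant_1g", "migrant_2g"),
        (0.82, 0.09, 0.09),
    ),
)

_DEFAULT_ASCRIBED_CORR = {
    ("paternal_education", "parental_occupation"): 0.50,
    ("year_of_birth", "paternal_education"): 0.15,
    ("year_of_birth", "parental_occupation"): 0.10,
}

# within-PGI genetic correlations (exchangeable baseline + named pairs)
_DEFAULT_PGI_CORR = {
    ("pgi_ea", "pgi_cog"): 0.50,
    ("pgi_ea", "pgi_math_ability"): 0.30,
    ("pgi_ea", "pgi_math_class"): 0.35,
    ("pgi_cog", "pgi_math_ability"): 0.35,
    ("pgi_math_ability", "pgi_math_class"): 0.45,
    ("pgi_depression", "pgi_neuroticism"): 0.50,
    ("pgi_depression", "pgi_wellbeing"): -0.35,
    ("pgi_neuroticism", "pgi_wellbeing"): -0.30,
}

# gene-environment correlation: parental background <-> child PGIs
_DEFAULT_CROSS = {
    ("paternal_education", "pgi_ea"): 0.30,
    ("paternal_education", "pgi_cog"): 0.20,
    ("parental_occupation", "pgi_ea"): 0.25,
    ("parental_occupation", "pgi_cog"): 0.15,
}

_DEFAULT_SKILL_LOADINGS = {
    "skill_cognition": {
        "pgi_cog": 0.35, "pgi_ea": 0.20,
        "paternal_education": 0.20, "parental_occupation": 0.10,
    },
    "skill_openness": {"pgi_ea": 0.15, "paternal_education": 0.15},
    "skill_conscientiousness": {"pgi_ea": 0.12},
    "skill_extraversion": {"pgi_wellbeing": 0.15},
    "skill_agreeableness": {"pgi_wellbeing": 0.10},
    "skill_neuroticism": {"pgi_neuroticism": 0.35, "pgi_depression": 0.20},
}

_DEFAULT_SKILL_NOISE = {
    "skill_cognition": 0.82,
    "skill_openness": 0.96,
    "skill_conscientiousness": 0.99,
    "skill_extraversion": 0.99,
    "skill_agreeableness": 0.99,
    "skill_neuroticism": 0.85,
}

_PC_BETA = 0.02  # tiny true stratification signal on each genetic PC

_DEFAULT_OUTCOME_BETAS = {
    "education": {
        "paternal_education": 0.275, "parental_occupation": 0.14,
        "year_of_birth": 0.10, "sex=male": -0.12,
        "migration_background=migrant_1g": -0.13,
        "migration_background=migrant_2g": -0.05,
        "pgi_ea": 0.135, "pgi_cog": 0.06, "pgi_math_class": 0.05,
        "skill_cognition": 0.42, "skill_openness": 0.05,
        "skill_conscientiousness": 0.15, "skill_neuroticism": -0.06,
        **{f"pc{i:02d}": _PC_BETA for i in range(1, 11)},
    },
    "occupation": {
        "paternal_education": 0.16, "parental_occupation": 0.24,
        "year_of_birth": 0.05, "sex=male": 0.10,
        "migration_background=migrant_1g": -0.12,
        "migration_background=migrant_2g": -0.05,
        "pgi_ea": 0.10, "pgi_cog": 0.05,
        "skill_cognition": 0.28, "skill_conscientiousness": 0.12,
        **{f"pc{i:02d}": _PC_BETA for i in range(1, 11)},
    },
    "income": {
        "paternal_education": 0.10, "parental_occupation": 0.18,
        "year_of_birth": 0.08, "sex=male": 0.42,
        "migration_background=migrant_1g": -0.12,
        "migration_background=migrant_2g": -0.05,
        "pgi_ea": 0.07, "pgi_cog": 0.04,
        "skill_cognition": 0.16, "skill_conscientiousness": 0.10,
        "skill_neuroticism": -0.05,
        **{f"pc{i:02d}": _PC_BETA for i in range(1, 11)},
    },
}

# residual SDs tuned once against population_r2 so that, under the PGI
# talent measure, population radical IOp is ~0.25 / ~0.16 / ~0.19 for
# education / occupation / income and education's conditional liberal IOp
# is ~0.11 — the orders of magnitude seen in genotyped survey cohorts.
_DEFAULT_OUTCOME_NOISE = {
    "education": 1.226,
    "occupation": 1.308,
    "income": 0.925,
}


@dataclass(frozen=True)
class SynthParams:
    """Generative specification of a synthetic cohort.

    All continuous predictors (continuous ascribed variables, PGIs, genetic
    PCs) are jointly multivariate normal with unit variances; categorical
    ascribed variables are thresholded independent latent normals; skills
    are linear in the continuous block plus Gaussian noise; each outcome is
    linear in all predictor columns (dummy-coded categoricals included)
    plus Gaussian noise.  Per-wave observations add transient noise with SD
    ``wave_noise_sd`` and MCAR missingness at ``missing_rate``.
    """

    n_individuals: int = 4000
    n_pcs: int = 10
    n_waves: int = 3
    ascribed_spec: tuple[AscribedVar, ...] = _DEFAULT_ASCRIBED
    pgi_names: tuple[str, ...] = _PGI_NAMES
    ascribed_corr: Mapping[tuple, float] = field(
        default_factory=lambda: dict(_DEFAULT_ASCRIBED_CORR)
    )
    pgi_corr_default: float = 0.10
    pgi_corr: Mapping[tuple, float] = field(
        default_factory=lambda: dict(_DEFAULT_PGI_CORR)
    )
    cross_block_corr: Mapping[tuple, float] = field(
        default_factory=lambda: dict(_DEFAULT_CROSS)
    )
    skill_loadings: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_SKILL_LOADINGS.items()}
    )
    skill_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SKILL_NOISE)
    )
    outcome_betas: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_OUTCOME_BETAS.items()}
    )
    outcome_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_OUTCOME_NOISE)
    )
    wave_noise_sd: float = 0.10
    missing_rate: float = 0.05
    exp_outcomes: tuple[str, ...] = ("income",)
    exp_location: float = 7.8
    exp_scale: float = 0.5
    seed: int = 0

    # ---- column bookkeeping -------------------------------------------------

    @property
    def ascribed_cont(self) -> list[str]:
        return [v.name for v in self.ascribed_spec if v.kind == "continuous"]

    @property
    def categoricals(self) -> list[AscribedVar]:
        return [v for v in self.ascribed_spec if v.kind == "categorical"]

    @property
    def dummy_cols(self) -> list[str]:
        return [d for v in self.categoricals for d in v.dummy_names()]

    @property
    def pc_names(self) -> list[str]:
        return [f"pc{i:02d}" for i in range(1, self.n_pcs + 1)]

    @property
    def skill_names(self) -> list[str]:
        return list(self.skill_loadings)

    @property
    def base_cols(self) -> list[str]:
        """Jointly-Gaussian continuous block: ascribed + PGIs + PCs."""
        return self.ascribed_cont + list(self.pgi_names) + self.pc_names

    def predictor_cols(self) -> list[str]:
        """All predictor columns in canonical order."""
        return (
            self.ascribed_cont
            + self.dummy_cols
            + self.pc_names
            + list(self.pgi_names)
            + self.skill_names
        )

    def role_of(self, col: str) -> str:
        if col in self.ascribed_cont or col in self.dummy_cols:
            return "ascribed"
        if col in self.pc_names:
            return "pc"
        if col in self.pgi_names:
            return "pgi"
        if col in self.skill_names:
            return "skill"
        raise KeyError(col)

    @property
    def outcomes(self) -> list[str]:
        return list(self.outcome_betas)

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise SynthParamsError("n_individuals must be >= 2")
        if self.n_waves < 1:
            raise SynthParamsError("n_waves must be >= 1")
        for name, sd in {
            "wave_noise_sd": self.wave_noise_sd,
            **{f"skill_noise_sd[{k}]": v for k, v in self.skill_noise_sd.items()},
            **{f"outcome_noise_sd[{k}]": v for k, v in self.outcome_noise_sd.items()},
        }.items():
            if sd < 0:
                raise SynthParamsError(f"{name} must be >= 0, got {sd}")
        if not 0 <= self.missing_rate < 1:
            raise SynthParamsError("missing_rate must be in [0, 1)")
        names = [v.name for v in self.ascribed_spec]
        if len(set(names)) != len(names):
            raise SynthParamsError("duplicate ascribed variable names")
        cont = set(self.ascribed_cont)
        for (a, b) in self.cross_block_corr:
            if a not in cont or b not in self.pgi_names:
                raise SynthParamsError(
                    "cross_block_corr keys must pair a continuous ascribed "
                    f"variable with a PGI; got {(a, b)} (categorical ascribed "
                    "variables are generated independently of the continuous "
                    "block so their dummy moments stay exact)"
                )
        missing_sd = set(self.skill_loadings) - set(self.skill_noise_sd)
        if missing_sd:
            raise SynthParamsError(f"skills without a noise SD: {sorted(missing_sd)}")
        for out, betas in self.outcome_betas.items():
            unknown = set(betas) - set(self.predictor_cols())
            if unknown:
                raise SynthParamsError(
                    f"outcome {out!r} has betas on unknown columns: {sorted(unknown)}"
                )
            if out not in self.outcome_noise_sd:
                raise SynthParamsError(f"outcome {out!r} has no noise SD")
        # PSD check happens here so invalid correlation inputs fail fast
        build_covariance(self)


def default_params(n_individuals: int = 4000, seed: int = 0, **overrides) -> SynthParams:
    """The calibrated default scenario (see module docstring)."""
    return SynthParams(n_individuals=n_individuals, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def _base_correlation(params: SynthParams) -> pd.DataFrame:
    cols = params.base_cols
    C = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)

    def put(a: str, b: str, r: float) -> None:
        if a not in C.index or b not in C.index:
            raise SynthParamsError(f"correlation names unknown: {(a, b)}")
        if not -1 < r < 1:
            raise SynthParamsError(f"correlation out of range for {(a, b)}: {r}")
        C.loc[a, b] = C.loc[b, a] = r

    for (a, b), r in params.ascribed_corr.items():
        put(a, b, r)
    pg = list(params.pgi_names)
    for i, a in enumerate(pg):
        for b in pg[i + 1:]:
            r = params.pgi_corr.get((a, b), params.pgi_corr.get((b, a),
                                    params.pgi_corr_default))
            put(a, b, r)
    for (a, b), r in params.cross_block_corr.items():
        put(a, b, r)

    eigs = np.linalg.eigvalsh(C.to_numpy())
    if eigs.min() < -1e-8:
        raise SynthParamsError(
            "implied covariance of the continuous block (ascribed x PGI x PC "
            f"correlations) is not positive semi-definite (min eigenvalue "
            f"{eigs.min():.3e})"
        )
    return C


def _skill_loading_matrix(params: SynthParams) -> pd.DataFrame:
    base = params.base_cols
    L = pd.DataFrame(0.0, index=params.skill_names, columns=base)
    for s, loads in params.skill_loadings.items():
        for v, w in loads.items():
            if v not in base:
                raise SynthParamsError(
                    f"skill {s!r} loads on unknown base variable {v!r}"
                )
            L.loc[s, v] = w
    return L


def build_covariance(params: SynthParams) -> pd.DataFrame:
    """Exact covariance of all predictor columns (dummies via their
    indicator moments).

    The matrix is symmetric PSD with unit diagonal for the standardized
    continuous block; dummy columns have variance p(1-p) and within-variable
    covariance -p_i p_j; skill rows follow from their structural equations.
    """
    C = _base_correlation(params)
    L = _skill_loading_matrix(params)
    cols = params.predictor_cols()
    S = pd.DataFrame(0.0, index=cols, columns=cols)

    base = params.base_cols
    S.loc[base, base] = C.to_numpy()

    for v in params.categoricals:
        order = sorted(v.levels)
        p = {lvl: v.probs[v.levels.index(lvl)] for lvl in v.levels}
        dums = v.dummy_names()
        for i, di in enumerate(dums):
            pi = p[order[i + 1]]
            S.loc[di, di] = pi * (1 - pi)
            for dj in dums[i + 1:]:
                pj = p[order[dums.index(dj) + 1]]
                S.loc[di, dj] = S.loc[dj, di] = -pi * pj

    if params.skill_names:
        Lm = L.to_numpy()
        Cb = C.to_numpy()
        cross = Lm @ Cb  # skills x base
        skills = params.skill_names
        S.loc[skills, base] = cross
        S.loc[base, skills] = cross.T
        noise = np.array([params.skill_noise_sd[s] ** 2 for s in skills])
        S.loc[skills, skills] = Lm @ Cb @ Lm.T + np.diag(noise)

    return S


def _beta_vector(params: SynthParams, outcome: str) -> np.ndarray:
    if outcome not in params.outcome_betas:
        raise KeyError(f"unknown outcome {outcome!r}")
    betas = params.outcome_betas[outcome]
    return np.array([betas.get(c, 0.0) for c in params.predictor_cols()])


ROLE_SETS = ("ascribed", "pc", "pgi", "skill")


def _subset_cols(params: SynthParams, subset) -> list[str]:
    cols: list[str] = []
    all_cols = set(params.predictor_cols())
    for item in subset:
        if item in ROLE_SETS:
            cols.extend(
                c for c in params.predictor_cols() if params.role_of(c) == item
            )
        elif item in all_cols:
            cols.append(item)
        else:
            raise KeyError(f"subset entry {item!r} is neither a role nor a column")
    seen: set[str] = set()
    return [c for c in cols if not (c in seen or seen.add(c))]


def population_r2(params: SynthParams, outcome: str, subset) -> float:
    """Population R2 of the best linear predictor of ``outcome`` from a
    subset of predictors.

    ``subset`` mixes role names ("ascribed", "pc", "pgi", "skill") and
    explicit column names.  Computed purely from the structural covariance:
    R2 = sigma_sy' Sigma_ss^{-1} sigma_sy / Var(y).  A singular subset
    covariance falls back to the pseudo-inverse with a warning.
    """
    Sigma = build_covariance(params)
    beta = _beta_vector(params, outcome)
    var_y = float(beta @ Sigma.to_numpy() @ beta) + params.outcome_noise_sd[outcome] ** 2
    if var_y == 0.0:
        return 0.0
    cols = _subset_cols(params, subset)
    if not cols:
        return 0.0
    S = Sigma.loc[cols, cols].to_numpy()
    c = Sigma.loc[cols, :].to_numpy() @ beta
    eigs = np.linalg.eigvalsh(S)
    if eigs.min() < 1e-10 * max(eigs.max(), 1.0):
        warnings.warn(
            f"singular subset covariance for {cols}; using pseudo-inverse",
            UserWarning,
            stacklevel=2,
        )
        b = np.linalg.pinv(S) @ c
    else:
        b = linalg.solve(S, c, assume_a="pos")
    r2 = float(c @ b) / var_y
    return float(np.clip(r2, 0.0, 1.0))


@dataclass(frozen=True)
class OutcomeTruth:
    r2_radical: float
    r2_liberal_conditional: float
    r2_liberal_unconditional: float
    r2_talents_only: float

    def __post_init__(self) -> None:
        vals = (
            self.r2_radical,
            self.r2_liberal_conditional,
            self.r2_liberal_unconditional,
            self.r2_talents_only,
        )
        if not all(-1e-12 <= v <= 1 + 1e-12 for v in vals):
            raise ValueError(f"R2 values outside [0,1]: {vals}")
        if self.r2_radical < self.r2_liberal_unconditional - 1e-10:
            raise ValueError("radical R2 below unconditional liberal R2")
        if self.r2_radical < self.r2_talents_only - 1e-10:
            raise ValueError("radical R2 below talents-only R2")


@dataclass(frozen=True)
class GroundTruth:
    """Population decomposition per outcome for one talent measure."""

    talent_measure: str
    per_outcome: Mapping[str, OutcomeTruth]

    def to_dict(self) -> dict:
        return {
            "talent_measure": self.talent_measure,
            "per_outcome": {
                o: vars(t).copy() for o, t in self.per_outcome.items()
            },
        }


def ground_truth_decomposition(
    params: SynthParams, talent_measure: str = "pgi"
) -> GroundTruth:
    """Population radical / conditional-liberal / unconditional-liberal R2.

    radical = R2(ascribed + PCs + talents); talents-only = R2(talents);
    conditional liberal = radical - talents-only (semipartial identity,
    exact by construction); unconditional liberal = R2(ascribed + PCs).
    """
    if talent_measure not in ("pgi", "skill"):
        raise ValueError("talent_measure must be 'pgi' or 'skill'")
    out = {}
    for o in params.outcomes:
        radical = population_r2(params, o, ["ascribed", "pc", talent_measure])
        talents = population_r2(params, o, [talent_measure])
        uncond = population_r2(params, o, ["ascribed", "pc"])
        out[o] = OutcomeTruth(
            r2_radical=radical,
            r2_liberal_conditional=radical - talents,
            r2_liberal_unconditional=uncond,
            r2_talents_only=talents,
        )
    return GroundTruth(talent_measure=talent_measure, per_outcome=out)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _psd_sqrt(C: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_cohort(
    params: SynthParams, seed: int | None = None
) -> tuple[pd.DataFrame, RoleMap]:
    """Draw a long-format cohort (individual x wave) and its role map.

    Deterministic given the seed (defaults to ``params.seed``).  Child RNG
    streams are spawned per component in a fixed order, so enlarging one
    block never perturbs draws in another.  Ages at first measurement are
    derived from the birth-year latent and spill slightly outside 25-65 to
    exercise the working-age filter downstream.
    """
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    s_base, s_cat, s_skill, s_out, s_wave, s_miss = ss.spawn(6)

    n = params.n_individuals
    base_cols = params.base_cols
    C = _base_correlation(params).to_numpy()
    z = np.random.default_rng(s_base).standard_normal((n, len(base_cols)))
    z = z @ _psd_sqrt(C).T
    base = pd.DataFrame(z, columns=base_cols)

    rng_cat = np.random.default_rng(s_cat)
    cat_labels: dict[str, np.ndarray] = {}
    for v in params.categoricals:
        latent = rng_cat.standard_normal(n)
        cuts = stats.norm.ppf(np.cumsum(v.probs)[:-1])
        idx = np.searchsorted(cuts, latent)
        cat_labels[v.name] = np.array(v.levels, dtype=object)[idx]

    dummies = pd.DataFrame(index=base.index)
    for v in params.categoricals:
        order = sorted(v.levels)
        for lvl in order[1:]:
            dummies[f"{v.name}={lvl}"] = (cat_labels[v.name] == lvl).astype(float)

    rng_skill = np.random.default_rng(s_skill)
    L = _skill_loading_matrix(params)
    skills = pd.DataFrame(
        base[params.base_cols].to_numpy() @ L.to_numpy().T,
        columns=params.skill_names,
    )
    for s in params.skill_names:
        skills[s] += params.skill_noise_sd[s] * rng_skill.standard_normal(n)

    design = pd.concat([base, dummies, skills], axis=1)
    rng_out = np.random.default_rng(s_out)
    latent_out = {}
    for o in params.outcomes:
        betas = params.outcome_betas[o]
        y = np.zeros(n)
        for colname, b in betas.items():
            y += b * design[colname].to_numpy()
        y += params.outcome_noise_sd[o] * rng_out.standard_normal(n)
        latent_out[o] = y

    # age at first outcome measurement: centered mid-career, younger birth
    # year -> younger age, tails beyond the 25-65 working-age band
    yob = base[params.ascribed_cont[0]].to_numpy() if params.ascribed_cont else np.zeros(n)
    age = np.clip(np.round(45.0 - 10.0 * yob), 18, 80)

    rng_wave = np.random.default_rng(s_wave)
    rng_miss = np.random.default_rng(s_miss)
    wave_cols = params.outcomes + params.skill_names
    rows = []
    for w in range(1, params.n_waves + 1):
        rec = pd.DataFrame({"id": np.arange(1, n + 1), "wave": w, "age": age})
        for v in params.categoricals:
            rec[v.name] = cat_labels[v.name]
        for c in params.ascribed_cont:
            rec[c] = base[c].to_numpy()
        for c in params.pc_names:
            rec[c] = base[c].to_numpy()
        for c in params.pgi_names:
            rec[c] = base[c].to_numpy()
        for c in params.skill_names:
            obs = skills[c].to_numpy() + params.wave_noise_sd * rng_wave.standard_normal(n)
            rec[c] = obs
        for o in params.outcomes:
            obs = latent_out[o] + params.wave_noise_sd * rng_wave.standard_normal(n)
            if o in params.exp_outcomes:
                obs = np.exp(params.exp_location + params.exp_scale * obs)
            rec[o] = obs
        if params.missing_rate > 0:
            for c in wave_cols:
                mask = rng_miss.random(n) < params.missing_rate
                rec.loc[mask, c] = np.nan
        rows.append(rec)
    long = pd.concat(rows, ignore_index=True)

    mapping = {"id": "id", "wave": "wave", "age": "age"}
    for v in params.ascribed_spec:
        mapping[v.name] = "ascribed"
    for c in params.pc_names:
        mapping[c] = "pc"
    for c in params.pgi_names:
        mapping[c] = "pgi"
    for c in params.skill_names:
        mapping[c] = "skill"
    for o in params.outcomes:
        mapping[o] = "outcome"
    return long, RoleMap(mapping)
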