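"""Run configuration and the simulate -> preprocess -> estimate -> report
pipeline, with a provenance manifest so every run is self-describing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .decomposition import BagSpec, bag_iop, draws_to_frame
from .inference import ComparisonCell, ComparisonFamily, assemble_table, figure_data
from .preprocess import FilterCriteria, RoleMap, load_table, prepare
from .selection import LassoConfig

CONFIG_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible estimation run needs."""

    data: str
    rolemap: str
    output_dir: str
    talent_measures: tuple[str, ...] = ("pgi", "skill")
    outcomes: tuple[str, ...] = ()  # empty = all outcomes in the role map
    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    age_range: tuple[float, float] | None = None
    exclude_ids: tuple = ()
    log_columns: tuple[str, ...] = ()
    selection: LassoConfig = field(default_factory=LassoConfig)
    include_pcs_in_reduced: bool = False
    significance: str = "paired_t"
    config_version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.config_version != CONFIG_VERSION:
            raise ConfigError(
                f"config_version {self.config_version} unsupported "
                f"(expected {CONFIG_VERSION})"
            )
        bad = set(self.talent_measures) - {"pgi", "skill"}
        if bad:
            raise ConfigError(f"unknown talent measures: {sorted(bad)}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    # ---- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selection"] = dataclasses.asdict(self.selection)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sel = raw.pop("selection", {})
        if not isinstance(sel, dict):
            raise ConfigError("selection must be a mapping")
        sel_known = {f.name for f in dataclasses.fields(LassoConfig)}
        sel_unknown = set(sel) - sel_known
        if sel_unknown:
            raise ConfigError(f"unknown selection keys: {sorted(sel_unknown)}")
        for key in ("talent_measures", "outcomes", "exclude_ids", "log_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("age_range") is not None:
            raw["age_range"] = tuple(raw["age_range"])
        try:
            return cls(selection=LassoConfig(**sel), **raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("talent_measures", "outcomes", "exclude_ids", "log_columns"):
            d[key] = list(d[key])
        if d["age_range"] is not None:
            d["age_range"] = list(d["age_range"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full estimation run; returns the output directory.

    Writes: analysis_frame.csv, provenance.json, per-cell draw CSVs,
    estimates.json, results_table.csv, results_table.txt (display form),
    figure_data.csv, manifest.json.  Deterministic given the config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        rolemap = RoleMap.from_yaml(config.rolemap)
        long_table = load_table(config.data, rolemap)

        stage = "preprocess"
        criteria = FilterCriteria(
            exclude_ids=tuple(config.exclude_ids),
            age_range=config.age_range,
        )
        frame = prepare(long_table, rolemap, criteria, config.log_columns)
        frame.data.to_csv(out / "analysis_frame.csv")
        with open(out / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(frame.provenance, fh, indent=2)

        stage = "estimate"
        outcomes = list(config.outcomes) or rolemap.outcome_cols
        estimates = {}
        cells = []
        ss = np.random.SeedSequence(config.seed)
        cell_seeds = ss.spawn(len(config.talent_measures) * len(outcomes))
        k = 0
        for tm in config.talent_measures:
            run_frame = dataclasses.replace(
                frame, rolemap=RoleMap(dict(rolemap_mapping(frame)), tm)
            )
            for outcome in outcomes:
                seed_b = int(cell_seeds[k].generate_state(1)[0] % (2**31))
                k += 1
                draws, est = bag_iop(
                    run_frame, tm, outcome,
                    config.selection,
                    BagSpec(B=config.B, master_seed=seed_b),
                    include_pcs_in_reduced=config.include_pcs_in_reduced,
                )
                estimates[(tm, outcome)] = est
                df = draws_to_frame(draws)
                df.to_csv(out / f"draws_{tm}_{outcome}.csv", index=False)
                cells.append(
                    ComparisonCell(
                        tm, outcome,
                        df["r2_radical"].to_numpy(),
                        df["r2_liberal_conditional"].to_numpy(),
                    )
                )

        stage = "report"
        family = ComparisonFamily(tuple(cells), alpha=config.alpha)
        table = assemble_table(estimates, family, config.significance)
        table.data.to_csv(out / "results_table.csv", index=False)
        table.display().to_string(open(out / "results_table.txt", "w"), index=False)
        figure_data(estimates).to_csv(out / "figure_data.csv", index=False)

        est_json = {
            f"{tm}:{o}": {
                "quantities": {
                    q: dataclasses.asdict(qe) for q, qe in est.quantities.items()
                },
                "difference": est.difference,
                "difference_se": est.difference_se,
                "difference_p_raw": est.difference_p_raw,
                "B": est.B,
                "n_failed_replicates": est.n_failed_replicates,
            }
            for (tm, o), est in estimates.items()
        }
        with open(out / "estimates.json", "w", encoding="utf-8") as fh:
            json.dump(est_json, fh, indent=2, default=_json_default)

        manifest = {
            "software_version": __version__,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "input_checksums": {
                "data": _sha256(Path(config.data)),
                "rolemap": _sha256(Path(config.rolemap)),
            },
            "rows": {
                "input": int(len(long_table)),
                "analysis_frame": int(frame.n),
            },
            "outcomes": outcomes,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out


def rolemap_mapping(frame) -> dict:
    """Mapping restricted to columns that survived preprocessing."""
    return {
        c: r
        for c, r in frame.rolemap.mapping.items()
        if c in frame.data.columns or r in ("id", "wave", "age")
    }
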