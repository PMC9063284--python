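"""End-to-end seeded pipeline: generate -> components -> index -> survey -> tobit.

A :class:`RunConfig` (usually loaded from a YAML file with a versioned
schema) fully determines a run; re-running the same config writes
byte-identical artifacts, recorded in a ``manifest.json`` with per-stage
file checksums.  One scenario seed is expanded into per-stage substreams
inside the synthetic module, so stages can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from shapely.geometry import Point

from . import __version__
from .components import COMPONENTS, compute_components
from .grids import write_ascii_grid
from .index import build_index_table, correlation_matrix
from .survey import apply_exclusions
from .synthetic import SyntheticScenario, generate_landscape, generate_survey
from .tobit import (MODEL2_CONFOUNDERS, attenuation_analysis, fit_and_report)
from .vectors import write_geojson

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
STAGES = ("generate", "components", "index", "survey", "tobit")

_VALID_KEYS = {"schema_version", "seed", "scenario", "scales", "outcomes",
               "models", "log_level"}
_VALID_SCALES = {"150", "500", "1000", "neighbourhood"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 1
    scenario: dict = field(default_factory=dict)
    scales: list = field(default_factory=lambda: [150])
    outcomes: list = field(default_factory=lambda: ["walk_minutes_total"])
    models: list = field(default_factory=lambda: [1, 2])
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _VALID_KEYS
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        version = raw.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"config schema_version {version} unsupported "
                             f"(expected {SCHEMA_VERSION})")
        cfg = cls(
            seed=int(raw.get("seed", 1)),
            scenario=dict(raw.get("scenario") or {}),
            scales=list(raw.get("scales") or [150]),
            outcomes=list(raw.get("outcomes") or ["walk_minutes_total"]),
            models=list(raw.get("models") or [1, 2]),
            log_level=str(raw.get("log_level", "INFO")),
        )
        for s in cfg.scales:
            if str(s) not in _VALID_SCALES:
                raise ValueError(f"invalid scale {s!r}; choose from "
                                 f"{sorted(_VALID_SCALES)}")
        for m in cfg.models:
            if m not in (1, 2):
                raise ValueError(f"invalid model {m!r}; choose 1 or 2")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_mapping(raw)

    def build_scenario(self) -> SyntheticScenario:
        return SyntheticScenario(seed=self.seed, **self.scenario)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all five stages; returns the artifact directory.

    A stage failure raises ``RuntimeError`` naming the stage; artifacts of
    completed stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = config.build_scenario()
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": {"scales": [str(s) for s in config.scales],
                   "outcomes": config.outcomes, "models": config.models,
                   "scenario": config.scenario},
        "stages": {},
    }

    state: dict = {}

    def _stage(name, fn):
        try:
            files = fn()
        except Exception as exc:
            _write_manifest(out, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "files": {f.name: _sha256(f) for f in sorted(files)}}

    _stage("generate", lambda: _run_generate(scenario, out, state))
    _stage("components", lambda: _run_components(config, out, state))
    _stage("index", lambda: _run_index(config, out, state))
    _stage("survey", lambda: _run_survey(scenario, config, out, state))
    _stage("tobit", lambda: _run_tobit(config, out, state))
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


def _run_generate(scenario, out: Path, state) -> list[Path]:
    bundle = generate_landscape(scenario)
    state["bundle"] = bundle
    files = []
    for name, layer in (("population", bundle.population),
                        ("landuse", bundle.landuse),
                        ("sidewalk", bundle.sidewalk)):
        p = out / f"{name}.asc"
        write_ascii_grid(layer, p)
        files.append(p)
    p = out / "roads.geojson"
    write_geojson([(g, {"road_class": c}) for g, c in bundle.roads], p)
    files.append(p)
    p = out / "transit.geojson"
    write_geojson([(Point(x, y), {}) for x, y in bundle.transit_points], p)
    files.append(p)
    p = out / "neighbourhoods.geojson"
    write_geojson([(poly, {"zone_id": z}) for z, poly in bundle.neighbourhoods], p)
    files.append(p)
    p = out / "centroids.csv"
    _write_csv(bundle.centroids, p)
    files.append(p)
    return files


def _run_components(config, out: Path, state) -> list[Path]:
    files = []
    state["components"] = {}
    for scale in config.scales:
        scale_key = str(scale)
        table = compute_components(state["bundle"],
                                   scale if scale_key == "neighbourhood"
                                   else float(scale))
        state["components"][scale_key] = table
        p = out / f"components_{scale_key}.csv"
        _write_csv(table, p)
        files.append(p)
    return files


def _run_index(config, out: Path, state) -> list[Path]:
    files = []
    state["index"] = {}
    for scale_key, table in state["components"].items():
        idx = build_index_table(table)
        state["index"][scale_key] = idx
        p = out / f"index_{scale_key}.csv"
        _write_csv(idx, p)
        files.append(p)
        r, _ = correlation_matrix(table, list(COMPONENTS))
        p = out / f"correlation_{scale_key}.csv"
        r.round(10).to_csv(p)
        files.append(p)
    return files


def _run_survey(scenario, config, out: Path, state) -> list[Path]:
    primary = str(config.scales[0])
    respondents, trips = generate_survey(scenario, state["index"][primary])
    kept, excl_log = apply_exclusions(respondents)
    state["respondents"] = kept
    files = []
    for name, df in (("respondents", respondents), ("trips", trips),
                     ("respondents_included", kept),
                     ("exclusion_log", excl_log)):
        p = out / f"{name}.csv"
        _write_csv(df, p)
        files.append(p)
    return files


def _run_tobit(config, out: Path, state) -> list[Path]:
    primary = str(config.scales[0])
    data = state["respondents"]
    rows = []
    for outcome in config.outcomes:
        for model in config.models:
            conf = MODEL2_CONFOUNDERS if model == 2 else None
            fit, eff = fit_and_report(data, outcome, confounders=conf,
                                      model_label=f"Model {model}")
            rows.append({"outcome": outcome, "model": f"Model {model}",
                         "scale": primary,
                         "estimate_per_10": eff.estimate,
                         "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                         "n": fit.n_total, "n_censored": fit.n_censored,
                         "sigma": fit.sigma, "loglik": fit.loglik,
                         "converged": fit.converged})
    files = []
    p = out / "tobit_effects.csv"
    _write_csv(pd.DataFrame(rows), p)
    files.append(p)

    partial_cols = [c for c in state["index"][primary].columns
                    if c.startswith("partial_")]
    merged = data.merge(
        state["index"][primary][["unit_id", *partial_cols]], on="unit_id")
    att = attenuation_analysis(merged, config.outcomes[0], partial_cols)
    p = out / "attenuation.csv"
    _write_csv(att, p)
    files.append(p)
    return files
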