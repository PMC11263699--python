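"""Run configuration and artifact output.

A run configuration is a TOML or YAML file with a ``[model]`` block (preset
name or explicit rates) and an ``[experiment]`` block. ``run_experiment``
executes it and writes CSV results plus a JSON metadata sidecar; identical
config + seed reproduce bit-identical CSV output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .engine import DEFAULT_DT, DEFAULT_SAMPLE_EVERY, TimeSeries, simulate, \
    simulate_single_species
from .observables import extinction_stats, scan
from .params import ModelParams, PRESETS, SingleSpeciesParams

_MODEL_KEYS = {
    "preset", "p1", "p2", "p3", "p4", "b", "K", "w",
    "replication_dist", "poisson_convention", "species",
}
_EXPERIMENT_KEYS = {
    "kind", "t_max", "seed", "dt", "sample_every", "init", "init_mode",
    "axis", "values", "metric", "n_reps", "burn_in",
}
_KINDS = ("simulate", "simulate_single", "scan", "extinction")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams | SingleSpeciesParams
    experiment: dict[str, Any]
    raw: dict[str, Any]

    @property
    def kind(self) -> str:
        return self.experiment["kind"]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _read_raw(path: Path) -> dict[str, Any]:
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ConfigError(f"unsupported config format: {path.suffix!r}")


def _build_model(section: dict[str, Any]) -> ModelParams | SingleSpeciesParams:
    unknown = set(section) - _MODEL_KEYS
    if unknown:
        raise ConfigError(f"unknown [model] keys: {sorted(unknown)}")
    section = dict(section)
    species = section.pop("species", 2)
    if (
        section.get("replication_dist", "uniform") == "uniform"
        and "w" not in section
    ):
        raise ConfigError("w is required for the uniform replication_dist")
    if species == 1:
        section.pop("preset", None)
        return SingleSpeciesParams(**section)
    preset = section.pop("preset", None)
    if preset is not None:
        if any(k in section for k in ("p1", "p2", "p3", "p4")):
            raise ConfigError("give either preset or explicit p1..p4, not both")
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}")
        p1, p2, p3, p4 = PRESETS[preset]
        return ModelParams(p1=p1, p2=p2, p3=p3, p4=p4, **section)
    missing = {"p1", "p2", "p3", "p4"} - set(section)
    if missing:
        raise ConfigError(f"missing [model] keys: {sorted(missing)}")
    return ModelParams(**section)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration; unknown keys are rejected."""
    path = Path(path)
    raw = _read_raw(path)
    unknown = set(raw) - {"model", "experiment"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    if "model" not in raw or "experiment" not in raw:
        raise ConfigError("config needs [model] and [experiment] sections")
    model = _build_model(raw["model"])
    exp = dict(raw["experiment"])
    unknown = set(exp) - _EXPERIMENT_KEYS
    if unknown:
        raise ConfigError(f"unknown [experiment] keys: {sorted(unknown)}")
    kind = exp.setdefault("kind", "simulate")
    if kind not in _KINDS:
        raise ConfigError(f"experiment kind must be one of {_KINDS}")
    if kind == "simulate_single" and not isinstance(model, SingleSpeciesParams):
        raise ConfigError("simulate_single requires [model] species = 1")
    exp.setdefault("seed", 0)
    exp.setdefault("t_max", 100.0)
    exp.setdefault("dt", DEFAULT_DT)
    exp.setdefault("sample_every", DEFAULT_SAMPLE_EVERY)
    return RunConfig(model=model, experiment=exp, raw=raw)


def _write_timeseries(ts: TimeSeries, out: Path) -> None:
    df = ts.to_frame()
    df.to_csv(out, index=False, float_format="%.10g")


def run_experiment(config: RunConfig, output_dir: str | Path) -> dict[str, Path]:
    """Execute a run configuration and write its artifact bundle.

    Returns the written paths. Output is deterministic for a fixed config and
    seed; partial files are removed if the run fails.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp = config.experiment
    written: list[Path] = []
    t0 = time.time()
    meta: dict[str, Any] = {
        "package_version": __version__,
        "config": config.raw,
        "config_digest": config.digest(),
        "kind": config.kind,
        "seed": exp["seed"],
        "dt": exp["dt"],
    }
    try:
        if config.kind in ("simulate", "simulate_single"):
            fn = simulate if config.kind == "simulate" else simulate_single_species
            kwargs = dict(
                t_max=exp["t_max"],
                sample_every=exp["sample_every"],
                rng_seed=exp["seed"],
                dt=exp["dt"],
            )
            if "init" in exp:
                kwargs["init"] = exp["init"]
            if "init_mode" in exp:
                kwargs["init_mode"] = exp["init_mode"]
            ts = fn(config.model, **kwargs)
            csv_path = out / "timeseries.csv"
            _write_timeseries(ts, csv_path)
            written.append(csv_path)
            meta["status"] = ts.status
            meta["t_end"] = ts.meta["t_end"]
        elif config.kind == "scan":
            df = scan(
                config.model,
                axis=exp["axis"],
                values=exp["values"],
                metric=exp.get("metric", "cv"),
                n_reps=exp.get("n_reps", 2),
                rng_seed=exp["seed"],
                t_max=exp["t_max"],
                burn_in=exp.get("burn_in"),
                sample_every=exp["sample_every"],
            )
            csv_path = out / "scan.csv"
            df.drop(columns=["seeds"]).to_csv(
                csv_path, index=False, float_format="%.10g"
            )
            written.append(csv_path)
            meta["status"] = "completed"
            meta["scan_attrs"] = {
                k: v for k, v in df.attrs.items() if k != "params_base"
            }
        else:  # extinction
            res = extinction_stats(
                config.model,
                n_reps=exp.get("n_reps", 10),
                t_max=exp["t_max"],
                rng_seed=exp["seed"],
            )
            ext_path = out / "extinction.json"
            ext_path.write_text(
                json.dumps(
                    {
                        "n_reps": res.n_reps,
                        "n_extinct": res.n_extinct,
                        "probability": res.probability,
                        "mean_time_to_extinction": res.mean_time_to_extinction,
                        "censored": res.censored,
                        "extinct_species": list(res.extinct_species),
                        "times": list(res.times),
                    },
                    indent=2,
                )
            )
            written.append(ext_path)
            meta["status"] = "completed"
        meta["wall_clock_s"] = round(time.time() - t0, 3)
        meta_path = out / "meta.json"
        meta_path.write_text(json.dumps(meta, indent=2, default=str))
        written.append(meta_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {p.name: p for p in written}
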