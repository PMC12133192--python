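"""Run configuration and tabular result I/O.

A run is described by a single human-editable YAML file with four sections
(``stimulus``, ``model``, ``experiment``, ``output``) plus a base ``seed``
and ``log_level``.  Unknown keys are rejected and numeric ranges are
validated on load; ``default_config()`` returns a fully populated default
and ``pcmotion init-config`` writes it to disk.  All sweep outputs are tidy
CSV (per-trial records plus a per-cell summary alongside).
"""

from __future__ import annotations

import copy
import io
import json
from dataclasses import dataclass

import pandas as pd
import yaml

from .engine import ModelConfig
from .stimuli import (
    Stimulus,
    generate_duncker,
    generate_johansson,
    generate_rdk,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "default_config",
    "load_config",
    "write_config",
    "write_results",
    "read_results",
    "make_fixture",
]

RESULTS_FORMAT = "pcmotion-results v1"


class ConfigError(ValueError):
    """Invalid configuration file: unknown key or out-of-range value."""


_GENERATORS = {
    "johansson": generate_johansson,
    "duncker": generate_duncker,
    "rdk": generate_rdk,
}

_MODEL_DEFAULTS = {
    "gamma": None,
    "eta": None,
    "eta_scale": 10.0,
    "inner_iters": 50,
    "theta1": None,
    "theta1_scale": 0.5,
    "theta2": 0.5,
    "window_ms": 30.0,
    "diameter": None,
    "strength": 1.0,
    "n_shared": 1,
    "max_frames": None,
}

_EXPERIMENT_DEFAULTS = {
    "n_trials": 30,
    "ratio": 0.4,
    "window_ms": 30.0,
    "ratios": [0.2, 0.4, 0.6, 0.8, 1.0],
    "durations_ms": [0.0, 10.0, 30.0, 50.0, 70.0, 90.0],
    "theta1_grid": [0.002, 0.005, 0.02],
    "ratio_grid": [0.2, 0.4, 0.8],
    "densities": [250.0, 500.0, 1000.0],
    "sustain_frames": 10,
    "stability_tol": 0.05,
    "rdk": {
        "n_dots": 200,
        "coherent_velocity": 0.01,
        "noise_velocity": 0.01,
        "dt": 0.05,
        "duration": 10.0,
    },
}


def default_config() -> dict:
    """A fully populated default configuration."""
    return {
        "seed": 0,
        "log_level": "INFO",
        "stimulus": {
            "generator": "rdk",
            "params": {
                "n_dots": 200,
                "signal_ratio": 0.5,
                "coherent_velocity": 0.01,
                "noise_velocity": 0.01,
                "dt": 0.05,
                "duration": 10.0,
            },
        },
        "model": copy.deepcopy(_MODEL_DEFAULTS),
        "experiment": copy.deepcopy(_EXPERIMENT_DEFAULTS),
        "output": {"dir": "."},
    }


def _check_keys(section: dict, allowed: dict, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown key {path}.{key!r}")


@dataclass
class RunConfig:
    """Validated run configuration (see module docs for the schema)."""

    raw: dict

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def log_level(self) -> str:
        return str(self.raw["log_level"])

    @property
    def output_dir(self) -> str:
        return str(self.raw["output"]["dir"])

    @property
    def experiment(self) -> dict:
        return self.raw["experiment"]

    def model_config(self, seed: int | None = None) -> ModelConfig:
        m = self.raw["model"]
        return ModelConfig(
            seed=self.seed if seed is None else seed,
            **{k: m[k] for k in _MODEL_DEFAULTS},
        )

    def make_stimulus(self, seed: int | None = None) -> Stimulus:
        sec = self.raw["stimulus"]
        gen = _GENERATORS[sec["generator"]]
        params = dict(sec["params"])
        if sec["generator"] == "rdk":
            params.setdefault("seed", self.seed if seed is None else seed)
        return gen(**params)


def validate_config(raw: dict) -> RunConfig:
    """Merge onto defaults, reject unknown keys, and range-check values."""
    base = default_config()
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, base, "config")
    merged = copy.deepcopy(base)
    for key, value in raw.items():
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config.{key} must be a mapping")
            if key == "stimulus":
                _check_keys(value, base[key], key)
                merged[key].update(copy.deepcopy(value))
            else:
                _check_keys(value, base[key], key)
                for k2, v2 in value.items():
                    merged[key][k2] = copy.deepcopy(v2)
        else:
            merged[key] = value

    gen = merged["stimulus"]["generator"]
    if gen not in _GENERATORS:
        raise ConfigError(
            f"stimulus.generator must be one of {sorted(_GENERATORS)}, got {gen!r}"
        )
    m = merged["model"]
    for key, low in [("theta1", 0.0), ("theta2", 0.0), ("window_ms", 0.0),
                     ("strength", 0.0), ("gamma", 0.0), ("eta", 0.0),
                     ("diameter", 0.0)]:
        v = m.get(key)
        if v is not None and v < low:
            raise ConfigError(f"model.{key} must be >= {low}, got {v}")
    if not 0.0 <= m["theta2"] <= 1.0:
        raise ConfigError(f"model.theta2 must be in [0, 1], got {m['theta2']}")
    if not 0.0 <= m["strength"] <= 1.0:
        raise ConfigError(f"model.strength must be in [0, 1], got {m['strength']}")
    if m["inner_iters"] < 1:
        raise ConfigError("model.inner_iters must be >= 1")
    e = merged["experiment"]
    if e["n_trials"] < 1:
        raise ConfigError("experiment.n_trials must be >= 1")
    if not 0.0 <= e["ratio"] <= 1.0:
        raise ConfigError("experiment.ratio must be in [0, 1]")
    cfg = RunConfig(raw=merged)
    cfg.model_config()  # constructor re-validates ranges
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def write_config(config: RunConfig | dict, path) -> None:
    raw = config.raw if isinstance(config, RunConfig) else config
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Sweep results I/O


def write_results(sweep_result, path) -> None:
    """Lossless tidy-CSV round trip of a sweep (records + summary alongside).

    The per-trial table goes to ``path`` with a versioned ``#`` header; the
    per-cell summary goes to ``path`` with a ``.summary.csv`` suffix.
    """
    header = {
        "format": RESULTS_FORMAT,
        "param_names": sweep_result.param_names,
        "meta": sweep_result.meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        sweep_result.data.to_csv(fh, index=False, float_format="%.17g")
    sweep_result.summary.to_csv(str(path) + ".summary.csv", index=False)


def read_results(path):
    """Read a sweep written by :func:`write_results`."""
    from .experiments import SweepResult

    comments = []
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                comments.append(line[1:].strip())
            else:
                body.write(line)
    body.seek(0)
    header = {}
    for c in comments:
        if c.startswith("{"):
            header = json.loads(c)
    if header.get("format") != RESULTS_FORMAT:
        raise ConfigError(
            f"unrecognised results format {header.get('format')!r}; "
            f"expected {RESULTS_FORMAT!r}"
        )
    data = pd.read_csv(body)
    if "converged" in data.columns:
        data["converged"] = data["converged"].astype(bool)
    return SweepResult(
        data=data,
        param_names=list(header["param_names"]),
        meta=dict(header.get("meta", {})),
    )


# ---------------------------------------------------------------------------
# Test fixtures


def make_fixture(name: str):
    """Deterministic miniature stimulus plus expected qualitative outcomes.

    Names: ``johansson-small``, ``duncker-small``, ``rdk-small``.  Returns
    ``(stimulus, expectations)`` where ``expectations`` is a machine-readable
    dict of properties the stimulus is built to satisfy.
    """
    if name == "johansson-small":
        stim = generate_johansson(duration=2.0)
        expected = {"n_dots": 3, "collinear": True, "labels": ["outer", "middle", "outer"]}
    elif name == "duncker-small":
        stim = generate_duncker(angular_speed=90.0, duration=4.0)
        expected = {"n_dots": 2, "rigid_radius": 10.0, "labels": ["hub", "rim"]}
    elif name == "rdk-small":
        stim = generate_rdk(n_dots=20, signal_ratio=0.5, duration=5.0, seed=1234)
        expected = {"n_dots": 20, "n_signal": 10, "coherence": 0.5}
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return stim, expected
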