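"""Experiment configuration files, fixtures, and run manifests.

Experiments are described by nested mappings (YAML or JSON) with one
section per model component. Loading is strict: unknown keys are
rejected and all defaults are resolved, so the echoed configuration
fully determines the run. A manifest (JSON) accompanies every CLI run
with the resolved configuration, seeds, version, wall times, and a
checksum inventory of the output files, sufficient to re-run the
experiment bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .params import DisorderSpec, NeuronTypeParams, preset, default_truncation

__all__ = ["load_config", "save_config", "resolve_config", "make_fixture",
           "RunManifest", "ConfigError"]

EXPERIMENTS = ("simulate_snn", "simulate_mf", "two_pop_snn", "regime_map",
               "bump", "reservoir", "entrain")


class ConfigError(ValueError):
    pass


def _check_keys(section: str, given: dict, allowed: dict) -> dict:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}")
    out = dict(allowed)
    out.update(given)
    return out


# allowed keys and defaults per section, by experiment
_SCHEMAS: dict[str, dict[str, dict[str, Any]]] = {
    "simulate_snn": {
        "population": {"cell_type": "rs", "kappa_override": None,
                       "delta_v": None, "disorder_family": "lorentzian"},
        "connectivity": {"n_neurons": 200, "topology": "random_sparse",
                         "coupling_prob": 0.2, "ring_exponent": 0.0,
                         "allow_self": False},
        "stimulus": {"baseline_current": 0.0, "segments": []},
        "integrator": {"dt": 0.01, "u_mode": "global"},
        "run": {"duration": 1000.0, "record_dt": 1.0},
    },
    "simulate_mf": {
        "population": {"cell_type": "rs", "kappa_override": None,
                       "delta_v": None},
        "run": {"duration": 1000.0, "dt": 0.01, "record_dt": 0.1,
                "input_pa": 0.0},
    },
    "two_pop_snn": {
        "population_a": {"cell_type": "rs", "kappa_override": None,
                         "delta_v": None, "disorder_family": "lorentzian",
                         "n_neurons": 100, "baseline_current": 60.0},
        "population_b": {"cell_type": "fs", "kappa_override": None,
                         "delta_v": None, "disorder_family": "lorentzian",
                         "n_neurons": 100, "baseline_current": 0.0},
        "coupling": {"coupling_prob": 0.2, "J_aa": 16.0, "J_ab": 16.0,
                     "J_ba": 4.0, "J_bb": 4.0},
        "integrator": {"dt": 0.01, "u_mode": "global"},
        "run": {"duration": 1000.0, "record_dt": 1.0},
    },
    "regime_map": {
        "population": {"cell_type": "rs", "kappa_override": None},
        "grid": {"input_min": 20.0, "input_max": 80.0, "input_n": 7,
                 "delta_min": 0.1, "delta_max": 2.0, "delta_n": 4},
        "detection": {"rate_threshold": 10.0, "osc_amplitude_min": 10.0,
                      "min_cycles": 5, "ramp_rate": 0.01,
                      "settle_time": 2000.0, "analysis_time": 1000.0},
    },
    "bump": {
        "population": {"cell_type": "rs", "kappa_override": None,
                       "disorder_family": "lorentzian"},
        "protocol": {"n_neurons": 2000, "coupling_prob": 0.2,
                     "ring_exponent": 1.5, "I_base": 30.0, "I_stim": 60.0,
                     "stim_on": 500.0, "stim_off": 1000.0,
                     "record_duration": 3000.0, "fs": 10.0,
                     "smooth_sigma": 200.0, "test_window": 200.0},
        "sweep": {"p_in": [0.25], "delta_v": [0.2, 1.5], "n_seeds": 10},
    },
    "reservoir": {
        "population": {"cell_type": "rs", "kappa_override": 100.0,
                       "disorder_family": "lorentzian"},
        "protocol": {"n_onsets": 50, "n_train": 40, "n_test": 10,
                     "burn_in": 2000.0, "post_onset": 250.0,
                     "onset_span": 250.0, "n_neurons": 2000,
                     "coupling_prob": 0.2, "ring_exponent": 0.75,
                     "pulse_width_frac": 0.25, "pulse_amp": 60.0,
                     "pulse_duration": 20.0, "feature_sigma": 10.0,
                     "feature_fs": 1.0},
        "sweep": {"regime_inputs": [45.0, 55.0, 70.0],
                  "delta_v": [0.1, 0.5, 1.0], "n_seeds": 10},
    },
    "entrain": {
        "population": {"cell_type": "rs", "kappa_override": 100.0},
        "forcing": {"I0": 60.0, "alpha": 4.0, "duration": 8000.0,
                    "discard": 2000.0},
        "grid": {"omega_min": 2.0, "omega_max": 16.0, "omega_n": 15,
                 "delta_v": [0.1, 1.0]},
    },
}


def resolve_config(raw: dict) -> dict:
    """Validate a raw mapping and fill in all defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    exp = raw.get("experiment")
    if exp not in EXPERIMENTS:
        raise ConfigError(
            f"experiment must be one of {EXPERIMENTS}, got {exp!r}")
    top = _check_keys("<top level>", raw,
                      {"experiment": None, "seed": 0,
                       **{k: {} for k in _SCHEMAS[exp]}})
    schema = _SCHEMAS[exp]
    out = {"experiment": exp, "seed": int(top.get("seed") or 0)}
    for section, allowed in schema.items():
        given = top.get(section) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        out[section] = _check_keys(section, given, allowed)
    _validate_values(out)
    return out


def _validate_values(cfg: dict) -> None:
    exp = cfg["experiment"]
    if exp == "bump":
        for p in cfg["sweep"]["p_in"]:
            if not (0 < p <= 1):
                raise ConfigError(f"p_in must be in (0, 1], got {p}")
    if exp == "reservoir":
        proto = cfg["protocol"]
        if proto["n_train"] + proto["n_test"] != proto["n_onsets"]:
            raise ConfigError("n_train + n_test must equal n_onsets")
    for section in cfg.values():
        if isinstance(section, dict):
            for key in ("coupling_prob",):
                if key in section and not (0 < section[key] <= 1):
                    raise ConfigError(f"{key} must be in (0, 1]")


def load_config(path: str | Path) -> dict:
    """Load, validate and default-resolve an experiment configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return resolve_config(raw)


def save_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def population_from_config(section: dict) -> NeuronTypeParams:
    return preset(section["cell_type"], section.get("kappa_override"))


def disorder_from_config(section: dict, params: NeuronTypeParams,
                         seed: int = 0) -> DisorderSpec:
    delta = section.get("delta_v")
    if delta is None:
        delta = params.delta_v
    low, high = default_truncation(params)
    return DisorderSpec(section.get("disorder_family", "lorentzian"),
                        params.vtheta_bar, float(delta), low, high, seed=seed)


def make_fixture(kind: str, seed: int = 0) -> dict:
    """Small ready-to-run configurations for tests and demos (< 30 s each)."""
    if kind == "tiny_rs":
        raw = {
            "experiment": "simulate_snn", "seed": seed,
            "population": {"cell_type": "rs", "delta_v": 0.5},
            "connectivity": {"n_neurons": 100, "topology": "random_sparse",
                             "coupling_prob": 0.2},
            "stimulus": {"baseline_current": 30.0,
                         "segments": [{"t_on": 200.0, "t_off": 600.0,
                                       "amplitude": 30.0, "waveform": "step"}]},
            "run": {"duration": 1000.0},
        }
    elif kind == "tiny_ring":
        raw = {
            "experiment": "bump", "seed": seed,
            "protocol": {"n_neurons": 200, "ring_exponent": 1.5,
                         "stim_on": 200.0, "stim_off": 500.0,
                         "record_duration": 1000.0, "test_window": 200.0},
            "sweep": {"p_in": [0.25], "delta_v": [0.2], "n_seeds": 1},
        }
    elif kind == "tiny_two_pop":
        raw = {
            "experiment": "two_pop_snn", "seed": seed,
            "population_a": {"cell_type": "rs", "n_neurons": 100,
                             "baseline_current": 60.0},
            "population_b": {"cell_type": "fs", "n_neurons": 100,
                             "baseline_current": 0.0},
            "run": {"duration": 500.0},
        }
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    return resolve_config(raw)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to every CLI run's outputs."""

    config: dict
    seed: int
    version: str = __version__
    wall_times: dict = dataclasses.field(default_factory=dict)
    outputs: dict = dataclasses.field(default_factory=dict)
    _t0: float = dataclasses.field(default_factory=time.perf_counter, repr=False)

    def stage_done(self, name: str) -> None:
        now = time.perf_counter()
        self.wall_times[name] = round(now - self._t0, 3)
        self._t0 = now

    def register_output(self, path: str | Path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path: str | Path) -> None:
        payload = {"config": self.config, "seed": self.seed,
                   "version": self.version, "wall_times": self.wall_times,
                   "outputs": self.outputs}
        Path(path).write_text(json.dumps(payload, indent=2))
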