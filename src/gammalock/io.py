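"""Configuration files and result serialization.

Configs are YAML (JSON being a YAML subset, .json files load too) with a
strict schema: unknown keys are rejected with the offending key named.
Results are written as CSV tables plus a JSON header, and a manifest
records input hashes, seeds and package versions so any output can be
regenerated from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coupled import CoupledTrajectory, GlobalPRCResult
from .coupling import GFunction
from .errors import ConfigError
from .meanfield import STATE_LABELS, LimitCycle, Trajectory
from .params import (
    CrossCoupling,
    DriveProtocol,
    PopulationParams,
    Pulse,
    SynapticCouplings,
)
from .prc import Z_LABELS, AdjointPRC, DirectPRC
from .presets import ConfigBundle, figure_preset
from .spiking import RateTrace, SpikeRaster

__all__ = ["load_config", "save_config", "write_outputs", "config_to_dict"]

_POP_KEYS = {"tau", "eta_bar", "delta", "size", "v_th", "v_reset"}
_COUP_KEYS = {"j_ee", "j_ei", "j_ie", "j_ii", "tau_s"}
_CROSS_KEYS = {"g_ee", "g_ie", "delay", "weak_threshold"}
_PULSE_KEYS = {"amplitude", "duration", "population"}
_TOP_KEYS = {"name", "preset", "e_params", "i_params", "couplings", "drive_e",
             "drive_i", "cross_coupling", "pulse", "duration", "step", "seed"}


def _check_keys(d: dict, allowed: set, where: str) -> None:
    for k in d:
        if k not in allowed:
            raise ConfigError(f"unknown key {k!r} in {where}")


def _drive_from(obj) -> DriveProtocol:
    if isinstance(obj, (int, float)):
        return DriveProtocol.constant(float(obj))
    if isinstance(obj, list):
        return DriveProtocol(tuple((float(t), float(v)) for t, v in obj))
    raise ConfigError("drive must be a number or a list of [start_ms, value] pairs")


def load_config(path) -> ConfigBundle:
    """Load and validate a config file, optionally layered over a preset."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> ConfigBundle:
    _check_keys(raw, _TOP_KEYS, "config root")
    if "preset" in raw:
        bundle = figure_preset(raw["preset"])
    else:
        bundle = ConfigBundle(
            name=raw.get("name", "custom"),
            e_params=PopulationParams(), i_params=PopulationParams(),
            couplings=SynapticCouplings(),
            drive_e=DriveProtocol.constant(0.0),
            drive_i=DriveProtocol.constant(0.0),
        )
    kwargs: dict = {}
    try:
        for side in ("e_params", "i_params"):
            if side in raw:
                _check_keys(raw[side], _POP_KEYS, side)
                kwargs[side] = replace(getattr(bundle, side), **raw[side])
        if "couplings" in raw:
            _check_keys(raw["couplings"], _COUP_KEYS, "couplings")
            kwargs["couplings"] = replace(bundle.couplings, **raw["couplings"])
        if "cross_coupling" in raw:
            _check_keys(raw["cross_coupling"], _CROSS_KEYS, "cross_coupling")
            base = bundle.cross_coupling or CrossCoupling()
            kwargs["cross_coupling"] = replace(base, **raw["cross_coupling"])
        if "pulse" in raw:
            _check_keys(raw["pulse"], _PULSE_KEYS, "pulse")
            base_p = bundle.pulse or Pulse()
            kwargs["pulse"] = replace(base_p, **raw["pulse"])
        for key in ("drive_e", "drive_i"):
            if key in raw:
                kwargs[key] = _drive_from(raw[key])
        for key in ("duration", "step", "seed", "name"):
            if key in raw:
                kwargs[key] = raw[key]
        return replace(bundle, **kwargs)
    except ConfigError:
        raise
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(bundle: ConfigBundle) -> dict:
    return {
        "name": bundle.name,
        "e_params": asdict(bundle.e_params),
        "i_params": asdict(bundle.i_params),
        "couplings": asdict(bundle.couplings),
        "drive_e": [list(seg) for seg in bundle.drive_e.segments],
        "drive_i": [list(seg) for seg in bundle.drive_i.segments],
        **({"cross_coupling": asdict(bundle.cross_coupling)}
           if bundle.cross_coupling else {}),
        **({"pulse": asdict(bundle.pulse)} if bundle.pulse else {}),
        "duration": bundle.duration,
        "step": bundle.step,
        "seed": bundle.seed,
    }


def save_config(bundle: ConfigBundle, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(bundle), fh, sort_keys=True)


def _frame_and_meta(result) -> tuple[pd.DataFrame, dict, str]:
    if isinstance(result, LimitCycle):
        df = pd.DataFrame(result.states, columns=list(STATE_LABELS))
        df.insert(0, "t", result.times)
        df.insert(0, "phase_index", np.arange(result.n_samples))
        return df, {"kind": "limit_cycle", "period_ms": result.period,
                    "closure_residual": result.residual}, "limit_cycle"
    if isinstance(result, AdjointPRC):
        df = pd.DataFrame(result.z, columns=list(Z_LABELS))
        df.insert(0, "t", result.times)
        df.insert(0, "phase", result.phases)
        return df, {"kind": "adjoint_prc", "period_ms": result.period,
                    "normalization_residual": result.normalization_residual,
                    "periodicity_residual": result.periodicity_residual}, "adjoint_prc"
    if isinstance(result, DirectPRC):
        df = pd.DataFrame({"onset_phase": result.onset_phases,
                           "shift_rad": result.shifts_rad,
                           "shift_ms": result.shifts_ms})
        return df, {"kind": "direct_prc", "period_ms": result.period,
                    "backend": result.backend,
                    "pulse": asdict(result.pulse)}, "direct_prc"
    if isinstance(result, GFunction):
        th, gv = result.sample(result.h.values.size)
        df = pd.DataFrame({"phase": th, "H": result.h(th), "G": gv})
        return df, {"kind": "coupling_functions", "period_ms": result.period,
                    "delay_ms": result.delay, "g_ee": result.h.g_ee,
                    "g_ie": result.h.g_ie}, "coupling"
    if isinstance(result, Trajectory):
        df = pd.DataFrame(result.states, columns=list(STATE_LABELS))
        df.insert(0, "time_ms", result.t)
        return df, {"kind": "mf_trajectory", "step_ms": result.step}, "trajectory"
    if isinstance(result, CoupledTrajectory):
        cols = [f"{lab}_1" for lab in STATE_LABELS] + [f"{lab}_2" for lab in STATE_LABELS]
        df = pd.DataFrame(result.states, columns=cols)
        df.insert(0, "time_ms", result.t)
        return df, {"kind": "coupled_trajectory", "delay_ms": result.delay,
                    "step_ms": result.step}, "coupled"
    if isinstance(result, GlobalPRCResult):
        df = pd.DataFrame({"onset_phase": result.onset_phases,
                           "shift_rad": result.shifts_rad,
                           "mode_switch": result.mode_switch})
        return df, {"kind": "global_prc", "period_ms": result.period,
                    "baseline_lag_ms": result.baseline_lag,
                    "target_circuit": result.target,
                    "target_population": result.population,
                    "pulse": asdict(result.pulse)}, "global_prc"
    if isinstance(result, RateTrace):
        df = pd.DataFrame({"time_ms": result.t, "r_e": result.r_e,
                           "r_i": result.r_i})
        return df, {"kind": "rate_trace", "bin_width_ms": result.bin_width}, "rates"
    if isinstance(result, SpikeRaster):
        pop = np.where(result.ids < result.n_e, "e", "i")
        df = pd.DataFrame({"neuron_id": result.ids, "population": pop,
                           "spike_time_ms": result.times})
        return df, {"kind": "spike_raster", "n_e": result.n_e,
                    "n_i": result.n_i, "window": list(result.window)}, "raster"
    raise TypeError(f"don't know how to serialize {type(result).__name__}")


def write_outputs(result, directory, config: ConfigBundle | None = None,
                  seed: int | None = None) -> dict:
    """Write a result as CSV + JSON header and return the manifest.

    Deterministic analyses rerun with the same config produce
    byte-identical CSVs, which the manifest hashes witness.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ConfigError(f"output directory does not exist: {directory}")
    df, meta, stem = _frame_and_meta(result)
    csv_path = directory / f"{stem}.csv"
    df.to_csv(csv_path, index=False, float_format="%.12g")
    header_path = directory / f"{stem}.json"
    with open(header_path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    manifest = {
        "files": {
            csv_path.name: hashlib.sha256(csv_path.read_bytes()).hexdigest(),
            header_path.name: hashlib.sha256(header_path.read_bytes()).hexdigest(),
        },
        "seed": seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    if config is not None:
        cfg_json = json.dumps(config_to_dict(config), sort_keys=True)
        manifest["config_sha256"] = hashlib.sha256(cfg_json.encode()).hexdigest()
        manifest["config"] = config_to_dict(config)
    with open(directory / f"{stem}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
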