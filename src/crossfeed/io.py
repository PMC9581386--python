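"""Configuration, snapshot and time-series I/O, and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np

from .engine import TimeSeries
from .model import ColonyState, ConfigurationError, ModelParams

__all__ = [
    "read_config",
    "params_to_json",
    "write_snapshot",
    "read_snapshot",
    "write_timeseries",
    "read_timeseries",
    "write_manifest",
]

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}

_FLOAT_KEYS = {"lambda_max_1", "lambda_max_2", "gamma_A", "gamma_B",
               "D_A", "D_B", "Y_A", "Y_B", "K_A", "K_B", "rho0", "T_max"}
_INT_KEYS = {"L0", "seed", "preseed_A", "preseed_B"}
_STR_KEYS = {"division_site_rule", "propensity_mode", "boundary_mode"}


def read_config(path) -> ModelParams:
    """Parse a TOML key/value config into ModelParams.

    Unknown keys are rejected; missing keys take the symmetric defaults.
    """
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as e:
            raise ConfigurationError(f"cannot parse {path}: {e}") from e
    return params_from_dict(data, source=str(path))


def params_from_dict(data: dict, source: str = "<dict>") -> ModelParams:
    kwargs = {}
    for key, value in data.items():
        if key not in _PARAM_FIELDS:
            raise ConfigurationError(
                f"{source}: unknown key {key!r} "
                f"(valid keys: {', '.join(sorted(_PARAM_FIELDS))})")
        if key in _FLOAT_KEYS:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigurationError(f"{source}: {key} must be a number")
            kwargs[key] = float(value)
        elif key in _INT_KEYS:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigurationError(f"{source}: {key} must be an integer")
            kwargs[key] = int(value)
        elif key in _STR_KEYS:
            if not isinstance(value, str):
                raise ConfigurationError(f"{source}: {key} must be a string")
            kwargs[key] = value
        elif key == "lattice_size":
            if value != "auto" and (isinstance(value, bool)
                                    or not isinstance(value, int)):
                raise ConfigurationError(
                    f"{source}: lattice_size must be an int or 'auto'")
            kwargs[key] = value
    try:
        return ModelParams(**kwargs)
    except ConfigurationError as e:
        raise ConfigurationError(f"{source}: {e}") from e


def params_to_json(params: ModelParams, path=None) -> str:
    text = json.dumps(params.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Snapshots: HDF5 (default) or plain-JSON fallback chosen by extension
# ---------------------------------------------------------------------------

def write_snapshot(state: ColonyState, path) -> None:
    """Lossless snapshot of the cell grid, both nutrient grids and t."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.attrs["t"] = state.t
            fh.create_dataset("cell_grid", data=state.cell_grid,
                              compression="gzip")
            fh.create_dataset("nutrient_A", data=state.nutrient_A,
                              compression="gzip")
            fh.create_dataset("nutrient_B", data=state.nutrient_B,
                              compression="gzip")
    elif path.suffix == ".json":
        payload = {
            "t": state.t,
            "shape": list(state.shape),
            "cell_grid": state.cell_grid.ravel().tolist(),
            "nutrient_A": state.nutrient_A.ravel().tolist(),
            "nutrient_B": state.nutrient_B.ravel().tolist(),
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unsupported snapshot extension: {path.suffix}")


def read_snapshot(path) -> ColonyState:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        try:
            with h5py.File(path, "r") as fh:
                return ColonyState(fh["cell_grid"][...],
                                   fh["nutrient_A"][...],
                                   fh["nutrient_B"][...],
                                   float(fh.attrs["t"]))
        except (OSError, KeyError) as e:
            raise IOError(f"cannot read snapshot {path}: {e}") from e
    elif path.suffix == ".json":
        try:
            payload = json.loads(path.read_text())
            shape = tuple(payload["shape"])
            return ColonyState(
                np.asarray(payload["cell_grid"], dtype=np.int8).reshape(shape),
                np.asarray(payload["nutrient_A"],
                           dtype=np.int64).reshape(shape),
                np.asarray(payload["nutrient_B"],
                           dtype=np.int64).reshape(shape),
                float(payload["t"]))
        except (json.JSONDecodeError, KeyError, ValueError) as e:
            raise IOError(f"cannot read snapshot {path}: {e}") from e
    raise ValueError(f"unsupported snapshot extension: {path.suffix}")


# ---------------------------------------------------------------------------
# Time series CSV
# ---------------------------------------------------------------------------

_TS_HEADER = "t,rho1,rho2,nA,nB,radius"


def write_timeseries(ts: TimeSeries, path) -> None:
    data = np.column_stack([ts.t, ts.rho1, ts.rho2, ts.nA, ts.nB, ts.radius])
    np.savetxt(path, data, delimiter=",", header=_TS_HEADER, comments="",
               fmt="%.17g", newline="\n")


def read_timeseries(path) -> TimeSeries:
    data = np.genfromtxt(path, delimiter=",", names=True)
    data = np.atleast_1d(data)
    return TimeSeries(t=data["t"], rho1=data["rho1"], rho2=data["rho2"],
                      nA=data["nA"], nB=data["nB"], radius=data["radius"])


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, params: ModelParams, event_counts,
                   outputs: list, extra: dict = None) -> dict:
    from . import __version__
    manifest = {
        "version": __version__,
        "params": params.to_dict(),
        "seed": params.seed,
        "event_counts": {
            name: {"executed": int(row[0]), "null": int(row[1])}
            for name, row in zip(
                ("divide_1", "excrete_B", "uptake_A", "divide_2",
                 "excrete_A", "uptake_B", "diffuse_B", "diffuse_A"),
                np.asarray(event_counts))},
        "outputs": [{"path": str(Path(p).name), "sha256": _sha256(p)}
                    for p in outputs],
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
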