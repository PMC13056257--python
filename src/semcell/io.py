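"""Readers, writers, configuration and the synthetic fixture generator.

Trajectories use the extended-XYZ dialect: per frame a particle-count line,
a comment line carrying ``time=<t> columns=<schema>``, then one whitespace-
separated record per particle (id, kind code, x, y, z, optional extra
columns).  Force curves are two-column CSV (time, force) with an optional
header.  All floats are written at 9 significant digits.
"""

from __future__ import annotations

import copy
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import DEFAULT_CONFIG, ParticleSystem

__all__ = [
    "FormatError",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "read_force_curve",
    "write_force_curve",
    "RunManifest",
    "make_fixture",
]

FLOAT_FMT = "{:.9g}"


class FormatError(ValueError):
    """Malformed input or inconsistent output schema."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None, overrides=None) -> dict:
    """Defaults (the reference parameter tables) merged with a YAML file
    and programmatic overrides, in that order."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"config root must be a mapping: {path}")
        _deep_update(config, loaded)
    if overrides:
        _deep_update(config, overrides)
    return config


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

def write_trajectory(frames, path, extra_columns=()):
    """Write frames as extended XYZ.

    ``frames`` is an iterable of (time, system) or (time, system, extras)
    where ``extras`` maps column name -> (N,) array.  The column schema
    must be identical in every frame.
    """
    path = Path(path)
    schema = ["id", "kind", "x", "y", "z", *extra_columns]
    with open(path, "w") as fh:
        for frame in frames:
            if len(frame) == 2:
                (time, system), extras = frame, {}
            else:
                time, system, extras = frame
            if sorted(extras) != sorted(extra_columns):
                raise FormatError(
                    f"frame at t={time} has columns {sorted(extras)}, "
                    f"declared {sorted(extra_columns)}")
            fh.write(f"{system.n}\n")
            fh.write(f"time={FLOAT_FMT.format(time)} "
                     f"columns={':'.join(schema)}\n")
            cols = [np.arange(system.n), system.kinds,
                    system.positions[:, 0], system.positions[:, 1],
                    system.positions[:, 2]]
            cols += [np.asarray(extras[c]) for c in extra_columns]
            for row in zip(*cols):
                fh.write(" ".join(
                    str(int(v)) if i < 2 else FLOAT_FMT.format(v)
                    for i, v in enumerate(row)) + "\n")
    return path


def read_trajectory(path):
    """Parse an extended-XYZ file into [(time, DataFrame)] frames."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError as err:
            raise FormatError(f"expected particle count at line {i+1}") from err
        header = dict(item.split("=", 1) for item in lines[i + 1].split())
        time = float(header["time"])
        columns = header["columns"].split(":")
        rows = [ln.split() for ln in lines[i + 2:i + 2 + n]]
        if len(rows) != n:
            raise FormatError(f"truncated frame at line {i+1}")
        df = pd.DataFrame(rows, columns=columns).astype(
            {c: (int if c in ("id", "kind") else float) for c in columns})
        frames.append((time, df))
        i += 2 + n
    return frames


def frame_to_system(df: pd.DataFrame) -> ParticleSystem:
    from .model import IMMOBILE_KINDS
    kinds = df["kind"].to_numpy()
    mobile = ~np.isin(kinds, [int(k) for k in IMMOBILE_KINDS])
    return ParticleSystem(
        positions=df[["x", "y", "z"]].to_numpy(float), kinds=kinds,
        mobile=mobile,
        cell_id=np.where(mobile, 0, -1))


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

def read_force_curve(path) -> pd.DataFrame:
    """Two-column CSV (time, force) with auto-detected header.

    Time must be strictly increasing; a violation reports the offending
    row number (1-based, counting the header).
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, comment="#")
    offset = 1
    try:
        float(raw.iloc[0, 0])
    except (TypeError, ValueError):
        raw = raw.iloc[1:].reset_index(drop=True)
        offset = 2
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (time, force)")
    df = pd.DataFrame({"time": raw.iloc[:, 0].astype(float),
                       "force": raw.iloc[:, 1].astype(float)})
    dt = np.diff(df["time"].to_numpy())
    bad = np.where(dt <= 0)[0]
    if len(bad):
        raise FormatError(
            f"{path}: time not strictly increasing at row {bad[0] + 1 + offset}")
    return df


def write_force_curve(df: pd.DataFrame, path):
    cols = ["time", "force"] + (["phase"] if "phase" in df else [])
    df.to_csv(path, index=False, columns=cols, float_format="%.9g")
    return Path(path)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    scenario: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    python: str = platform.python_version()

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return Path(path)

    @classmethod
    def read(cls, path):
        with open(path) as fh:
            data = json.load(fh)
        return cls(**{k: data[k] for k in
                      ("scenario", "seed", "config", "outputs", "version",
                       "python")})


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixture(kind, out_dir, *, scale="test", seed=7, params=None):
    """Deterministic synthetic fixtures for tests and examples.

    kind:
      - "separated_cell": a phase-separated cell snapshot (staged anneal)
      - "spread_cell": a synthetic pre-spread adherent cell snapshot
      - "synthetic_target": a simulator-generated three-phase indentation
        force curve at known parameters
      - "toy_pattern": a small circular ECM pattern

    scale "test" uses 200 particles (180 cytoplasmic / 20 nuclear); "full"
    uses the reference 1000 (900/100).
    """
    from . import scenarios
    from .model import (drag_array, init_cell, nuclear_drag,
                        params_from_config, table_from_config)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np_scale = {"test": 200, "full": 1000}[scale]
    config = load_config(overrides={"cell": {"Np": np_scale},
                                    "rng": {"seed": seed}})
    if params:
        _deep_update(config, params)
    p = params_from_config(config)
    table = table_from_config(config, p)
    eta_nuc = nuclear_drag(config, p)
    outputs = []

    if kind == "separated_cell":
        cell = init_cell(np_scale, config["cell"]["nuclear_fraction"],
                         radius=config["cell"]["Rcell"],
                         height=config["cell"]["Rcell"],
                         min_spacing=0.5 * p.deq, seed=seed,
                         mcell=config["cell"]["mcell"])
        drag = drag_array(cell, p, eta_nuc)
        cell, trace, _ = scenarios.equilibrate_nucleus(
            cell, table, p, drag, seed=seed)
        path = out_dir / "separated_cell.xyz"
        write_trajectory([(0.0, cell)], path)
        outputs.append(str(path))
    elif kind == "spread_cell":
        cell = scenarios.make_spread_cell(
            p, config["cell"]["nuclear_fraction"],
            z_bottom=2 ** (1 / 6) * config["ecm"]["sigma"], seed=seed)
        path = out_dir / "spread_cell.xyz"
        write_trajectory([(0.0, cell)], path)
        outputs.append(str(path))
    elif kind == "synthetic_target":
        curve = synthetic_indentation_curve(config, seed=seed)
        path = out_dir / "synthetic_target.csv"
        write_force_curve(curve, path)
        outputs.append(str(path))
    elif kind == "toy_pattern":
        pattern = scenarios.EcmPattern(shape="circle", size=10.0,
                                       spacing=2.0, margin=4.0)
        ecm = scenarios.build_ecm(pattern)
        path = out_dir / "toy_pattern.xyz"
        write_trajectory([(0.0, ecm)], path)
        outputs.append(str(path))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    manifest = RunManifest(scenario=f"fixture:{kind}", seed=seed,
                           config=config, outputs=outputs)
    manifest.write(out_dir / f"{kind}_manifest.json")
    return outputs


def synthetic_indentation_curve(config=None, *, seed=7, overrides=None,
                                protocol=None):
    """Simulator-generated three-phase indentation target at known
    parameters (used in place of external digitized AFM data)."""
    from . import scenarios
    from .model import drag_array, nuclear_drag, params_from_config, table_from_config

    if config is None:
        config = load_config(overrides=overrides)
    p = params_from_config(config)
    table = table_from_config(config, p)
    cell = scenarios.make_spread_cell(
        p, config["cell"]["nuclear_fraction"],
        z_bottom=2 ** (1 / 6) * config["ecm"]["sigma"], seed=seed)
    drag = drag_array(cell, p, nuclear_drag(config, p))
    if protocol is None:
        protocol = scenarios.IndentationProtocol()
    result = scenarios.run_indentation(cell, table, p, drag, protocol,
                                       kT_eff=0.0, seed=seed)
    return result.force_curve
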