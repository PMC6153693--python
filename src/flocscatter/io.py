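"""CSV/JSON/YAML readers and writers for the package's text formats.

Dialects (all plain text, ``#`` comment lines allowed):

* scattering curve: columns ``q_per_um,intensity`` or ``angle_deg,intensity``
  (angles are converted with the optics configuration);
* binned PSD: columns ``edge_low_um,edge_high_um,weight`` preceded by a
  ``# basis=volume|number`` comment;
* particle list: single column ``diameter_um``;
* run configuration: a flat YAML mapping;
* reports: versioned JSON (``"schema": 1``) at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .forward import OpticalConfig, QGrid, ScatteringCurve, q_from_angle
from .psd import ParticleList, SizeDistribution, SizeGrid, VALID_BASES

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_psd_csv", "write_psd_csv",
    "read_particles_csv", "write_particles_csv",
    "load_config", "write_report",
    "CONFIG_KEYS",
]

#: Keys accepted in a YAML run-configuration file.
CONFIG_KEYS = frozenset({
    "wavelength_um", "medium_refractive_index", "noise_sd", "n_reps", "seed",
    "level", "r2_min", "slope_tol", "min_points", "convention",
    "cut_um", "to_basis", "edges_um", "log_level",
})


def _read_table(path, expected_cols: int) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty or has no data rows")
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV ({exc})")
    if df.shape[0] == 0:
        raise SchemaError(f"{path}: no data rows")
    if df.shape[1] < expected_cols:
        raise SchemaError(
            f"{path}: expected {expected_cols} columns, found {df.shape[1]}"
        )
    return df


def read_curve_csv(path, optics: OpticalConfig = OpticalConfig()
                   ) -> ScatteringCurve:
    """Read a scattering curve; angle input is converted to q via optics."""
    df = _read_table(path, 2)
    cols = {c.strip().lower() for c in df.columns}
    df.columns = [c.strip().lower() for c in df.columns]
    if "intensity" not in cols:
        raise SchemaError(f"{path}: missing 'intensity' column")
    if "q_per_um" in cols:
        q = df["q_per_um"].to_numpy(float)
    elif "angle_deg" in cols:
        q = np.asarray(q_from_angle(df["angle_deg"].to_numpy(float), optics))
    else:
        raise SchemaError(
            f"{path}: need a 'q_per_um' or 'angle_deg' column"
        )
    order = np.argsort(q)
    return ScatteringCurve(QGrid(q[order]),
                           df["intensity"].to_numpy(float)[order])


def write_curve_csv(curve: ScatteringCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("# flocscatter scattering curve\n")
        fh.write("q_per_um,intensity\n")
        for q, i in zip(curve.q, curve.intensity):
            fh.write(f"{float(q)!r},{float(i)!r}\n")


def read_psd_csv(path) -> SizeDistribution:
    """Read a binned PSD; the basis comes from a ``# basis=...`` comment."""
    path = Path(path)
    basis = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "basis=" in line:
                basis = line.split("basis=")[1].strip()
                break
    if basis not in VALID_BASES:
        raise SchemaError(
            f"{path}: needs a '# basis=volume|number' comment line"
        )
    df = _read_table(path, 3)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("edge_low_um", "edge_high_um", "weight"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing '{col}' column")
    lo = df["edge_low_um"].to_numpy(float)
    hi = df["edge_high_um"].to_numpy(float)
    if not np.allclose(lo[1:], hi[:-1], rtol=1e-9):
        raise SchemaError(f"{path}: bins must be contiguous (edges must chain)")
    grid = SizeGrid(np.concatenate([lo, hi[-1:]]))
    return SizeDistribution.from_weights(grid, df["weight"].to_numpy(float),
                                         basis)


def write_psd_csv(dist: SizeDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# basis={dist.basis}\n")
        fh.write("edge_low_um,edge_high_um,weight\n")
        e = dist.grid.edges
        for lo, hi, w in zip(e[:-1], e[1:], dist.weights):
            fh.write(f"{float(lo)!r},{float(hi)!r},{float(w)!r}\n")


def read_particles_csv(path) -> ParticleList:
    df = _read_table(path, 1)
    df.columns = [c.strip().lower() for c in df.columns]
    if "diameter_um" not in df.columns:
        raise SchemaError(f"{path}: missing 'diameter_um' column")
    return ParticleList(df["diameter_um"].to_numpy(float))


def write_particles_csv(particles: ParticleList, path) -> None:
    with open(path, "w") as fh:
        fh.write("diameter_um\n")
        for d in particles.diameters:
            fh.write(f"{float(d)!r}\n")


def load_config(path) -> dict:
    """Load a flat YAML config mapping; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a YAML mapping")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise SchemaError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"allowed: {sorted(CONFIG_KEYS)}"
        )
    return cfg


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_report(payload: dict, path) -> None:
    """Write a versioned JSON report at full float precision."""
    body = {"schema": 1, **payload}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
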