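"""Plate layouts, synthetic-plate generation, CSV/config I/O and replay.

All tabular artifacts are RFC-4180-style CSV with a mandatory header row:

* plate layout:   well,label,mu_max,lag_time,x0,x_max
* OD log:         well,cycle,t,raw_od,reported_od,in_range
* dilution log:   well,cycle,t,reported_od,mu,factor_requested,
                  factor_achieved,remove_vol,add_medium_vol,clamped

Floats are serialized at full ``repr`` precision so every file round-trips
losslessly; in particular, replaying a simulated run's own OD log through
:func:`replay_controller` reproduces the run's dilution log bit-identically.
Experiment settings live in a flat YAML key-value file whose keys mirror the
config-dataclass fields; unknown keys are errors.
"""

from __future__ import annotations

import dataclasses
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .batch import BatchConfig
from .controller import ControllerConfig, WellController, harvest_ready
from .growth import StrainParams
from .measurement import MeasurementConfig

__all__ = [
    "PlateLayout",
    "well_name",
    "generate_synthetic_plate",
    "read_plate_layout",
    "write_plate_layout",
    "load_config",
    "write_summary",
    "replay_controller",
]

PLATE_COLUMNS = ["well", "label", "mu_max", "lag_time", "x0", "x_max"]
DILUTION_LOG_COLUMNS = [
    "well",
    "cycle",
    "t",
    "reported_od",
    "mu",
    "factor_requested",
    "factor_achieved",
    "remove_vol",
    "add_medium_vol",
    "clamped",
]


def well_name(index: int, cols: int = 12) -> str:
    """Row-major SBS well id (0 -> 'A1', 12 -> 'B1' on a 12-column plate)."""
    return f"{string.ascii_uppercase[index // cols]}{index % cols + 1}"


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of SBS well ids (A1..H12 by default) to strain parameters."""

    wells: dict[str, StrainParams] = field(default_factory=dict)
    rows: int = 8
    cols: int = 12

    def __post_init__(self) -> None:
        valid = {well_name(i, self.cols) for i in range(self.rows * self.cols)}
        bad = set(self.wells) - valid
        if bad:
            raise ValueError(f"well ids outside {self.rows}x{self.cols} geometry: {sorted(bad)}")

    def items(self) -> list[tuple[str, StrainParams]]:
        """Wells in row-major plate order."""
        order = {well_name(i, self.cols): i for i in range(self.rows * self.cols)}
        return sorted(self.wells.items(), key=lambda kv: order[kv[0]])

    def __len__(self) -> int:
        return len(self.wells)


def generate_synthetic_plate(
    n_wells: int,
    mu_range: tuple[float, float] = (0.9, 1.5),
    lag_range: tuple[float, float] = (0.0, 1.0),
    x0_range: tuple[float, float] = (0.05, 0.2),
    seed: int = 0,
    x_max: float = 3.0,
    rows: int = 8,
    cols: int = 12,
) -> PlateLayout:
    """Draw a plate of heterogeneous strains, reproducibly under ``seed``.

    Emulates a strain library whose members differ in maximum growth rate,
    lag phase and starting density — the heterogeneity that makes a common
    harvest point hard to hit with plain batch cultivation.  Parameters are
    uniform within the given ranges; wells fill row-major.
    """
    if n_wells > rows * cols:
        raise ValueError(f"n_wells={n_wells} exceeds plate geometry {rows}x{cols}")
    for lo, hi in (mu_range, lag_range, x0_range):
        if hi < lo:
            raise ValueError("ranges must satisfy lo <= hi")
    rng = np.random.default_rng(seed)
    wells: dict[str, StrainParams] = {}
    for i in range(n_wells):
        wells[well_name(i, cols)] = StrainParams(
            label=f"strain_{i + 1:02d}",
            mu_max=float(rng.uniform(*mu_range)),
            lag_time=float(rng.uniform(*lag_range)),
            x0=float(rng.uniform(*x0_range)),
            x_max=x_max,
        )
    return PlateLayout(wells=wells, rows=rows, cols=cols)


def write_plate_layout(layout: PlateLayout, path: Union[str, Path]) -> None:
    rows = [
        {
            "well": w,
            "label": p.label,
            "mu_max": p.mu_max,
            "lag_time": p.lag_time,
            "x0": p.x0,
            "x_max": p.x_max,
        }
        for w, p in layout.items()
    ]
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plate_layout(path: Union[str, Path]) -> PlateLayout:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return PlateLayout()
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate layout {path} lacks columns {sorted(missing)}")
    wells = {
        str(row.well): StrainParams(
            label=str(row.label),
            mu_max=float(row.mu_max),
            lag_time=float(row.lag_time),
            x0=float(row.x0),
            x_max=float(row.x_max),
        )
        for row in df.itertuples()
    }
    if len(wells) != len(df):
        raise ValueError(f"duplicate well ids in {path}")
    return PlateLayout(wells=wells)


# --- configuration -----------------------------------------------------------

_ENGINE_KEYS = {
    "strategy": str,
    "seed": int,
    "simulation_step": float,
    "harvest_band_low": float,
    "harvest_band_high": float,
}


def load_config(path: Union[str, Path]) -> dict:
    """Parse a flat YAML key-value file into config objects.

    Returns a dict with keys ``controller``, ``measurement``, ``batch`` and
    ``engine`` (the latter a plain dict of loop-level settings).  Each YAML
    key must match a field of one of the config dataclasses or an
    engine-level key; unknown keys raise, so typos fail fast.  A key shared
    by several configs (e.g. ``sample_vol``) is applied to all of them.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    groups = {
        "controller": {f.name: f.type for f in dataclasses.fields(ControllerConfig)},
        "measurement": {f.name: f.type for f in dataclasses.fields(MeasurementConfig)},
        "batch": {f.name: f.type for f in dataclasses.fields(BatchConfig)},
    }
    kwargs: dict[str, dict] = {g: {} for g in groups}
    engine: dict = {}
    unknown = []
    for key, value in raw.items():
        hit = False
        for g, fields in groups.items():
            if key in fields:
                kwargs[g][key] = value
                hit = True
        if key in _ENGINE_KEYS:
            engine[key] = _ENGINE_KEYS[key](value)
            hit = True
        if not hit:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return {
        "controller": ControllerConfig(**kwargs["controller"]),
        "measurement": MeasurementConfig(**kwargs["measurement"]),
        "batch": BatchConfig(**kwargs["batch"]),
        "engine": engine,
    }


def write_summary(metrics: dict, path: Union[str, Path]) -> None:
    """Write a flat ``key = value`` text summary."""
    lines = [f"{k} = {v}" for k, v in metrics.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# --- offline replay ----------------------------------------------------------

def replay_controller(
    od_log: Union[str, Path, pd.DataFrame],
    cfg: Optional[ControllerConfig] = None,
) -> pd.DataFrame:
    """Run the controller over a recorded OD log, without simulation.

    The log needs columns ``well``, ``t`` and ``reported_od`` (extra columns
    are ignored); rows are processed cycle by cycle in time order, wells in
    file order within a cycle.  The output is a dilution log with exactly the
    growth-rate estimates and plans the live loop would have produced,
    including the sample-replacement-only rows of first readings.  Wells with
    a single reading therefore yield no actual dilution.  Replay stops where
    the live loop would: when every well read in a cycle is within the
    harvest band, or after ``max_cycles`` cycles.

    Malformed rows (missing or non-numeric fields) are reported with their
    line numbers.  An empty file yields an empty log.
    """
    if cfg is None:
        cfg = ControllerConfig()
    if isinstance(od_log, (str, Path)):
        try:
            df = pd.read_csv(od_log, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=DILUTION_LOG_COLUMNS)
    else:
        df = od_log.copy()
    if df.empty:
        return pd.DataFrame(columns=DILUTION_LOG_COLUMNS)
    missing = {"well", "t", "reported_od"} - set(df.columns)
    if missing:
        raise ValueError(f"OD log lacks columns {sorted(missing)}")

    bad_lines = [
        int(i) + 2  # header is line 1
        for i, row in df.iterrows()
        if pd.isna(row["well"])
        or pd.isna(pd.to_numeric(row["t"], errors="coerce"))
        or pd.isna(pd.to_numeric(row["reported_od"], errors="coerce"))
    ]
    if bad_lines:
        raise ValueError(f"malformed OD log rows at lines {bad_lines}")
    df["t"] = df["t"].astype(float)
    df["reported_od"] = df["reported_od"].astype(float)

    controllers: dict[str, WellController] = {}
    records: list[dict] = []
    for cycle, (t, group) in enumerate(
        sorted(df.groupby("t", sort=False), key=lambda kv: kv[0]), start=1
    ):
        ods = group["reported_od"].tolist()
        if harvest_ready(ods, cfg):
            break
        if cycle >= cfg.max_cycles:  # the live loop stops after this reading
            break
        for row in group.itertuples():
            well = str(row.well)
            ctl = controllers.setdefault(well, WellController(well, cfg))
            mu, plan = ctl.update(float(row.reported_od), float(row.t))
            records.append(
                {
                    "well": well,
                    "cycle": cycle,
                    "t": float(row.t),
                    "reported_od": float(row.reported_od),
                    "mu": np.nan if mu is None else mu,
                    "factor_requested": (
                        np.nan
                        if plan.factor_requested is None
                        else plan.factor_requested
                    ),
                    "factor_achieved": plan.factor_achieved,
                    "remove_vol": plan.remove_vol,
                    "add_medium_vol": plan.add_medium_vol,
                    "clamped": plan.clamped,
                }
            )
    return pd.DataFrame(records, columns=DILUTION_LOG_COLUMNS)
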