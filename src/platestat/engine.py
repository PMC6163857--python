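"""Event loop coupling wells, measurement and either control strategy.

``run_turbidostat`` executes the quasi-turbidostat cycle — (I) sampling,
(II) OD600 measurement, (III) dilution — on every well until all wells read
within the harvest band of the setpoint.  ``run_batch`` executes the
comparison arm: fixed preculture, 1:20 inoculation, and mean-OD-triggered
interval switching and harvest.  ``compare_strategies`` runs both arms on
the same plates and seeds and quantifies how tightly each arm synchronizes
the harvest densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .batch import (
    CONTINUE_LONG,
    CONTINUE_SHORT,
    HARVEST,
    BatchConfig,
    batch_next_action,
    inoculate_from_preculture,
)
from .controller import ControllerConfig, WellController, harvest_ready
from .fileio import DILUTION_LOG_COLUMNS, PlateLayout, generate_synthetic_plate
from .growth import StrainParams, WellState, advance_well, chemostat_trajectory
from .measurement import MeasurementConfig, read_od

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_turbidostat",
    "run_batch",
    "run_chemostat",
    "compare_strategies",
    "ComparisonReport",
    "harvest_spread",
    "band_fraction",
    "threshold_crossing_times",
]

READINGS_COLUMNS = ["well", "cycle", "t", "raw_od", "reported_od", "in_range"]
TRAJECTORY_COLUMNS = ["well", "t", "true_od", "reported_od"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one in-silico cultivation run."""

    plate: Union[PlateLayout, Sequence[StrainParams]]
    strategy: str = "turbidostat"
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    batch: BatchConfig = field(default_factory=BatchConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    seed: int = 0
    simulation_step: float = 0.05
    harvest_band: tuple[float, float] = (0.7, 1.4)

    def well_items(self) -> list[tuple[str, StrainParams]]:
        if isinstance(self.plate, PlateLayout):
            return self.plate.items()
        from .fileio import well_name

        return [(well_name(i), p) for i, p in enumerate(self.plate)]


@dataclass
class ExperimentResult:
    """Trajectories, logs and synchronization metrics of one run."""

    strategy: str
    trajectories: pd.DataFrame
    readings: pd.DataFrame
    dilution_log: pd.DataFrame
    harvest_time: float
    harvest_ods: dict[str, float]
    harvest_ods_reported: dict[str, float]
    harvested: bool
    cycles_used: int
    metrics: dict


def harvest_spread(harvest_ods: Sequence[float]) -> float:
    """Range (max - min) of the per-well harvest densities."""
    if len(harvest_ods) == 0:
        raise ValueError("harvest_ods must be non-empty")
    return max(harvest_ods) - min(harvest_ods)


def band_fraction(
    harvest_ods: Sequence[float], band: tuple[float, float]
) -> float:
    """Fraction of wells harvested inside the optimal-density band."""
    if len(harvest_ods) == 0:
        raise ValueError("harvest_ods must be non-empty")
    lo, hi = band
    return sum(lo <= od <= hi for od in harvest_ods) / len(harvest_ods)


def _advance(
    state: WellState,
    params: StrainParams,
    duration: float,
    step: float,
    traj: Optional[list],
    well: str,
) -> WellState:
    """Advance a well by ``duration`` hours in ``step`` increments.

    The growth law is integrated by its exact closed form, so the result is
    independent of the step size; sub-stepping only adds trajectory
    resolution.  The final sub-step is not recorded: it coincides with the
    next measurement row.
    """
    n = max(1, round(duration / step))
    dt = duration / n
    for i in range(n):
        state = advance_well(state, params, dt)
        if traj is not None and i < n - 1:
            traj.append((well, state.t, state.x_true, np.nan))
    return state


def _result_metrics(
    harvest_ods: dict[str, float],
    band: tuple[float, float],
    cycles: int,
) -> dict:
    ods = list(harvest_ods.values())
    return {
        "harvest_spread": harvest_spread(ods),
        "band_fraction": band_fraction(ods, band),
        "cycles_used": cycles,
    }


def run_turbidostat(
    cfg: ExperimentConfig, record_dense: bool = True
) -> ExperimentResult:
    """Simulate the quasi-turbidostat loop until harvest or max_cycles.

    The first sample is taken directly after inoculation (t = 0); the first
    dilution can only follow the second measurement, once a growth rate
    exists.  Wells are processed in plate order; dilutions within a cycle
    are simultaneous.  The controller sees only the noisy, back-calculated
    reported ODs.  If ``max_cycles`` measurements pass without every well
    reading inside the harvest band, the run is flagged not-harvested and
    the final densities are reported instead.
    """
    ctrl = cfg.controller
    rng = np.random.default_rng(cfg.seed)
    items = cfg.well_items()
    if not items:
        raise ValueError("plate must contain at least one well")
    states = {
        w: WellState(x_true=p.x0, volume=ctrl.culture_volume, t=0.0)
        for w, p in items
    }
    controllers = {w: WellController(w, ctrl) for w, _ in items}
    meas = replace(cfg.measurement, sample_vol=ctrl.sample_vol)

    traj: list = []
    dense = traj if record_dense else None
    readings_rows: list = []
    dilution_rows: list[dict] = []
    harvested = False
    harvest_time = math.nan
    cycle = 0

    while cycle < ctrl.max_cycles:
        cycle += 1
        t = next(iter(states.values())).t
        cycle_readings = {}
        for w, p in items:
            reading, states[w] = read_od(states[w], meas, rng, well_id=w)
            cycle_readings[w] = reading
            readings_rows.append(
                (w, cycle, t, reading.raw, reading.reported, reading.in_range)
            )
            traj.append((w, t, states[w].x_true, reading.reported))
        reported = [cycle_readings[w].reported for w, _ in items]
        if harvest_ready(reported, ctrl):
            harvested = True
            harvest_time = t
            break
        if cycle >= ctrl.max_cycles:
            break
        V, s = ctrl.culture_volume, ctrl.sample_vol
        for w, p in items:
            mu, plan = controllers[w].update(cycle_readings[w].reported, t)
            st = states[w]
            # physical dilution: remove r at current concentration, then top
            # up with s + r fresh medium back to the working volume
            conc = st.x_true * (V - s - plan.remove_vol) / V
            states[w] = WellState(x_true=conc, volume=V, t=t)
            dilution_rows.append(
                {
                    "well": w,
                    "cycle": cycle,
                    "t": t,
                    "reported_od": cycle_readings[w].reported,
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
        for w, p in items:
            states[w] = _advance(
                states[w], p, ctrl.cycle_time, cfg.simulation_step, dense, w
            )

    harvest_ods = {w: states[w].x_true for w, _ in items}
    harvest_reported = {w: cycle_readings[w].reported for w, _ in items}
    return ExperimentResult(
        strategy="turbidostat",
        trajectories=pd.DataFrame(traj, columns=TRAJECTORY_COLUMNS),
        readings=pd.DataFrame(readings_rows, columns=READINGS_COLUMNS),
        dilution_log=pd.DataFrame(dilution_rows, columns=DILUTION_LOG_COLUMNS),
        harvest_time=harvest_time,
        harvest_ods=harvest_ods,
        harvest_ods_reported=harvest_reported,
        harvested=harvested,
        cycles_used=cycle,
        metrics=_result_metrics(harvest_ods, cfg.harvest_band, cycle),
    )


def run_batch(cfg: ExperimentConfig, record_dense: bool = True) -> ExperimentResult:
    """Simulate the batch arm: preculture, inoculation, mean-OD triggers.

    Each well grows undisturbed for ``preculture_hours`` (typically into its
    capacity, which absorbs lag and starting-density differences), then a
    fresh main culture is inoculated at the configured ratio.  The main
    culture carries no residual lag.  Monitoring reads all wells, averages
    the in-range reported ODs and switches from hourly to half-hourly
    sampling at the adaptation threshold; once the mean crosses the harvest
    threshold all wells are harvested simultaneously, however far the
    individual wells are from the target.  Out-of-range readings are
    excluded from the mean with a warning.
    """
    bat = cfg.batch
    rng = np.random.default_rng(cfg.seed)
    items = cfg.well_items()
    if not items:
        raise ValueError("plate must contain at least one well")

    preculture_ods = {}
    states = {}
    main_params = {}
    for w, p in items:
        pc = advance_well(
            WellState(x_true=p.x0, volume=bat.main_culture_volume, t=0.0),
            p,
            bat.preculture_hours,
        )
        preculture_ods[w] = pc.x_true
        states[w] = inoculate_from_preculture(pc.x_true, bat)
        main_params[w] = replace(p, lag_time=0.0, x0=states[w].x_true)

    traj: list = []
    dense = traj if record_dense else None
    readings_rows: list = []
    harvested = False
    harvest_time = math.nan
    cycle = 0
    action = CONTINUE_LONG
    cycle_readings: dict = {}

    while True:
        cycle += 1
        t = next(iter(states.values())).t
        if any(
            states[w].volume <= cfg.measurement.sample_vol for w, _ in items
        ):
            warnings.warn("culture volume exhausted by sampling; stopping batch run")
            break
        cycle_readings = {}
        for w, _ in items:
            reading, states[w] = read_od(states[w], cfg.measurement, rng, well_id=w)
            cycle_readings[w] = reading
            traj.append((w, t, states[w].x_true, reading.reported))
        usable = [r.reported for r in cycle_readings.values() if r.in_range]
        if not usable:
            warnings.warn("no in-range OD reading in cycle; using all readings")
            usable = [r.reported for r in cycle_readings.values()]
        mean_od = float(np.mean(usable))
        action = batch_next_action(mean_od, bat)
        for w, _ in items:
            r = cycle_readings[w]
            readings_rows.append(
                (w, cycle, t, r.raw, r.reported, r.in_range, mean_od, action)
            )
        if action == HARVEST:
            harvested = True
            harvest_time = t
            break
        if t >= bat.max_hours:
            break
        interval = (
            bat.interval_long if action == CONTINUE_LONG else bat.interval_short
        ) / 60.0
        for w, _ in items:
            states[w] = _advance(
                states[w], main_params[w], interval, cfg.simulation_step, dense, w
            )

    harvest_ods = {w: states[w].x_true for w, _ in items}
    harvest_reported = {
        w: cycle_readings[w].reported for w, _ in items if w in cycle_readings
    }
    metrics = _result_metrics(harvest_ods, cfg.harvest_band, cycle)
    metrics["preculture_ods"] = preculture_ods
    return ExperimentResult(
        strategy="batch",
        trajectories=pd.DataFrame(traj, columns=TRAJECTORY_COLUMNS),
        readings=pd.DataFrame(
            readings_rows, columns=READINGS_COLUMNS + ["mean_od", "action"]
        ),
        dilution_log=pd.DataFrame(columns=DILUTION_LOG_COLUMNS),
        harvest_time=harvest_time,
        harvest_ods=harvest_ods,
        harvest_ods_reported=harvest_reported,
        harvested=harvested,
        cycles_used=cycle,
        metrics=metrics,
    )


def run_chemostat(
    cfg: ExperimentConfig,
    dilution_rates: Optional[dict[str, float]] = None,
    duration: float = 8.0,
) -> pd.DataFrame:
    """Illustrative continuous-culture trajectories (no controller).

    Each well follows the ideal chemostat solution at dilution rate D
    (default: the well's own mu_max, i.e. steady state).  Returns a dense
    trajectory table in the same schema as the other strategies; used for
    the batch/chemostat/turbidostat mode contrast.
    """
    rows = []
    for w, p in cfg.well_items():
        d = p.mu_max if dilution_rates is None else dilution_rates[w]
        ts = np.arange(0.0, duration + 1e-9, cfg.simulation_step)
        xs = chemostat_trajectory(p.x0, p.mu_max, d, ts)
        rows.extend((w, float(t), float(x), np.nan) for t, x in zip(ts, xs))
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


@dataclass
class ComparisonReport:
    """Per-replicate metrics for both arms plus aggregate fractions."""

    table: pd.DataFrame
    summary: dict


def compare_strategies(
    cfg: ExperimentConfig,
    n_replicates: int,
    plate_spec: Optional[dict] = None,
) -> ComparisonReport:
    """Run the turbidostat and batch arms on matched plates and seeds.

    With ``plate_spec`` (kwargs for :func:`generate_synthetic_plate`, minus
    the seed) a fresh plate is drawn per replicate; otherwise ``cfg.plate``
    is reused with fresh measurement noise.  Both arms of a replicate share
    the plate and the noise seed.  The summary reports, over replicates, how
    often the turbidostat harvest spread beats the batch spread and how
    often the batch arm leaves at least one well outside the harvest band.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(n_replicates):
        plate_seed = int(base.integers(2**31))
        run_seed = int(base.integers(2**31))
        plate = (
            generate_synthetic_plate(seed=plate_seed, **plate_spec)
            if plate_spec is not None
            else cfg.plate
        )
        for arm, runner in (("turbidostat", run_turbidostat), ("batch", run_batch)):
            r = runner(
                replace_cfg(cfg, plate=plate, seed=run_seed, strategy=arm),
                record_dense=False,
            )
            rows.append(
                {
                    "replicate": i,
                    "arm": arm,
                    "harvest_spread": r.metrics["harvest_spread"],
                    "band_fraction": r.metrics["band_fraction"],
                    "harvested": r.harvested,
                    "harvest_time": r.harvest_time,
                    "cycles_used": r.cycles_used,
                }
            )
    table = pd.DataFrame(rows)
    turb = table[table.arm == "turbidostat"].set_index("replicate")
    bat = table[table.arm == "batch"].set_index("replicate")
    tighter = (
        turb["harvest_spread"].to_numpy() < bat["harvest_spread"].to_numpy()
    )
    outside = bat["band_fraction"].to_numpy() < 1.0
    summary = {
        "n_replicates": n_replicates,
        "turbidostat_tighter_fraction": float(np.mean(tighter)),
        "batch_any_outside_band_fraction": float(np.mean(outside)),
        "mean_spread_turbidostat": float(turb["harvest_spread"].mean()),
        "mean_spread_batch": float(bat["harvest_spread"].mean()),
        "band_low": cfg.harvest_band[0],
        "band_high": cfg.harvest_band[1],
    }
    return ComparisonReport(table=table, summary=summary)


def replace_cfg(cfg: ExperimentConfig, **kw) -> ExperimentConfig:
    return replace(cfg, **kw)


def threshold_crossing_times(
    trajectories: pd.DataFrame, threshold: float
) -> dict[str, float]:
    """First time each well's true OD crosses ``threshold``.

    Log-linear interpolation between recorded points — exact for
    exponential growth.  Wells that never cross map to NaN.
    """
    out: dict[str, float] = {}
    for well, g in trajectories.groupby("well", sort=False):
        g = g.sort_values("t")
        ts = g["t"].to_numpy()
        xs = g["true_od"].to_numpy()
        above = np.nonzero(xs >= threshold)[0]
        if len(above) == 0:
            out[well] = math.nan
            continue
        j = above[0]
        if j == 0 or xs[j - 1] <= 0:
            out[well] = float(ts[j])
            continue
        frac = (math.log(threshold) - math.log(xs[j - 1])) / (
            math.log(xs[j]) - math.log(xs[j - 1])
        )
        out[well] = float(ts[j - 1] + frac * (ts[j] - ts[j - 1]))
    return out
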