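"""Quasi-turbidostat decision core.

Per well and per cycle the controller

1. estimates the specific growth rate from the two most recent culture-scale
   OD readings, ``mu = ln(X_k / X_{k-1}) / (t_k - t_{k-1})``;
2. forecasts the biomass one cycle ahead, ``X_{k+1} = X_k * exp(mu * dt)``;
3. back-computes the biomass needed *now* to land on the setpoint at the
   next reading, ``X_req = X_threshold / exp(mu * dt)``;
4. converts the ratio ``f = X_req / X_measured`` into pipettable
   remove/add volumes at constant working volume; and
5. declares harvest once every well reads within a tolerance band of the
   setpoint.

Under a perfect growth-rate estimate and noise-free measurement this is a
deadbeat controller: one dilution places the well exactly on the setpoint at
the next reading, up to pipette quantization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .growth import min_sustainable_mu

__all__ = [
    "ControllerConfig",
    "GrowthEstimate",
    "DilutionPlan",
    "estimate_growth_rate",
    "predict_biomass",
    "required_biomass",
    "compute_dilution_factor",
    "plan_dilution_volumes",
    "harvest_ready",
    "adapt_cycle_time",
    "WellController",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Setpoint, cycle and liquid-handling settings of the control loop.

    ``pipette_resolution`` (µL) quantizes planned volumes; set it to 0 for an
    idealized handler with continuous volumes.  ``min_residual_vol`` is the
    smallest culture volume that must survive a dilution, which bounds the
    strongest achievable dilution factor at ``min_residual_vol /
    culture_volume``.  ``mu_smoothing`` is an optional exponential-smoothing
    weight on the previous growth-rate estimate (0 = use the latest pairwise
    estimate only, the platform default).
    """

    x_threshold: float = 0.8
    cycle_time: float = 1.0
    culture_volume: float = 170.0
    sample_vol: float = 20.0
    pipette_resolution: float = 1.0
    min_residual_vol: float = 10.0
    harvest_tol: float = 0.05
    max_cycles: int = 24
    mu_smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.x_threshold <= 0:
            raise ValueError(f"x_threshold must be > 0, got {self.x_threshold}")
        if self.cycle_time <= 0:
            raise ValueError(f"cycle_time must be > 0, got {self.cycle_time}")
        if not 0 < self.sample_vol < self.culture_volume:
            raise ValueError("require 0 < sample_vol < culture_volume")
        if not self.min_residual_vol < self.culture_volume - self.sample_vol:
            raise ValueError(
                "require min_residual_vol < culture_volume - sample_vol"
            )
        if self.pipette_resolution < 0:
            raise ValueError("pipette_resolution must be >= 0")
        if self.harvest_tol < 0:
            raise ValueError("harvest_tol must be >= 0")
        if not 0 <= self.mu_smoothing < 1:
            raise ValueError("mu_smoothing must be in [0, 1)")


@dataclass(frozen=True)
class GrowthEstimate:
    """The controller's belief about one well after a reading."""

    well_id: str
    mu: float
    x_k: float
    t_k: float
    x_prev: float
    t_prev: float


@dataclass(frozen=True)
class DilutionPlan:
    """Requested dilution factor and the volumes realizing it.

    ``factor_requested`` is None when no dilution is needed (the forecast
    already undershoots the setpoint); the handler then only replaces the
    sampling volume with fresh medium.  For such plans ``factor_achieved`` is
    1.0 — the bookkeeping concentration factor the controller feeds into its
    next growth-rate estimate, mirroring a platform that applies the
    growth-rate equation directly to successive measured ODs.  For performed
    dilutions ``factor_achieved = (V - s - r) / V`` is the true concentration
    factor.
    """

    well_id: str
    factor_requested: Optional[float]
    factor_achieved: float
    remove_vol: float
    add_medium_vol: float
    clamped: bool


def estimate_growth_rate(
    x_prev: float, x_curr: float, t_prev: float, t_curr: float
) -> float:
    """Pairwise log-ratio growth-rate estimate in h^-1."""
    if x_prev <= 0 or x_curr <= 0:
        raise ValueError("ODs must be positive to estimate a growth rate")
    if t_curr <= t_prev:
        raise ValueError(f"require t_curr > t_prev, got {t_prev} -> {t_curr}")
    return math.log(x_curr / x_prev) / (t_curr - t_prev)


def predict_biomass(x_k: float, mu: float, dt: float) -> float:
    """Forecast biomass ``dt`` hours ahead assuming constant ``mu``."""
    if x_k <= 0:
        raise ValueError(f"x_k must be > 0, got {x_k}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return x_k * math.exp(mu * dt)


def required_biomass(x_threshold: float, mu: float, dt: float) -> float:
    """Biomass needed now to reach ``x_threshold`` after ``dt`` hours.

    Exact inverse of :func:`predict_biomass`.
    """
    if x_threshold <= 0:
        raise ValueError(f"x_threshold must be > 0, got {x_threshold}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return x_threshold / math.exp(mu * dt)


def compute_dilution_factor(
    x_required: float, x_measured: float
) -> Optional[float]:
    """Ratio of required to measured biomass, or None if no dilution needed.

    A factor >= 1 would mean concentrating the culture, which the handler
    cannot do; the well is then left to grow and only the sampling volume is
    replaced.
    """
    if x_measured <= 0:
        raise ValueError(f"x_measured must be > 0, got {x_measured}")
    f = x_required / x_measured
    return None if f >= 1.0 else f


def _round_half_away(x: float, resolution: float) -> float:
    if resolution == 0:
        return x
    q = x / resolution
    return math.copysign(math.floor(abs(q) + 0.5), q) * resolution


def plan_dilution_volumes(
    f: Optional[float], cfg: ControllerConfig, well_id: str = ""
) -> DilutionPlan:
    """Convert a dilution factor into remove/add volumes at constant volume.

    After the ``s`` µL sample is withdrawn, ``r`` µL of suspension is removed
    and ``s + r`` µL of fresh medium added, restoring ``culture_volume`` and
    diluting the biomass by ``(V - s - r) / V``.  Solving for ``r`` gives
    ``r = (V - s) - f*V``, rounded half-away-from-zero to the pipette
    resolution and clamped so at least ``min_residual_vol`` of culture
    survives.  ``clamped`` flags a requested factor outside the achievable
    band ``[min_residual_vol/V, (V - s)/V]``.
    """
    V = cfg.culture_volume
    s = cfg.sample_vol
    if f is None:
        return DilutionPlan(
            well_id=well_id,
            factor_requested=None,
            factor_achieved=1.0,
            remove_vol=0.0,
            add_medium_vol=s,
            clamped=False,
        )
    if not 0 < f < 1:
        raise ValueError(f"dilution factor must satisfy 0 < f < 1, got {f}")
    r_max = V - s - cfg.min_residual_vol
    clamped = not (cfg.min_residual_vol / V <= f <= (V - s) / V)
    r = _round_half_away((V - s) - f * V, cfg.pipette_resolution)
    r = min(max(r, 0.0), r_max)
    return DilutionPlan(
        well_id=well_id,
        factor_requested=f,
        factor_achieved=(V - s - r) / V,
        remove_vol=r,
        add_medium_vol=s + r,
        clamped=clamped,
    )


def harvest_ready(
    reported_ods: Sequence[float], cfg: ControllerConfig
) -> bool:
    """True iff every reported OD lies within ±harvest_tol of the setpoint."""
    if len(reported_ods) == 0:
        raise ValueError("reported_ods must be non-empty")
    lo = cfg.x_threshold - cfg.harvest_tol
    hi = cfg.x_threshold + cfg.harvest_tol
    return all(lo <= od <= hi for od in reported_ods)


def adapt_cycle_time(
    mu_estimates: Sequence[float],
    cfg: ControllerConfig,
    max_fold_growth: float = 4.0,
    clamp: tuple[float, float] = (0.25, 2.0),
) -> float:
    """Pick a cycle time covering the plate's slowest and fastest wells.

    The fastest well must not grow more than ``max_fold_growth``-fold within
    one cycle (``T <= ln(max_fold_growth) / mu_fastest``) while the slowest
    well must outgrow the passive sampling dilution
    (``T >= ln(V/(V-s)) / mu_slowest``).  The result is clamped to ``clamp``;
    the sustainability constraint wins a conflict since washout is
    irrecoverable.  With no finite positive estimate the current cycle time
    is kept and a warning emitted.
    """
    finite = [m for m in mu_estimates if math.isfinite(m) and m > 0]
    if not finite:
        warnings.warn(
            "no positive growth-rate estimate; keeping current cycle time",
            stacklevel=2,
        )
        return cfg.cycle_time
    t_fast = math.log(max_fold_growth) / max(finite)
    t_sustain = (
        min_sustainable_mu(cfg.culture_volume, cfg.sample_vol, 1.0) / min(finite)
    )  # min_sustainable_mu(V, s, T) <= mu  <=>  T >= ln(V/(V-s)) / mu
    T = min(t_fast, clamp[1])
    T = max(T, t_sustain, clamp[0])
    return min(T, clamp[1])


class WellController:
    """Per-well controller state machine shared by simulation and replay.

    Feeding it the sequence of reported ODs yields exactly the growth-rate
    estimates and dilution plans the live loop would produce: the belief
    carried to the next cycle is ``reported * factor_achieved`` of the plan
    just issued.
    """

    def __init__(self, well_id: str, cfg: ControllerConfig):
        self.well_id = well_id
        self.cfg = cfg
        self._x_prev: Optional[float] = None
        self._t_prev: Optional[float] = None
        self._mu_prev: Optional[float] = None
        self._last_estimate: Optional[GrowthEstimate] = None

    def update(
        self, reported_od: float, t: float
    ) -> tuple[Optional[float], DilutionPlan]:
        """Process one reading; return the µ estimate (None on the first
        cycle or unusable readings) and the dilution plan."""
        cfg = self.cfg
        mu: Optional[float] = None
        if (
            self._x_prev is not None
            and self._x_prev > 0
            and reported_od > 0
            and self._t_prev is not None
            and t > self._t_prev
        ):
            mu = estimate_growth_rate(self._x_prev, reported_od, self._t_prev, t)
            if cfg.mu_smoothing > 0 and self._mu_prev is not None:
                mu = (1 - cfg.mu_smoothing) * mu + cfg.mu_smoothing * self._mu_prev
            self._last_estimate = GrowthEstimate(
                well_id=self.well_id,
                mu=mu,
                x_k=reported_od,
                t_k=t,
                x_prev=self._x_prev,
                t_prev=self._t_prev,
            )
        if mu is None:
            f = None
        else:
            x_req = required_biomass(cfg.x_threshold, mu, cfg.cycle_time)
            f = compute_dilution_factor(x_req, reported_od)
        plan = plan_dilution_volumes(f, cfg, self.well_id)
        self._x_prev = reported_od * plan.factor_achieved
        self._t_prev = t
        self._mu_prev = mu
        return mu, plan

    @property
    def estimate(self) -> Optional[GrowthEstimate]:
        """Most recent growth-rate estimate with the reading pair behind it."""
        return self._last_estimate
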