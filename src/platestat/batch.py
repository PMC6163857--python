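"""Batch comparison arm: preculture, 1:20 inoculation, mean-OD triggers.

The traditional strategy runs a fixed-length preculture to absorb lag-phase
and starting-OD differences, inoculates a fresh main culture at 1:20, and
monitors the *mean* OD of all wells: hourly sampling until the mean reaches
0.4, half-hourly until it reaches 0.7, then harvest.  Because the triggers
act on the mean, individual wells can be far from the target density at
harvest — the failure mode the quasi-turbidostat removes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .growth import WellState

__all__ = ["BatchConfig", "batch_next_action", "inoculate_from_preculture"]

CONTINUE_LONG = "continue_long"
CONTINUE_SHORT = "continue_short"
HARVEST = "harvest"


@dataclass(frozen=True)
class BatchConfig:
    """Settings of the batch arm.

    ``main_culture_volume`` defaults to 200 µL so that the 10 µL inoculum
    realizes an exact 1:20 dilution.  Intervals are in minutes.  ``max_hours``
    bounds the main cultivation so runs that never reach the harvest
    threshold still terminate (flagged not-harvested).
    """

    preculture_hours: float = 8.0
    inoculum_vol: float = 10.0
    interval_long: float = 60.0
    interval_short: float = 30.0
    threshold_adapt: float = 0.4
    threshold_harvest: float = 0.7
    main_culture_volume: float = 200.0
    max_hours: float = 12.0

    def __post_init__(self) -> None:
        if not self.threshold_adapt < self.threshold_harvest:
            raise ValueError("require threshold_adapt < threshold_harvest")
        if not self.interval_short < self.interval_long:
            raise ValueError("require interval_short < interval_long")
        if self.inoculum_vol <= 0 or self.main_culture_volume <= 0:
            raise ValueError("volumes must be > 0")
        if self.preculture_hours < 0 or self.max_hours <= 0:
            raise ValueError("durations must be positive")


def batch_next_action(mean_od: float, cfg: BatchConfig) -> str:
    """Decide the next monitoring step from the plate-mean OD.

    Boundary values trigger the higher-urgency action: a mean exactly at the
    adaptation threshold shortens the interval, exactly at the harvest
    threshold harvests.
    """
    if mean_od < 0:
        raise ValueError(f"mean_od must be >= 0, got {mean_od}")
    if mean_od >= cfg.threshold_harvest:
        return HARVEST
    if mean_od >= cfg.threshold_adapt:
        return CONTINUE_SHORT
    return CONTINUE_LONG


def inoculate_from_preculture(preculture_od: float, cfg: BatchConfig) -> WellState:
    """Start a main culture from a preculture at the configured ratio.

    The starting OD is ``preculture_od * inoculum_vol / main_culture_volume``
    (1:20 at the defaults); elapsed time restarts at zero.
    """
    if preculture_od <= 0:
        raise ValueError(f"preculture_od must be > 0, got {preculture_od}")
    x0 = preculture_od * cfg.inoculum_vol / cfg.main_culture_volume
    return WellState(x_true=x0, volume=cfg.main_culture_volume, t=0.0)
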