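"""Ground-truth growth dynamics for simulated wells.

Biomass is expressed throughout as an OD600-equivalent concentration and time
in hours.  Wells grow exponentially at their maximum specific growth rate
``mu_max`` after a hard lag delay, and saturate at a carrying capacity
``x_max``.  The module also provides the illustrative chemostat solution and
the analytic minimum growth rate a culture needs to survive periodic
sample-withdrawal-and-replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StrainParams",
    "WellState",
    "advance_well",
    "chemostat_trajectory",
    "min_sustainable_mu",
]


@dataclass(frozen=True)
class StrainParams:
    """Intrinsic growth characteristics of the strain occupying one well.

    Parameters
    ----------
    label:
        Free-text strain identifier.
    mu_max:
        Maximum specific growth rate in h^-1.
    lag_time:
        Hard lag before exponential growth starts, in hours.
    x0:
        Initial biomass concentration (OD600-equivalent).
    x_max:
        Carrying capacity (OD600-equivalent); growth stops at this density.
    """

    label: str
    mu_max: float
    lag_time: float = 0.0
    x0: float = 0.1
    x_max: float = 3.0

    def __post_init__(self) -> None:
        if self.mu_max < 0:
            raise ValueError(f"mu_max must be >= 0, got {self.mu_max}")
        if self.lag_time < 0:
            raise ValueError(f"lag_time must be >= 0, got {self.lag_time}")
        if not 0 < self.x0 <= self.x_max:
            raise ValueError(
                f"require 0 < x0 <= x_max, got x0={self.x0}, x_max={self.x_max}"
            )


@dataclass(frozen=True)
class WellState:
    """True physical state of one well at elapsed time ``t``.

    ``x_true`` is the biomass concentration (OD600-equivalent), ``volume``
    the liquid volume in µL.
    """

    x_true: float
    volume: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x_true < 0:
            raise ValueError(f"x_true must be >= 0, got {self.x_true}")
        if self.volume <= 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")


def advance_well(state: WellState, params: StrainParams, dt: float) -> WellState:
    """Advance a well by ``dt`` hours of undisturbed growth.

    Growth is exponential at ``params.mu_max`` once elapsed time has passed
    ``params.lag_time``, and is capped at ``params.x_max``.  Volume is
    unchanged (no evaporation model).  The closed form makes the map a
    semigroup: advancing by ``a`` then ``b`` equals advancing by ``a + b``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    t_end = state.t + dt
    # effective growth time: the part of [t, t+dt] past the lag
    g = max(0.0, t_end - max(state.t, params.lag_time))
    x = min(state.x_true * math.exp(params.mu_max * g), params.x_max)
    return WellState(x_true=x, volume=state.volume, t=t_end)


def chemostat_trajectory(x0: float, mu: float, dilution_rate: float, t):
    """Biomass of an ideal chemostat: ``x0 * exp((mu - D) * t)``.

    At ``mu == D`` the culture sits at steady state.  Substrate limitation is
    ignored; this is the textbook washout/steady-state contrast used to
    illustrate continuous-cultivation modes.  ``t`` may be a scalar or a
    numpy array of times (hours).
    """
    import numpy as np

    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = x0 * np.exp((mu - dilution_rate) * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def min_sustainable_mu(volume: float, sample_vol: float, cycle_time: float) -> float:
    """Minimum specific growth rate that offsets periodic sampling losses.

    Each cycle a ``sample_vol`` µL sample is withdrawn from ``volume`` µL of
    culture and replaced with fresh medium, passively diluting the biomass by
    ``(volume - sample_vol) / volume``.  Growth sustains the culture iff
    ``mu >= ln(volume / (volume - sample_vol)) / cycle_time``.
    """
    if not 0 <= sample_vol < volume:
        raise ValueError(
            f"require 0 <= sample_vol < volume, got sample_vol={sample_vol}, "
            f"volume={volume}"
        )
    if cycle_time <= 0:
        raise ValueError(f"cycle_time must be > 0, got {cycle_time}")
    return math.log(volume / (volume - sample_vol)) / cycle_time
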