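"""Simulated sampling-and-reading step of the cultivation cycle.

A sample is withdrawn from the well, diluted (1:5 by default) into a read
plate, and its OD600 measured with multiplicative plus additive noise.  The
reported value is back-calculated to culture scale (raw reading times the
read dilution), which is what the controller consumes — matching a platform
that reports culture ODs from diluted reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import WellState

__all__ = ["MeasurementConfig", "ODReading", "read_od"]


@dataclass(frozen=True)
class MeasurementConfig:
    """Sampling and plate-reader model.

    ``mult_cv`` is the relative (multiplicative) noise fraction and ``add_sd``
    the additive noise SD on the raw (at-reader) OD scale; the defaults give a
    low-OD relative error comparable to the growth-rate misestimation seen in
    early control cycles on real readers.  ``reader_min``/``reader_max``
    delimit the reader's trusted linear range on the raw scale; the 1:5
    read dilution exists precisely to keep exponential-phase cultures inside
    it.
    """

    sample_vol: float = 20.0
    read_dilution: float = 5.0
    mult_cv: float = 0.02
    add_sd: float = 0.01
    reader_min: float = 0.0
    reader_max: float = 1.0

    def __post_init__(self) -> None:
        if self.read_dilution < 1:
            raise ValueError(f"read_dilution must be >= 1, got {self.read_dilution}")
        if self.mult_cv < 0 or self.add_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not self.reader_min < self.reader_max:
            raise ValueError("require reader_min < reader_max")
        if self.sample_vol <= 0:
            raise ValueError(f"sample_vol must be > 0, got {self.sample_vol}")


@dataclass(frozen=True)
class ODReading:
    """One OD600 reading: raw at-reader value and culture-scale report."""

    well_id: str
    t: float
    raw: float
    reported: float
    in_range: bool


def read_od(
    state: WellState,
    cfg: MeasurementConfig,
    rng: np.random.Generator,
    well_id: str = "",
) -> tuple[ODReading, WellState]:
    """Withdraw a sample, dilute, and read OD600 with noise.

    The raw reading is ``(x_true / d) * (1 + eps_m) + eps_a`` with
    ``eps_m ~ N(0, mult_cv)``, ``eps_a ~ N(0, add_sd)``, truncated at zero;
    the reported culture OD is ``raw * d``.  Sampling removes ``sample_vol``
    µL of suspension: the returned state has reduced volume but unchanged
    concentration.
    """
    if cfg.sample_vol >= state.volume:
        raise ValueError(
            f"sample_vol {cfg.sample_vol} exceeds available volume {state.volume}"
        )
    d = cfg.read_dilution
    eps_m = rng.normal(0.0, cfg.mult_cv)
    eps_a = rng.normal(0.0, cfg.add_sd)
    raw = max(0.0, (state.x_true / d) * (1.0 + eps_m) + eps_a)
    reading = ODReading(
        well_id=well_id,
        t=state.t,
        raw=raw,
        reported=raw * d,
        in_range=cfg.reader_min <= raw <= cfg.reader_max,
    )
    sampled = WellState(
        x_true=state.x_true, volume=state.volume - cfg.sample_vol, t=state.t
    )
    return reading, sampled
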