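"""Validated configuration objects shared across the pipeline.

All time-lapse parameters are in minutes, dose schedules in hours (matching
the conventions of the imaging and pharmacology experiments they describe),
glucose concentrations in mM, inhibitor concentrations in μM.
"""
from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

import numpy as np


class BiosensorModel(BaseModel):
    """Saturable response of the glucose FRET biosensor.

    The emitted acceptor/donor ratio rises with intracellular glucose G (mM)
    following a Hill curve::

        R(G) = r_min + (r_max - r_min) * G^h / (Kd^h + G^h)

    The sensor's true Kd and dynamic range in ratio units are instrument- and
    construct-specific; the defaults below are placeholders chosen to give a
    ratio range of 1-3 with half-saturation at 0.6 mM and must be configured
    for any quantitative use.
    """

    r_min: float = 1.0
    r_max: float = 3.0
    kd: float = 0.6
    hill: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "BiosensorModel":
        if not (self.r_max > self.r_min > 0):
            raise ValueError("require r_max > r_min > 0")
        if self.kd <= 0 or self.hill <= 0:
            raise ValueError("kd and hill must be positive")
        return self

    def response(self, glucose: np.ndarray | float) -> np.ndarray | float:
        """Map intracellular glucose (mM) to the noiseless FRET ratio."""
        g = np.maximum(np.asarray(glucose, dtype=float), 0.0)
        gh = g ** self.hill
        out = self.r_min + (self.r_max - self.r_min) * gh / (self.kd ** self.hill + gh)
        return out if out.ndim else float(out)


class ScenarioConfig(BaseModel):
    """One simulated time-lapse experiment.

    ``glucose_media_schedule`` is a list of (time_min, extracellular_mM)
    switch points; the medium holds each concentration until the next switch.
    ``heritability_rho`` is the AR(1) coefficient linking a daughter cell's
    standardized glycolytic state to its parent's.
    """

    n_cells: int = Field(gt=0, default=100)
    duration: float = Field(gt=0, default=600.0)  # minutes
    frame_interval: float = Field(gt=0, default=5.0)  # minutes
    glucose_media_schedule: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.0, 25.0)]
    )
    state_mix: dict[str, float] = Field(
        default_factory=lambda: {"high": 0.5, "low": 0.5}
    )
    heritability_rho: float = 0.8
    division_rate: float = 0.04  # divisions per hour per cell
    noise_sd: float = 0.02  # additive ratio noise per frame
    seed: int = 0
    # sensor / kinetic constants (see docs/methods.md)
    km_consumption: float = 2.0  # mM, Michaelis constant of consumption
    k_media: float = 1.0  # mM, half-saturation of media-dependent uptake
    motion_sd: float = 0.3  # px/frame random-walk step for rendered movies

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if not (0.0 <= self.heritability_rho <= 1.0):
            raise ValueError("heritability_rho must lie in [0, 1]")
        if self.division_rate < 0:
            raise ValueError("division_rate must be >= 0")
        if abs(sum(self.state_mix.values()) - 1.0) > 1e-9:
            raise ValueError("state_mix fractions must sum to 1")
        times = [t for t, _ in self.glucose_media_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("glucose_media_schedule times must be strictly increasing")
        if any(t < 0 or t > self.duration for t in times):
            raise ValueError("schedule times must lie within [0, duration]")
        if any(g < 0 for _, g in self.glucose_media_schedule):
            raise ValueError("media glucose must be >= 0")
        return self

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def media_glucose(self, t: np.ndarray | float) -> np.ndarray:
        """Extracellular glucose (mM) at time t: piecewise-constant schedule."""
        times = np.array([s[0] for s in self.glucose_media_schedule])
        values = np.array([s[1] for s in self.glucose_media_schedule])
        idx = np.clip(np.searchsorted(times, np.atleast_1d(t), side="right") - 1, 0, None)
        return values[idx]


class DoseSchedule(BaseModel):
    """Stepped inhibitor schedule: (start_time_h, concentration_uM) per step.

    By default each step is assayed just before the next step begins (and the
    last step at ``end_time``), so the measured ratio reflects the full dwell
    at that concentration.
    """

    steps: list[tuple[float, float]]
    end_time: float = 4.0  # h
    assay_times: Optional[list[float]] = None
    washout: bool = False

    @model_validator(mode="after")
    def _check(self) -> "DoseSchedule":
        if len(self.steps) == 0:
            raise ValueError("schedule must contain at least one step")
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("step times must be strictly increasing")
        concs = [c for _, c in self.steps]
        if not self.washout and any(b < a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be non-decreasing unless washout is set")
        if self.assay_times is not None and len(self.assay_times) != len(self.steps):
            raise ValueError("one assay time per step required")
        return self

    @property
    def concentrations(self) -> list[float]:
        return [c for _, c in self.steps]

    def resolved_assay_times(self) -> list[float]:
        if self.assay_times is not None:
            return list(self.assay_times)
        starts = [t for t, _ in self.steps]
        return [*starts[1:], self.end_time]


def default_dose_schedule() -> DoseSchedule:
    """The stepped PI3K-inhibitor protocol: 0, 0.05, 0.1, 0.5 μM at 0-3 h."""
    return DoseSchedule(steps=[(0.0, 0.0), (1.0, 0.05), (2.0, 0.1), (3.0, 0.5)], end_time=4.0)
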