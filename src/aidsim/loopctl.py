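"""Loop-style dosing controller (model-predictive, temp-basal only).

Loop builds a *single* glucose forecast as the sum of component effects on
top of the current reading: the expected effect of delivered insulin, a
glucose-momentum term extrapolating the recent rate of change, and a
retrospective correction driven by the discrepancy between what the
controller predicted and what the CGM then observed.  (A carbohydrate
component exists in normal use but is identically zero here: the challenge
runs without meal announcements.)

* **Momentum** uses the 5-min rates of change from the prior 20 min,
  weighted 1:2:3:4 oldest to newest, extrapolated forward and linearly
  blended to zero over ``momentum_blend`` minutes.
* **Retrospective correction** (standard) adds the mean recent
  prediction--observation discrepancy to the forecast, decayed linearly to
  zero over ``rc_decay_horizon``.  The *integral* variant additionally
  adds a gain times an exponentially forgotten running sum of
  discrepancies (clamped relative to the standard term) for more rapid
  adaptation to sustained disturbances.

Dosing is by temporary basal rate only -- the command type has no bolus
field.  A suspend threshold forces a zero temp basal whenever any actual
or predicted glucose falls below it; otherwise the rate delivers
``min((eventual - target_mid)/ISF, (min_pred - suspend)/ISF)`` units over
a 30-min window on top of the scheduled basal.
"""

from __future__ import annotations

import dataclasses
from collections import deque

import numpy as np

from .insulin import InsulinActionCurve, LOOP_CURVE, future_insulin_delta
from .pig import PigParams

__all__ = [
    "LoopConfig",
    "Forecast",
    "TempBasalCommand",
    "insulin_effect",
    "momentum",
    "retrospective_correction",
    "make_forecast",
    "recommend_temp_basal",
    "LoopController",
]


@dataclasses.dataclass(frozen=True)
class LoopConfig:
    target_range: tuple[float, float] = (100.0, 115.0)  # mg/dl
    suspend_threshold: float = 70.0  # mg/dl
    momentum_window: int = 20  # minutes of rate-of-change history
    momentum_blend: int = 30  # minutes to blend momentum to zero
    rc_window: int = 30  # minutes of discrepancies averaged
    rc_decay_horizon: int = 60  # minutes to decay the correction to zero
    integral_rc: bool = True
    integral_gain: float = 0.1
    integral_cap_factor: float = 3.0  # cap = factor * |standard term|
    forecast_horizon: int = 240  # minutes
    step: int = 5  # minutes per cycle
    max_temp_basal: float = 35.0  # U/h
    temp_duration: int = 30  # minutes
    max_stored_forecasts: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.target_range
        if not lo <= hi:
            raise ValueError("target_range must be (low, high) with low <= high")
        if not self.suspend_threshold < lo:
            raise ValueError("suspend_threshold must be below the target range")
        if self.forecast_horizon <= 0 or self.rc_decay_horizon <= 0:
            raise ValueError("horizons must be > 0")

    @property
    def target_mid(self) -> float:
        return 0.5 * (self.target_range[0] + self.target_range[1])


@dataclasses.dataclass
class Forecast:
    """A single predicted BG path and its component decomposition."""

    start: float  # minute the forecast was issued
    times: np.ndarray  # minutes from start (first entry 0)
    values: np.ndarray  # mg/dl
    components: dict[str, np.ndarray]

    @property
    def eventual(self) -> float:
        return float(self.values[-1])

    @property
    def minimum(self) -> float:
        return float(np.min(self.values))


@dataclasses.dataclass(frozen=True)
class TempBasalCommand:
    """Loop output: a temporary basal rate only (no bolus field exists)."""

    temp_basal: float  # U/h
    duration: int  # minutes
    reason: str = ""


def _grid(config: LoopConfig) -> np.ndarray:
    return np.arange(0.0, config.forecast_horizon + 0.5 * config.step, config.step)


def insulin_effect(
    net_doses,
    curve: InsulinActionCurve,
    isf: float,
    config: LoopConfig,
    now: float = 0.0,
) -> np.ndarray:
    """Cumulative expected BG change from delivered insulin vs scheduled basal."""
    grid = _grid(config)
    if not net_doses:
        return np.zeros_like(grid)
    arr = np.asarray(net_doses, dtype=float)
    return future_insulin_delta(arr[:, 0], arr[:, 1], now, grid, curve, isf)


def momentum(times, readings, config: LoopConfig) -> np.ndarray:
    """Momentum component: recency-weighted recent slope, blended to zero.

    Needs the last ``momentum_window`` minutes of 5-min readings (four
    deltas); with fewer, or with a gap, the component is zero.
    """
    grid = _grid(config)
    t = np.asarray(times, dtype=float)
    bg = np.asarray(readings, dtype=float)
    n_deltas = config.momentum_window // config.step
    if t.size < n_deltas + 1:
        return np.zeros_like(grid)
    t, bg = t[-(n_deltas + 1):], bg[-(n_deltas + 1):]
    if np.any(np.diff(t) > config.step + 2.5):
        return np.zeros_like(grid)
    deltas = np.diff(bg)
    w = np.arange(1, n_deltas + 1, dtype=float)
    slope = float(np.dot(w, deltas) / w.sum())  # mg/dl per step
    k = np.arange(1, grid.size, dtype=float)
    taper = np.maximum(0.0, 1.0 - (k - 1.0) * config.step / config.momentum_blend)
    return np.concatenate([[0.0], np.cumsum(slope * taper)])


def retrospective_correction(
    disc_times,
    discrepancies,
    config: LoopConfig,
    now: float,
) -> np.ndarray:
    """Retrospective-correction component from stored discrepancies.

    ``discrepancies[i]`` is observed-minus-predicted glucose at
    ``disc_times[i]`` (each paired with the forecast issued ``rc_window``
    minutes earlier).  The correction term is the mean discrepancy over
    the last ``rc_window`` minutes; integral mode adds a clamped,
    exponentially forgotten running sum for more rapid adaptation.

    The term is applied as a glucose velocity -- the discrepancy accrued
    over one correction window is re-applied over the coming one, with the
    rate blended linearly to zero by ``rc_decay_horizon`` -- so the
    forecast is shifted by (approximately) the discrepancy itself and the
    shift persists to the forecast's eventual value.  Once observations
    track predictions again the correction returns to zero within the
    decay horizon.
    """
    grid = _grid(config)
    t = np.asarray(disc_times, dtype=float)
    d = np.asarray(discrepancies, dtype=float)
    recent = (t > now - config.rc_window) & (t <= now)
    if not np.any(recent):
        return np.zeros_like(grid)
    standard = float(np.mean(d[recent]))
    corr = standard
    if config.integral_rc:
        lam = 0.5 ** (config.step / config.rc_window)  # half-life = rc_window
        ages = (now - t) / config.step
        integral = float(np.dot(lam**ages, d))
        cap = config.integral_cap_factor * abs(standard)
        corr = standard + float(np.clip(config.integral_gain * integral, -cap, cap))
    k = np.arange(1, grid.size, dtype=float)
    taper = np.maximum(0.0, 1.0 - (k - 1.0) * config.step / config.rc_decay_horizon)
    rate = corr / config.rc_window * config.step  # mg/dl per forecast step
    return np.concatenate([[0.0], np.cumsum(rate * taper)])


def make_forecast(
    current_bg: float,
    components: dict[str, np.ndarray],
    config: LoopConfig,
    start: float = 0.0,
) -> Forecast:
    """Sum the component arrays into a single predicted BG path."""
    grid = _grid(config)
    total = np.full_like(grid, float(current_bg))
    for arr in components.values():
        if arr.shape != grid.shape:
            raise ValueError("component arrays must share the forecast grid")
        total = total + arr
    return Forecast(start=start, times=grid, values=total, components=dict(components))


def recommend_temp_basal(
    forecast: Forecast,
    basal_rate: float,
    isf: float,
    config: LoopConfig,
) -> TempBasalCommand:
    """Temp-basal recommendation pushing the forecast toward target."""
    if forecast.minimum < config.suspend_threshold:
        return TempBasalCommand(0.0, config.temp_duration,
                                f"suspend: minPred={forecast.minimum:.0f}")
    units = min(
        (forecast.eventual - config.target_mid) / isf,
        (forecast.minimum - config.suspend_threshold) / isf,
    )
    rate = float(np.clip(basal_rate + 2.0 * units, 0.0, config.max_temp_basal))
    return TempBasalCommand(
        rate, config.temp_duration,
        f"eventual={forecast.eventual:.0f} minPred={forecast.minimum:.0f}"
    )


class LoopController:
    """Stateful 5-min-cycle wrapper around the Loop forecast and dosing."""

    def __init__(
        self,
        pig: PigParams,
        curve: InsulinActionCurve | None = None,
        config: LoopConfig | None = None,
    ) -> None:
        self.basal_rate = pig.basal_rate
        self.isf = pig.isf
        self.curve = curve if curve is not None else LOOP_CURVE
        self.config = config if config is not None else LoopConfig()
        self.net_doses: list[tuple[float, float]] = []
        self.past_forecasts: deque[Forecast] = deque(
            maxlen=self.config.max_stored_forecasts
        )
        self._disc_times: deque[float] = deque(maxlen=48)
        self._discs: deque[float] = deque(maxlen=48)

    def notify_delivery(self, minute: float, delivered_units: float) -> None:
        net = delivered_units - self.basal_rate / 60.0
        if abs(net) > 1e-12:
            self.net_doses.append((float(minute), float(net)))
        cutoff = minute - self.curve.dia
        while self.net_doses and self.net_doses[0][0] < cutoff:
            self.net_doses.pop(0)

    def _update_discrepancy(self, now: float, bg: float) -> None:
        """Record observed-minus-predicted glucose for the current reading.

        The observation is paired with the forecast issued ``rc_window``
        minutes ago -- the discrepancy measures how the world diverged from
        the prediction over the whole correction window, which is what
        makes unannounced-meal excursions (and insulin-driven falls the
        model did not anticipate) visible to the correction.
        """
        ref = None
        for fc in self.past_forecasts:  # oldest first; keep latest old-enough
            if fc.start <= now - self.config.rc_window:
                ref = fc
            else:
                break
        if ref is None:
            return
        offset = now - ref.start
        if offset > ref.times[-1]:
            return
        predicted = float(np.interp(offset, ref.times, ref.values))
        self._disc_times.append(now)
        self._discs.append(bg - predicted)

    def decide(self, now: float, times, readings) -> TempBasalCommand:
        bg = float(readings[-1])
        self._update_discrepancy(now, bg)
        cfg = self.config
        comps = {
            "insulin": insulin_effect(self.net_doses, self.curve, self.isf, cfg,
                                      now=now),
            "momentum": momentum(times, readings, cfg),
            "retrospective": retrospective_correction(self._disc_times, self._discs,
                                                      cfg, now),
        }
        fc = make_forecast(bg, comps, cfg, start=now)
        self.past_forecasts.append(fc)
        return recommend_temp_basal(fc, self.basal_rate, self.isf, cfg)
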