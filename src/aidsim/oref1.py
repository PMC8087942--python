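"""oref1-style dosing controller (the OpenAPS/AndroidAPS algorithm family).

Every 5-min CGM cycle the controller:

1. computes *deviations* -- how much glucose moved over each recent 5-min
   interval relative to what insulin activity alone predicts;
2. builds three parallel forecasts over the dosing horizon:
   insulin-only (``IOBpredBGs``), zero-temp (``ZTpredBGs``, the worst-case
   path if carbohydrate absorption ceases and basal delivery is suspended
   from now on) and unannounced-meal (``UAMpredBGs``, which extrapolates
   the deviation series to zero and integrates it on top of the
   insulin-only path);
3. blends them into a minimum predicted glucose
   ``minPredBG = max(min IOBpred from 90 min on,
   (min UAMpred from 60 min on + min ZTpred) / 2)``;
4. converts it to an insulin requirement
   ``insulinReq = (minPredBG - target) / ISF`` and doses half of it as a
   supermicrobolus (SMB) -- capped by 30 min of scheduled basal and by the
   max-IOB headroom -- with the remainder expressed as a 30-min temporary
   basal; a negative requirement becomes a low/zero temporary basal.

Deviation extrapolation for the unannounced-meal forecast follows three
cases: deviations falling at a reasonable rate continue at that rate until
they reach zero; deviations falling too slowly are forced linearly to zero
over 3 h; rising deviations are assumed to peak immediately and decay at
one-third of the rate at which they rose from their recent minimum (never
slower than the 3-h linear decay).

All insulin bookkeeping is net of the scheduled basal rate: boluses and
temp-basal excursions count positive, withheld basal counts negative.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .insulin import InsulinActionCurve, PIG_CURVE, absorbed_between, future_insulin_delta
from .pig import PigParams

__all__ = [
    "Oref1Config",
    "GlucoseHistory",
    "PredictionSet",
    "DoseCommand",
    "compute_deviations",
    "extrapolate_deviations",
    "predict_iob",
    "predict_zt",
    "predict_uam",
    "min_pred_bg",
    "insulin_req",
    "recommend_dose",
    "Oref1Controller",
]

#: Forecasts never drop below this clamp, mg/dl.
BG_CLAMP = 39.0


@dataclasses.dataclass(frozen=True)
class Oref1Config:
    target: float = 110.0  # mg/dl
    max_iob: float = 2.0  # U
    max_temp_basal: float = 35.0  # U/h (pump ceiling)
    smb_enabled: bool = True
    uam_enabled: bool = True
    forecast_horizon: int = 240  # minutes
    step: int = 5  # minutes per cycle
    smb_step: float = 0.05  # U pump granularity
    temp_duration: int = 30  # minutes
    uam_recent_min_window: int = 60  # minutes, lookback for the rise rule

    def __post_init__(self) -> None:
        if not 80.0 <= self.target <= 200.0:
            raise ValueError(f"target must be in [80, 200] mg/dl, got {self.target}")
        if self.max_iob <= 0 or self.max_temp_basal <= 0:
            raise ValueError("max_iob and max_temp_basal must be > 0")
        if self.forecast_horizon < 90:
            raise ValueError("forecast_horizon must be >= 90 min")


@dataclasses.dataclass
class GlucoseHistory:
    """Recent CGM readings plus the controller's net insulin dose log."""

    times: np.ndarray  # minutes, strictly increasing
    readings: np.ndarray  # mg/dl
    net_doses: list[tuple[float, float]]  # (minute, units net of scheduled basal)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.size != self.readings.size:
            raise ValueError("times and readings differ in length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclasses.dataclass
class PredictionSet:
    """The three parallel forecasts on a shared 5-min time base."""

    times: np.ndarray  # minutes from now (starting at 0)
    iob: np.ndarray  # IOBpredBGs
    zt: np.ndarray  # ZTpredBGs
    uam: np.ndarray  # UAMpredBGs


@dataclasses.dataclass(frozen=True)
class DoseCommand:
    """Controller output: a microbolus and/or a temporary basal rate."""

    smb: float  # U, >= 0
    temp_basal: float  # U/h
    duration: int  # minutes
    reason: str = ""


def _dose_arrays(net_doses) -> tuple[np.ndarray, np.ndarray]:
    if not net_doses:
        return np.empty(0), np.empty(0)
    arr = np.asarray(net_doses, dtype=float)
    return arr[:, 0], arr[:, 1]


def compute_deviations(
    history: GlucoseHistory,
    curve: InsulinActionCurve,
    isf: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval deviation: observed 5-min BG change minus insulin-expected.

    Returns ``(interval_end_times, deviations)``; intervals with reading
    gaps over 10 min are skipped.
    """
    t, bg = history.times, history.readings
    if t.size < 2:
        return np.empty(0), np.empty(0)
    m, u = _dose_arrays(history.net_doses)
    out_t, out_d = [], []
    for i in range(1, t.size):
        dt = t[i] - t[i - 1]
        if dt > 10.0:
            continue
        expected = -isf * absorbed_between(m, u, t[i - 1], t[i], curve)
        out_t.append(t[i])
        out_d.append((bg[i] - bg[i - 1]) - expected)
    return np.asarray(out_t), np.asarray(out_d)


def _horizon_grid(config: Oref1Config) -> np.ndarray:
    return np.arange(0.0, config.forecast_horizon + 0.5 * config.step, config.step)


def predict_iob(
    current_bg: float,
    net_doses,
    curve: InsulinActionCurve,
    isf: float,
    config: Oref1Config,
    now: float = 0.0,
) -> np.ndarray:
    """Insulin-only forecast: BG under remaining net insulin action."""
    grid = _horizon_grid(config)
    m, u = _dose_arrays(net_doses)
    delta = future_insulin_delta(m, u, now, grid, curve, isf)
    return np.clip(current_bg + delta, BG_CLAMP, None)


def predict_zt(
    current_bg: float,
    net_doses,
    curve: InsulinActionCurve,
    isf: float,
    basal_rate: float,
    config: Oref1Config,
    now: float = 0.0,
) -> np.ndarray:
    """Zero-temp forecast: insulin-only path with basal suspended from now.

    Each future minute of withheld scheduled basal is a negative dose whose
    absorbed fraction raises the forecast.
    """
    grid = _horizon_grid(config)
    m, u = _dose_arrays(net_doses)
    delta = future_insulin_delta(m, u, now, grid, curve, isf)
    # Withheld basal: at horizon t the minute-dose withheld at future minute
    # f (1 <= f <= t) has absorbed a fraction 1 - iob(t - f).
    n = int(config.forecast_horizon)
    absorbed = 1.0 - curve.iob(np.arange(n, dtype=float))
    cum = np.concatenate([[0.0], np.cumsum(absorbed)])  # index by t minutes
    withheld = isf * (basal_rate / 60.0) * cum[grid.astype(int)]
    return np.clip(current_bg + delta + withheld, BG_CLAMP, None)


def extrapolate_deviations(
    deviations: np.ndarray,
    dev_times: np.ndarray,
    config: Oref1Config,
) -> np.ndarray:
    """Future deviation per 5-min step under the three-case rule.

    Returns one value per future step (first entry = the interval ending
    ``step`` minutes from now).  Extrapolated deviations are clamped at
    zero once they reach it, and always reach zero within 180 min.
    """
    n_steps = int(config.forecast_horizon // config.step)
    d = np.asarray(deviations, dtype=float)
    if d.size < 3 or d[-1] <= 0.0:
        return np.zeros(n_steps)
    d0 = d[-1]
    slope = d[-1] - d[-2]  # per step
    floor_slope = -d0 / (180.0 / config.step)  # linear to zero over 3 h
    if slope < 0.0:
        eff = min(slope, floor_slope)  # too-slow decay forced onto the 3-h line
    else:
        t = np.asarray(dev_times, dtype=float)
        recent = t >= t[-1] - config.uam_recent_min_window
        dr, tr = d[recent], t[recent]
        i_min = int(np.argmin(dr))
        steps_since_min = max((tr[-1] - tr[i_min]) / config.step, 1.0)
        rise_rate = (d0 - dr[i_min]) / steps_since_min
        eff = -rise_rate / 3.0 if rise_rate > 0 else floor_slope
        eff = min(eff, floor_slope)
    k = np.arange(1, n_steps + 1, dtype=float)
    return np.maximum(0.0, d0 + eff * k)


def predict_uam(
    current_bg: float,
    deviations: np.ndarray,
    config: Oref1Config,
    dev_times: np.ndarray | None = None,
    iob_pred: np.ndarray | None = None,
) -> np.ndarray:
    """Unannounced-meal forecast: extrapolated deviations on the IOB path."""
    grid = _horizon_grid(config)
    if iob_pred is None:
        iob_pred = np.full_like(grid, current_bg)
    if dev_times is None:
        dev_times = config.step * np.arange(len(deviations), dtype=float)
    extra = extrapolate_deviations(np.asarray(deviations, float),
                                   np.asarray(dev_times, float), config)
    carb_delta = np.concatenate([[0.0], np.cumsum(extra)])[: grid.size]
    return np.clip(iob_pred + carb_delta, BG_CLAMP, None)


def min_pred_bg(predictions: PredictionSet, config: Oref1Config) -> float:
    """Blend the three forecasts into the dosing floor.

    ``max(min IOBpred over [90, horizon],
    (min UAMpred over [60, horizon] + min ZTpred over [0, horizon]) / 2)``.
    """
    g = predictions.times
    min_iob = float(np.min(predictions.iob[g >= 90.0]))
    min_uam = float(np.min(predictions.uam[g >= 60.0]))
    min_zt = float(np.min(predictions.zt))
    return max(min_iob, 0.5 * (min_uam + min_zt))


def insulin_req(min_pred: float, target: float, isf: float) -> float:
    """Units needed to bring the minimum predicted BG to target (may be < 0)."""
    if isf <= 0:
        raise ValueError("isf must be > 0")
    return (min_pred - target) / isf


def recommend_dose(
    req: float,
    basal_rate: float,
    current_iob: float,
    config: Oref1Config,
) -> DoseCommand:
    """Convert an insulin requirement into an SMB and/or temp basal.

    SMB = min(req/2, 30 min of scheduled basal, max-IOB headroom), rounded
    down to the pump step; the remainder (still headroom-capped) becomes a
    30-min temporary basal.  A non-positive requirement becomes a
    below-scheduled temp basal, down to zero.
    """
    caps: list[str] = []
    if req > 0.0:
        headroom = max(0.0, config.max_iob - current_iob)
        smb = 0.0
        if config.smb_enabled:
            smb = min(req / 2.0, 0.5 * basal_rate, headroom)
            if smb == 0.5 * basal_rate:
                caps.append("30min-basal")
            if smb == headroom:
                caps.append("maxIOB")
            smb = max(0.0, math.floor(smb / config.smb_step + 1e-9) * config.smb_step)
        rest = max(0.0, min(req - smb, headroom - smb))
        rate = basal_rate + 2.0 * rest  # deliver the remainder over 30 min
        if rate > config.max_temp_basal:
            rate = config.max_temp_basal
            caps.append("maxTempBasal")
        reason = f"insulinReq={req:.3f}U" + (f" caps={'+'.join(caps)}" if caps else "")
        return DoseCommand(smb, rate, config.temp_duration, reason)
    rate = min(config.max_temp_basal, max(0.0, basal_rate + 2.0 * req))
    return DoseCommand(0.0, rate, config.temp_duration,
                       f"insulinReq={req:.3f}U low-temp")


class Oref1Controller:
    """Stateful 5-min-cycle wrapper around the oref1 dosing calculus."""

    def __init__(
        self,
        pig: PigParams,
        curve: InsulinActionCurve | None = None,
        config: Oref1Config | None = None,
    ) -> None:
        self.basal_rate = pig.basal_rate
        self.isf = pig.isf
        self.curve = curve if curve is not None else PIG_CURVE
        self.config = config if config is not None else Oref1Config()
        self.net_doses: list[tuple[float, float]] = []

    def notify_delivery(self, minute: float, delivered_units: float) -> None:
        """Record actual pump delivery for one minute (bolus + basal)."""
        net = delivered_units - self.basal_rate / 60.0
        if abs(net) > 1e-12:
            self.net_doses.append((float(minute), float(net)))
        # Keep only doses still acting.
        cutoff = minute - self.curve.dia
        while self.net_doses and self.net_doses[0][0] < cutoff:
            self.net_doses.pop(0)

    def current_iob(self, now: float) -> float:
        """Net insulin on board, units (negative when basal was withheld)."""
        m, u = _dose_arrays(self.net_doses)
        if m.size == 0:
            return 0.0
        return float(np.dot(u, self.curve.iob(now - m)))

    def predictions(self, now: float, times, readings) -> PredictionSet:
        bg = float(readings[-1])
        cfg = self.config
        grid = _horizon_grid(cfg)
        iob_p = predict_iob(bg, self.net_doses, self.curve, self.isf, cfg, now=now)
        zt_p = predict_zt(bg, self.net_doses, self.curve, self.isf,
                          self.basal_rate, cfg, now=now)
        hist = GlucoseHistory(np.asarray(times, float)[-20:],
                              np.asarray(readings, float)[-20:], self.net_doses)
        dev_t, devs = compute_deviations(hist, self.curve, self.isf)
        if cfg.uam_enabled and devs.size >= 3:
            uam_p = predict_uam(bg, devs, cfg, dev_times=dev_t, iob_pred=iob_p)
        else:
            uam_p = iob_p.copy()
        return PredictionSet(times=grid, iob=iob_p, zt=zt_p, uam=uam_p)

    def decide(self, now: float, times, readings) -> DoseCommand:
        preds = self.predictions(now, times, readings)
        mp = min_pred_bg(preds, self.config)
        req = insulin_req(mp, self.config.target, self.isf)
        cmd = recommend_dose(req, self.basal_rate, self.current_iob(now), self.config)
        return dataclasses.replace(
            cmd, reason=f"minPredBG={mp:.0f} " + cmd.reason
        )
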