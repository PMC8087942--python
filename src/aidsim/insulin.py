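"""Exponential insulin activity and insulin-on-board (IOB) kinetics.

Subcutaneous rapid-acting insulin is modelled with the two-parameter
exponential family used by the open-source closed-loop community
(oref1/AndroidAPS and Loop).  A dose's *activity* -- the fraction of the
dose acting per minute -- rises from an optional onset delay, peaks at
``tpa`` minutes after injection, and returns to zero at ``dia`` minutes
(the duration of insulin action).  The curve integrates to exactly one
dose, and IOB is its complementary survival function.

With ``tp = tpa - delay``, ``td = dia - delay`` and ``s = t - delay``::

    tau = tp * (1 - tp/td) / (1 - 2*tp/td)
    a   = 2 * tau / td
    S   = 1 / (1 - a + (1 + a) * exp(-td/tau))

    activity(s) = (S / tau**2) * s * (1 - s/td) * exp(-s/tau)
    iob(s)      = 1 - S*(1-a) * ((s**2/(tau*td*(1-a)) - s/tau - 1)
                                  * exp(-s/tau) + 1)

This parameterization requires the peak to fall in the first half of the
action window (``tp < td/2``); it then satisfies, by construction,
``iob(0) = 1``, ``iob(td) = 0``, a unique activity maximum exactly at
``tpa`` and unit total activity.

The fitted pig model used throughout the package peaks at 25 min with a
3-h duration; the Loop-variant curve additionally carries a 15-min onset
delay.
"""

from __future__ import annotations

import dataclasses
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ParameterizationError",
    "InsulinActionCurve",
    "PKSample",
    "InsulinFit",
    "make_action_curve",
    "fit_action_curve",
    "read_pk_samples",
    "future_insulin_delta",
    "absorbed_between",
    "PIG_CURVE",
    "LOOP_CURVE",
]


class ParameterizationError(ValueError):
    """(delay, tpa, dia) cannot define a valid exponential action curve."""


@dataclasses.dataclass(frozen=True)
class InsulinActionCurve:
    """Exponential insulin activity/IOB curve.

    Parameters
    ----------
    delay
        Onset lag in minutes; activity is exactly zero up to this time.
    tpa
        Time of peak activity, minutes after injection.
    dia
        Duration of insulin action, minutes after injection.
    """

    delay: float = 0.0
    tpa: float = 25.0
    dia: float = 180.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delay:
            raise ParameterizationError(f"delay must be >= 0, got {self.delay}")
        if not self.delay < self.tpa < self.dia:
            raise ParameterizationError(
                f"require delay < tpa < dia, got ({self.delay}, {self.tpa}, {self.dia})"
            )
        tp = self.tpa - self.delay
        td = self.dia - self.delay
        if not tp < td / 2.0:
            raise ParameterizationError(
                "peak must fall in the first half of the action window: "
                f"tpa-delay={tp} >= (dia-delay)/2={td / 2}"
            )

    @cached_property
    def _coeffs(self) -> tuple[float, float, float, float, float]:
        tp = self.tpa - self.delay
        td = self.dia - self.delay
        tau = tp * (1.0 - tp / td) / (1.0 - 2.0 * tp / td)
        a = 2.0 * tau / td
        s = 1.0 / (1.0 - a + (1.0 + a) * np.exp(-td / tau))
        return tp, td, tau, a, s

    def activity(self, t):
        """Fraction of a dose acting per minute at ``t`` minutes post-injection.

        Zero for ``t <= delay`` and ``t >= dia``; accepts scalars or arrays.
        """
        _, td, tau, a, scale = self._coeffs
        t = np.asarray(t, dtype=float)
        s = t - self.delay
        sc = np.clip(s, 0.0, td)
        val = (scale / tau**2) * sc * (1.0 - sc / td) * np.exp(-sc / tau)
        out = np.where((s > 0.0) & (s < td), val, 0.0)
        return float(out) if out.ndim == 0 else out

    def iob(self, t):
        """Fraction of a dose not yet acted at ``t`` minutes post-injection.

        ``iob(0) = 1``; monotone non-increasing; zero from ``dia`` onward.
        Times before injection (negative ``t``) return 1.
        """
        _, td, tau, a, scale = self._coeffs
        t = np.asarray(t, dtype=float)
        s = np.clip(t - self.delay, 0.0, td)
        val = 1.0 - scale * (1.0 - a) * (
            (s**2 / (tau * td * (1.0 - a)) - s / tau - 1.0) * np.exp(-s / tau) + 1.0
        )
        out = np.where(t - self.delay >= td, 0.0, np.clip(val, 0.0, 1.0))
        return float(out) if out.ndim == 0 else out

    def delivery_kernel(self, step: float = 1.0) -> np.ndarray:
        """Discrete absorbed fraction per ``step``-minute bin over [0, dia].

        ``kernel[j]`` is the fraction of a dose acting during
        ``[j*step, (j+1)*step)``.  Because the bins telescope over IOB the
        kernel sums to exactly 1, which makes dose mass balance exact in the
        minute-step simulator.
        """
        n = int(np.ceil(self.dia / step))
        edges = np.arange(n + 1, dtype=float) * step
        iobs = self.iob(edges)
        iobs[-1] = 0.0
        return -np.diff(iobs)


#: Fitted pig insulin model: immediate onset, peak 25 min, 3-h duration.
PIG_CURVE = InsulinActionCurve(0.0, 25.0, 180.0)
#: Loop-variant model: same peak/duration with a 15-min onset delay.
LOOP_CURVE = InsulinActionCurve(15.0, 25.0, 180.0)


def make_action_curve(delay: float, tpa: float, dia: float) -> InsulinActionCurve:
    """Construct a validated :class:`InsulinActionCurve`."""
    return InsulinActionCurve(delay, tpa, dia)


@dataclasses.dataclass(frozen=True)
class PKSample:
    """One pharmacokinetic sample: plasma insulin at a time post-injection."""

    time: float  # minutes since injection
    concentration: float  # arbitrary units, e.g. mU/L

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"sample time must be >= 0, got {self.time}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclasses.dataclass(frozen=True)
class InsulinFit:
    """Result of fitting the activity shape to PK samples."""

    curve: InsulinActionCurve
    scale: float  # concentration units per (fraction/min) of activity
    residual_norm: float  # RMS residual on peak-normalized concentrations
    n_samples: int


def fit_action_curve(samples, delay: float = 0.0) -> InsulinFit:
    """Least-squares fit of the scaled activity shape to concentration data.

    The onset ``delay`` is held fixed (0 for the pig/oref1 variant, 15 min
    for the Loop variant); ``tpa`` and ``dia`` are free.  Concentrations are
    peak-normalized before fitting so the reported residual norm is
    scale-free.

    Raises
    ------
    ValueError
        On fewer than 5 samples, all-zero concentrations, or samples taken
        at a single time point.
    """
    t = np.array([s.time for s in samples], dtype=float)
    c = np.array([s.concentration for s in samples], dtype=float)
    if t.size < 5:
        raise ValueError(f"need at least 5 PK samples, got {t.size}")
    if np.all(c == 0.0):
        raise ValueError("all concentrations are zero; nothing to fit")
    if np.unique(t).size < 2:
        raise ValueError("samples span a single time point; cannot fit a curve")

    cn = c / c.max()
    tp0 = float(np.clip(t[np.argmax(c)] - delay, 5.0, 120.0))
    m0 = 7.0
    guess = InsulinActionCurve(delay, delay + tp0, delay + tp0 * m0)
    a0 = 1.0 / guess.activity(guess.tpa)

    def resid(p):
        amp, tp, m = p
        curve = InsulinActionCurve(delay, delay + tp, delay + tp * m)
        return amp * curve.activity(t) - cn

    sol = least_squares(
        resid,
        x0=[a0, tp0, m0],
        bounds=([1e-6, 1.0, 2.05], [1e6, 240.0, 60.0]),
    )
    amp, tp, m = sol.x
    curve = InsulinActionCurve(delay, delay + tp, delay + tp * m)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return InsulinFit(curve=curve, scale=float(amp), residual_norm=rms, n_samples=t.size)


def read_pk_samples(path) -> list[PKSample]:
    """Read PK samples from a two-column CSV (minutes, concentration).

    A header row is required; column names are free but order is fixed.
    """
    df = pd.read_csv(Path(path), comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (minutes, concentration)")
    return [PKSample(float(r.iloc[0]), float(r.iloc[1])) for _, r in df.iterrows()]


def absorbed_between(dose_minutes, dose_units, t1: float, t2: float,
                     curve: InsulinActionCurve) -> float:
    """Units of insulin (from the given doses) absorbed during (t1, t2].

    Doses delivered inside the interval count only their partial absorption;
    ``curve.iob`` returns 1 before injection so the bookkeeping telescopes.
    """
    m = np.asarray(dose_minutes, dtype=float)
    u = np.asarray(dose_units, dtype=float)
    if m.size == 0:
        return 0.0
    return float(np.dot(u, curve.iob(t1 - m) - curve.iob(t2 - m)))


def future_insulin_delta(dose_minutes, dose_units, now: float,
                         horizon_offsets, curve: InsulinActionCurve,
                         isf: float) -> np.ndarray:
    """Expected future BG change (mg/dl) from already-delivered doses.

    For each horizon offset ``t`` (minutes from ``now``) returns
    ``-isf * sum_d u_d * (iob(now - t_d) - iob(now - t_d + t))``: the glucose
    impact of the insulin still scheduled to act.  Negative doses (withheld
    basal) contribute positive deltas.
    """
    offs = np.asarray(horizon_offsets, dtype=float)
    m = np.asarray(dose_minutes, dtype=float)
    u = np.asarray(dose_units, dtype=float)
    if m.size == 0:
        return np.zeros_like(offs)
    e0 = now - m
    remaining = curve.iob(e0)[:, None] - curve.iob(e0[:, None] + offs[None, :])
    return -isf * (u @ remaining)
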