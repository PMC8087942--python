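"""Virtual diabetic pig: minute-step glucose dynamics with a 5-min CGM.

The pig is an insulin-deficient (type-1-like) animal whose steady state is
constructed from its individually determined dosing parameters: a net
endogenous glucose production of ``isf * basal_rate / 60`` mg/dl per minute
exactly balances subcutaneous insulin delivered at the configured basal
rate, so a pig receiving its basal with no meals holds glucose constant.
Subcutaneous doses lower glucose through the exponential action curve
(total effect ``isf * units``), intravenous doses through a 90-min
triangular profile, and meal carbohydrate raises glucose through
triangular absorption profiles (total effect ``CSF * grams`` with
``CSF = ISF / ICR``).  A CGM samples the state every 5 minutes with
seedable Gaussian noise, a constant bias and a reporting range.

The module also hosts the in-silico versions of the dosing-parameter
determination protocols: the IV insulin-sensitivity test (glucose drop per
1 U intravenous insulin at steady basal) and overnight basal titration
(adjust the rate until the 6-h nocturnal glucose change is within
30 mg/dl).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .insulin import InsulinActionCurve, PIG_CURVE

__all__ = [
    "PigParams",
    "MealEvent",
    "SensorModel",
    "SimEvent",
    "SimTrace",
    "PigSimulator",
    "REFERENCE_PIGS",
    "CARB_PROFILES",
    "carb_sensitivity",
    "triangular_kernel",
    "sample_cgm",
    "iv_isf_test",
    "titrate_basal",
    "TitrationError",
]


@dataclasses.dataclass(frozen=True)
class PigParams:
    """One virtual pig's individually determined dosing parameters."""

    id: str
    basal_rate: float  # U/h
    isf: float  # mg/dl per U
    icr: float  # g carbohydrate per U

    def __post_init__(self) -> None:
        if not 0.0 < self.basal_rate <= 5.0:
            raise ValueError(f"basal_rate must be in (0, 5] U/h, got {self.basal_rate}")
        if self.isf <= 0:
            raise ValueError(f"isf must be > 0, got {self.isf}")
        if self.icr <= 0:
            raise ValueError(f"icr must be > 0, got {self.icr}")


#: The six reference virtual pigs (basal U/h, ISF mg/dl/U, ICR g/U), spanning
#: basal rates 0.10-0.30 U/h and ISF 110-167 mg/dl/U.
REFERENCE_PIGS: tuple[PigParams, ...] = (
    PigParams("1", 0.15, 110.0, 49.0),
    PigParams("2", 0.20, 167.0, 90.0),
    PigParams("3", 0.10, 154.0, 68.0),
    PigParams("4", 0.30, 158.0, 59.0),
    PigParams("5", 0.20, 160.0, 69.0),
    PigParams("6", 0.25, 132.0, 58.0),
)


def carb_sensitivity(pig: PigParams) -> float:
    """Glucose rise per gram of carbohydrate, mg/dl/g (CSF = ISF / ICR)."""
    return pig.isf / pig.icr


@dataclasses.dataclass(frozen=True)
class MealEvent:
    """A carbohydrate intake at a clock minute, with an absorption profile."""

    time: float  # minutes from simulation start
    grams: float
    profile: str = "fast"  # "fast" (simple sugars) or "mixed" (chow)

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValueError(f"grams must be >= 0, got {self.grams}")
        if self.profile not in CARB_PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclasses.dataclass(frozen=True)
class SensorModel:
    """CGM sampling model: additive Gaussian noise, bias, reporting range.

    Defaults emulate a slightly under-reading interstitial sensor:
    5 mg/dl noise SD, -3 mg/dl bias, 40-400 mg/dl reporting range.
    """

    interval: int = 5  # minutes between readings
    noise_sd: float = 5.0  # mg/dl
    bias: float = -3.0  # mg/dl
    floor: float = 40.0  # mg/dl
    ceiling: float = 400.0  # mg/dl

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.floor < self.ceiling:
            raise ValueError("floor must be < ceiling")


#: Triangular carbohydrate absorption-rate profiles: (peak min, end min).
#: "fast" emulates sugared applesauce, "mixed" standard pig chow.
CARB_PROFILES: dict[str, tuple[float, float]] = {
    "fast": (30.0, 120.0),
    "mixed": (90.0, 240.0),
}

# Intravenous insulin: triangular activity, peak 15 min, complete by 90 min
# (glucose stabilizes ~90 min after an IV bolus).
IV_PEAK_MIN = 15.0
IV_END_MIN = 90.0

#: Hard simulator floor keeping the glucose state physical, mg/dl.
GLUCOSE_FLOOR = 20.0


def triangular_kernel(peak: float, end: float, step: float = 1.0) -> np.ndarray:
    """Discrete triangular rate profile over [0, end], normalized to sum 1."""
    if not 0.0 < peak < end:
        raise ValueError("require 0 < peak < end")
    mid = np.arange(step / 2.0, end, step)
    rate = np.where(mid < peak, mid / peak, (end - mid) / (end - peak))
    rate = np.clip(rate, 0.0, None)
    return rate / rate.sum()


def sample_cgm(glucose: float, sensor: SensorModel, rng: np.random.Generator) -> float:
    """One CGM reading: glucose + bias + Gaussian noise, clamped to range."""
    if glucose <= 0:
        raise ValueError(f"glucose must be > 0, got {glucose}")
    noise = rng.normal(0.0, sensor.noise_sd) if sensor.noise_sd > 0 else 0.0
    return float(np.clip(glucose + sensor.bias + noise, sensor.floor, sensor.ceiling))


@dataclasses.dataclass(frozen=True)
class SimEvent:
    """One logged simulation event (doses, meals, rescues, clamps)."""

    time: float  # minutes from simulation start
    kind: str  # basal | temp_basal | bolus | smb | iv_bolus | meal | rescue | clamp
    amount: float
    unit: str
    note: str = ""


@dataclasses.dataclass
class SimTrace:
    """Completed simulation output.

    ``true_glucose[k]`` is the ground-truth glucose at minute ``k``
    (``k = 0`` is the initial state); CGM timestamps are a subset of those
    minutes.  ``delivered[k]`` is subcutaneous insulin (U) delivered during
    minute ``k``.
    """

    true_minutes: np.ndarray
    true_glucose: np.ndarray
    cgm_times: np.ndarray
    cgm_values: np.ndarray
    delivered: np.ndarray
    events: list[SimEvent]


class PigSimulator:
    """Minute-step glucose simulator for one virtual pig.

    The simulator is initialized at steady state: the subcutaneous dose
    history is pre-seeded with ``history_rate`` (default: the pig's basal
    rate) over one full action-curve duration, so that minute 0 already
    sees the steady-state insulin activity.
    """

    def __init__(
        self,
        pig: PigParams,
        curve: InsulinActionCurve | None = None,
        sensor: SensorModel | None = None,
        duration_min: int = 1440,
        start_glucose: float = 120.0,
        rng: np.random.Generator | None = None,
        history_rate: float | None = None,
    ) -> None:
        self.pig = pig
        self.curve = curve if curve is not None else PIG_CURVE
        self.sensor = sensor if sensor is not None else SensorModel()
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._sc_kernel = self.curve.delivery_kernel(1.0)
        self._iv_kernel = triangular_kernel(IV_PEAK_MIN, IV_END_MIN)
        self._carb_kernels = {
            name: triangular_kernel(peak, end)
            for name, (peak, end) in CARB_PROFILES.items()
        }
        self._pad = len(self._sc_kernel)
        margin = max(len(k) for k in self._carb_kernels.values()) + len(self._iv_kernel)
        self._n = self._pad + int(duration_min) + margin + 1
        # Per-minute glucose increments scheduled by past deliveries/meals.
        self._delta = np.zeros(self._n)
        self.delivered = np.zeros(self._n)
        self.true_glucose = np.full(self._n, np.nan)
        self.events: list[SimEvent] = []
        self.cgm_times: list[float] = []
        self.cgm_values: list[float] = []
        self._temp_rate: float | None = None
        self._temp_until = -1

        self._t = self._pad  # absolute array index of the current minute
        self.glucose = float(start_glucose)
        self.true_glucose[self._t] = self.glucose
        self.egp_per_min = pig.isf * pig.basal_rate / 60.0

        hist = pig.basal_rate if history_rate is None else history_rate
        for m in range(self._pad):
            self._deliver_sc(hist / 60.0, m)

    # -- clock -----------------------------------------------------------

    @property
    def minute(self) -> int:
        """Minutes elapsed since simulation start."""
        return self._t - self._pad

    # -- dosing and meals ------------------------------------------------

    def _deliver_sc(self, units: float, idx: int) -> None:
        k = self._sc_kernel
        end = min(idx + len(k), self._n)
        self._delta[idx:end] -= self.pig.isf * units * k[: end - idx]
        self.delivered[idx] += units

    def bolus(self, units: float, kind: str = "bolus") -> None:
        """Deliver a subcutaneous bolus at the current minute."""
        if units < 0:
            raise ValueError("bolus units must be >= 0")
        if units > 0:
            self._deliver_sc(units, self._t)
        self.events.append(SimEvent(self.minute, kind, units, "U"))

    def iv_bolus(self, units: float) -> None:
        """Deliver an intravenous bolus at the current minute."""
        if units < 0:
            raise ValueError("iv bolus units must be >= 0")
        k = self._iv_kernel
        idx = self._t
        end = min(idx + len(k), self._n)
        self._delta[idx:end] -= self.pig.isf * units * k[: end - idx]
        self.events.append(SimEvent(self.minute, "iv_bolus", units, "U"))

    def meal(self, grams: float, profile: str = "fast", kind: str = "meal") -> None:
        """Ingest carbohydrate at the current minute."""
        ev = MealEvent(self.minute, grams, profile)  # validates
        k = self._carb_kernels[profile]
        idx = self._t
        end = min(idx + len(k), self._n)
        csf = carb_sensitivity(self.pig)
        self._delta[idx:end] += csf * grams * k[: end - idx]
        self.events.append(SimEvent(ev.time, kind, grams, "g", note=profile))

    def set_temp_basal(self, rate: float, duration_min: int) -> None:
        """Override the scheduled basal with ``rate`` U/h for ``duration_min``."""
        if rate < 0:
            raise ValueError("temp basal rate must be >= 0")
        self._temp_rate = rate
        self._temp_until = self._t + int(duration_min)
        self.events.append(
            SimEvent(self.minute, "temp_basal", rate, "U/h", note=f"{duration_min}min")
        )

    def current_rate(self) -> float:
        """Basal rate (U/h) in effect for the current minute."""
        if self._temp_rate is not None and self._t < self._temp_until:
            return self._temp_rate
        return self.pig.basal_rate

    # -- stepping --------------------------------------------------------

    def step(self) -> None:
        """Advance one minute: deliver basal, apply scheduled deltas."""
        idx = self._t
        if idx + 1 >= self._n:
            raise RuntimeError("simulation exceeded configured duration")
        self._deliver_sc(self.current_rate() / 60.0, idx)
        g = self.glucose + self._delta[idx] + self.egp_per_min
        if g < GLUCOSE_FLOOR:
            g = GLUCOSE_FLOOR
            self.events.append(SimEvent(self.minute, "clamp", g, "mg/dl"))
        self._t = idx + 1
        self.glucose = g
        self.true_glucose[self._t] = g

    def run(self, minutes: int) -> None:
        for _ in range(int(minutes)):
            self.step()

    def delivered_at(self, minute: int) -> float:
        """Subcutaneous insulin (U) delivered during a completed minute."""
        return float(self.delivered[self._pad + int(minute)])

    def read_cgm(self) -> float:
        """Sample and log one CGM reading at the current minute."""
        v = sample_cgm(self.glucose, self.sensor, self.rng)
        self.cgm_times.append(float(self.minute))
        self.cgm_values.append(v)
        return v

    # -- output ----------------------------------------------------------

    def trace(self) -> SimTrace:
        sl = slice(self._pad, self._t + 1)
        return SimTrace(
            true_minutes=np.arange(self._t + 1 - self._pad, dtype=float),
            true_glucose=self.true_glucose[sl].copy(),
            cgm_times=np.asarray(self.cgm_times, dtype=float),
            cgm_values=np.asarray(self.cgm_values, dtype=float),
            delivered=self.delivered[self._pad:self._t + 1].copy(),
            events=list(self.events),
        )


class TitrationError(RuntimeError):
    """Basal titration failed to converge within the iteration cap."""


_NOISELESS = SensorModel(noise_sd=0.0, bias=0.0)


def iv_isf_test(pig: PigParams, dose: float = 1.0, stabilize_min: int = 120) -> float:
    """In-silico IV insulin-sensitivity test.

    At fasted steady state under the configured basal infusion, deliver
    ``dose`` units intravenously, wait for glucose to stabilize (the IV
    effect completes within ~90 min) and return the drop per unit with
    noise-free sensing.
    """
    if dose == 0:
        return 0.0
    # Start well above range so the measured drop never hits the simulator
    # floor (the largest reference ISF drops glucose by 167 mg/dl per unit).
    sim = PigSimulator(pig, sensor=_NOISELESS, duration_min=stabilize_min + 10,
                       start_glucose=250.0)
    g0 = sim.glucose
    sim.iv_bolus(dose)
    sim.run(stabilize_min)
    return (g0 - sim.glucose) / dose


def titrate_basal(
    pig: PigParams,
    start_rate: float = 0.15,
    step: float = 0.05,
    window_min: int = 360,
    tolerance_mgdl: float = 30.0,
    max_iter: int = 50,
) -> float:
    """In-silico overnight basal titration.

    Simulates a nocturnal window at each candidate rate (with the pig
    equilibrated on that rate) and steps the rate toward smaller overnight
    drift -- up when glucose rises, down when it falls -- for as long as the
    drift keeps shrinking.  A perfectly stable night returns immediately;
    otherwise the best candidate is returned once no neighbouring rate
    improves on it, provided its drift is within ``tolerance_mgdl``.
    """
    if start_rate <= 0:
        raise ValueError("start_rate must be > 0")

    def overnight_drift(rate: float) -> float:
        sim = PigSimulator(pig, sensor=_NOISELESS, duration_min=window_min + 5,
                           history_rate=rate)
        sim.set_temp_basal(rate, window_min + 5)
        g0 = sim.glucose
        sim.run(window_min)
        return sim.glucose - g0

    rate = round(float(start_rate), 6)
    dg = overnight_drift(rate)
    if abs(dg) < 1e-9:  # already stable
        return rate
    seen = {rate}
    for _ in range(max_iter):
        nxt = round(rate + (step if dg > 0 else -step), 6)
        if nxt <= 0 or nxt in seen:
            break
        dg_next = overnight_drift(nxt)
        if abs(dg_next) < abs(dg) + 1e-9:  # equal-or-better: keep moving
            rate, dg = nxt, dg_next
            seen.add(rate)
            if abs(dg) < 1e-9:
                return rate
        else:
            break
    if abs(dg) <= tolerance_mgdl:
        return rate
    raise TitrationError(
        f"titration for pig {pig.id} stalled at {rate} U/h "
        f"(overnight drift {dg:+.1f} mg/dl exceeds {tolerance_mgdl})"
    )
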