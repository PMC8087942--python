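"""The full closed-loop meal challenge: schedule, rescue rule, metrics.

Each simulated pig-day starts at 01:00 at steady state and serves three
unannounced meals: a fast-absorbing 66-g carbohydrate breakfast at 07:30
and two 132-g mixed meals (chow) at 13:30 and 19:00.  Glycemic outcomes
are scored over four monitoring windows per day -- the 6 h after
breakfast, the 5 h after lunch and dinner, and the 01:00-07:00 overnight
window *following* that day's dinner (so overnight control reflects
post-dinner carryover; the simulation therefore runs ``days * 1440 + 360``
minutes and the initial steady-state night is unscored).

Corrective carbohydrates (10 g fast sugar) are given when two glucose
measurements agree below 55 mg/dl or the CGM alone reads below 40 mg/dl;
any window containing a rescue is flagged as a severe hypoglycemic event.
Windows whose CGM record has a gap longer than 1 h are excluded.

Metrics per window: time-in-range 70-180 mg/dl and time-below-70 as the
percentage of 5-min readings, insulin delivered (U), severe-event flag.
Aggregation is mean +/- SE across pigs, each pig first averaged over its
days.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .insulin import InsulinActionCurve, LOOP_CURVE, PIG_CURVE
from .loopctl import LoopConfig, LoopController
from .oref1 import Oref1Config, Oref1Controller
from .pig import (
    PigParams,
    PigSimulator,
    REFERENCE_PIGS,
    SensorModel,
    SimTrace,
)

__all__ = [
    "ChallengeSchedule",
    "ChallengeResult",
    "time_in_range",
    "time_below",
    "time_above",
    "rescue_check",
    "run_challenge",
    "run_pig_day",
    "aggregate",
    "DAY_MINUTES",
]

DAY_MINUTES = 1440
#: Minutes from the 01:00 day start.
_BREAKFAST = 390  # 07:30
_LUNCH = 750  # 13:30
_DINNER = 1080  # 19:00


@dataclasses.dataclass(frozen=True)
class ChallengeSchedule:
    """Daily meal times/sizes and scoring windows (minutes from 01:00)."""

    breakfast_min: int = _BREAKFAST
    lunch_min: int = _LUNCH
    dinner_min: int = _DINNER
    breakfast_grams: float = 66.0
    lunch_grams: float = 132.0
    dinner_grams: float = 132.0
    breakfast_window_h: float = 6.0
    lunch_window_h: float = 5.0
    dinner_window_h: float = 5.0
    overnight_window_h: float = 6.0

    def meals(self) -> list[tuple[int, float, str]]:
        return [
            (self.breakfast_min, self.breakfast_grams, "fast"),
            (self.lunch_min, self.lunch_grams, "mixed"),
            (self.dinner_min, self.dinner_grams, "mixed"),
        ]

    def windows(self) -> dict[str, tuple[int, int]]:
        """Scoring windows for one day, minutes from that day's 01:00.

        The overnight window is the 01:00-07:00 interval after dinner,
        i.e. it starts at the following day boundary.
        """
        w = {
            "breakfast": (self.breakfast_min,
                          self.breakfast_min + int(60 * self.breakfast_window_h)),
            "lunch": (self.lunch_min, self.lunch_min + int(60 * self.lunch_window_h)),
            "dinner": (self.dinner_min,
                       self.dinner_min + int(60 * self.dinner_window_h)),
            "overnight": (DAY_MINUTES, DAY_MINUTES + int(60 * self.overnight_window_h)),
        }
        spans = sorted(w.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("monitoring windows overlap")
        return w


def time_in_range(readings, lo: float = 70.0, hi: float = 180.0) -> float:
    """% of readings with lo <= glucose <= hi (bounds inclusive)."""
    v = np.asarray(readings, dtype=float)
    if v.size == 0:
        raise ValueError("time_in_range is undefined for an empty window")
    return 100.0 * float(np.mean((v >= lo) & (v <= hi)))


def time_below(readings, thresh: float = 70.0) -> float:
    """% of readings strictly below ``thresh``."""
    v = np.asarray(readings, dtype=float)
    if v.size == 0:
        raise ValueError("time_below is undefined for an empty window")
    return 100.0 * float(np.mean(v < thresh))


def time_above(readings, thresh: float = 180.0) -> float:
    """% of readings strictly above ``thresh``."""
    v = np.asarray(readings, dtype=float)
    if v.size == 0:
        raise ValueError("time_above is undefined for an empty window")
    return 100.0 * float(np.mean(v > thresh))


def rescue_check(cgm: float, second_measure: float | None = None) -> bool:
    """Corrective-carbohydrate rule.

    Rescue iff two measurements are both below 55 mg/dl, or the CGM alone
    is below 40 mg/dl.  A CGM alone just under 55 does not qualify.
    """
    if cgm < 40.0:
        return True
    return second_measure is not None and cgm < 55.0 and second_measure < 55.0


@dataclasses.dataclass
class ChallengeResult:
    windows: pd.DataFrame  # one row per pig x day x window
    aggregate: pd.DataFrame  # mean +/- SE per (algorithm, meal)
    traces: dict[str, SimTrace]


_MAX_CGM_GAP_MIN = 60.0
_RESCUE_GRAMS = 10.0
_RESCUE_COOLDOWN_MIN = 30


def _make_controller(name: str, pig: PigParams, config):
    if name == "oref1":
        return Oref1Controller(pig, curve=PIG_CURVE,
                               config=config if config is not None else Oref1Config())
    if name == "loop":
        return LoopController(pig, curve=LOOP_CURVE,
                              config=config if config is not None else LoopConfig())
    raise ValueError(f"unknown controller {name!r}; expected 'oref1' or 'loop'")


def run_pig_day(
    pig: PigParams,
    controller: str,
    days: int,
    rng: np.random.Generator,
    controller_config=None,
    sensor: SensorModel | None = None,
    schedule: ChallengeSchedule | None = None,
) -> SimTrace:
    """Simulate one pig continuously over ``days`` days plus the final night.

    The control cycle runs on each new 5-min CGM reading; the rescue rule
    is checked at the same cadence, with the true glucose standing in for
    the confirmatory second measurement (ear prick) and a 30-min carb
    cooldown after each rescue.
    """
    sched = schedule if schedule is not None else ChallengeSchedule()
    total = days * DAY_MINUTES + int(60 * sched.overnight_window_h)
    sim = PigSimulator(pig, curve=PIG_CURVE, sensor=sensor, duration_min=total,
                       rng=rng)
    ctl = _make_controller(controller, pig, controller_config)
    times: list[float] = []
    readings: list[float] = []
    rescue_ok_after = -1
    for m in range(total):
        day_min = m % DAY_MINUTES
        if m < days * DAY_MINUTES:
            for meal_min, grams, profile in sched.meals():
                if day_min == meal_min:
                    sim.meal(grams, profile)
        if m % 5 == 0:
            reading = sim.read_cgm()
            times.append(float(m))
            readings.append(reading)
            if m >= rescue_ok_after and rescue_check(
                reading, second_measure=sim.glucose if reading < 55.0 else None
            ):
                sim.meal(_RESCUE_GRAMS, "fast", kind="rescue")
                rescue_ok_after = m + _RESCUE_COOLDOWN_MIN
            cmd = ctl.decide(float(m), times, readings)
            smb = getattr(cmd, "smb", 0.0)
            if smb > 0:
                sim.bolus(smb, kind="smb")
            sim.set_temp_basal(cmd.temp_basal, cmd.duration)
        sim.step()
        ctl.notify_delivery(float(m), sim.delivered_at(m))
    return sim.trace()


def _window_rows(pig: PigParams, algorithm: str, trace: SimTrace, days: int,
                 sched: ChallengeSchedule) -> list[dict]:
    rows = []
    rescue_times = np.array(
        [ev.time for ev in trace.events if ev.kind == "rescue"], dtype=float
    )
    for day in range(days):
        base = day * DAY_MINUTES
        for label, (start, end) in sched.windows().items():
            s, e = base + start, base + end
            sel = (trace.cgm_times >= s) & (trace.cgm_times < e)
            t_in = trace.cgm_times[sel]
            if t_in.size == 0:
                continue
            edges = np.concatenate([[s], t_in, [e]])
            if np.max(np.diff(edges)) > _MAX_CGM_GAP_MIN:
                continue  # sensor outage longer than 1 h: window excluded
            vals = trace.cgm_values[sel]
            minutes = (trace.true_minutes >= s) & (trace.true_minutes < e)
            rows.append({
                "pig": pig.id,
                "day": day + 1,
                "meal": label,
                "algorithm": algorithm,
                "tir": time_in_range(vals),
                "below70": time_below(vals),
                "above180": time_above(vals),
                "severe": bool(np.any((rescue_times >= s) & (rescue_times < e))),
                "insulin_u": float(trace.delivered[minutes].sum()),
                "n_intervals": int(vals.size),
            })
    return rows


def aggregate(windows: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE per (algorithm, meal); pigs averaged over days first."""
    if windows.empty:
        return pd.DataFrame(
            columns=["algorithm", "meal", "tir_mean", "tir_se",
                     "below70_mean", "below70_se", "insulin_mean", "insulin_se",
                     "n_pigs"]
        )
    per_pig = (
        windows.groupby(["algorithm", "meal", "pig"], as_index=False)
        [["tir", "below70", "insulin_u"]].mean()
    )
    out = []
    for (alg, meal), grp in per_pig.groupby(["algorithm", "meal"]):
        n = len(grp)
        rec = {"algorithm": alg, "meal": meal, "n_pigs": n}
        for col, name in (("tir", "tir"), ("below70", "below70"),
                          ("insulin_u", "insulin")):
            rec[f"{name}_mean"] = float(grp[col].mean())
            rec[f"{name}_se"] = (
                float(grp[col].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        out.append(rec)
    return pd.DataFrame(out).sort_values(["algorithm", "meal"]).reset_index(drop=True)


def run_challenge(
    pigs=None,
    controller: str = "oref1",
    days: int = 3,
    seed: int = 0,
    controller_config=None,
    sensor: SensorModel | None = None,
    schedule: ChallengeSchedule | None = None,
) -> ChallengeResult:
    """Run the meal challenge for a herd of pigs under one controller.

    Seeds are derived per pig from ``seed`` via ``numpy``'s SeedSequence
    spawning, so the same configuration and seed reproduce the result
    bit-for-bit.
    """
    herd = tuple(pigs) if pigs is not None else REFERENCE_PIGS
    sched = schedule if schedule is not None else ChallengeSchedule()
    rows: list[dict] = []
    traces: dict[str, SimTrace] = {}
    for i, pig in enumerate(herd):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        trace = run_pig_day(pig, controller, days, rng,
                            controller_config=controller_config,
                            sensor=sensor, schedule=sched)
        traces[pig.id] = trace
        rows.extend(_window_rows(pig, controller, trace, days, sched))
    windows = pd.DataFrame(rows)
    return ChallengeResult(windows=windows, aggregate=aggregate(windows),
                           traces=traces)
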