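"""Timed external inputs and clinical endpoints.

A protocol collects everything that happens *to* the virtual patient over the
simulated horizon: the daily meal schedule, drug regimens (dose, qd/bid,
duration), and oral-glucose-tolerance tests; plus the output specification.

Conventions (fixed here, used consistently by calibration and prediction):

* day 0 is the first dosing day; time t = 0 h is midnight starting day 0;
* run-in days (meals only, no drug) occupy negative time;
* fasting endpoints (FPG, FPI) are read at the morning sampling time, before
  any dose or meal of that day;
* on OGTT mornings the glucose load replaces breakfast: meals within the
  post-load suspension window are pushed to its end, and the morning dose is
  taken after the AUC window, so the test itself runs at trough drug
  concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError, ValidationError

QD = "qd"
BID = "bid"

#: default output variables every simulation records
DEFAULT_OUTPUTS = (
    "G_plasma", "I_plasma", "Cpep", "FFA_plasma", "TAG_plasma",
    "Gn_1", "GLP1", "GIP", "Gly_liver",
)


@dataclass(frozen=True)
class Meal:
    """One daily meal: clock time (h), caloric content, macronutrient split."""

    time: float          # clock time of day, h in [0, 24)
    kcal: float
    carb_frac: float
    fat_frac: float
    protein_frac: float

    def __post_init__(self):
        if not 0.0 <= self.time < 24.0:
            raise ValidationError(f"meal time must be in [0, 24), got {self.time}")
        if self.kcal < 0.0:
            raise ValidationError("meal kcal must be non-negative")
        fr = (self.carb_frac, self.fat_frac, self.protein_frac)
        if any(f < 0.0 for f in fr):
            raise ValidationError("macronutrient fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(
                f"macronutrient fractions must sum to 1, got {sum(fr)!r}")

    def grams(self) -> tuple[float, float, float]:
        """(carb, fat, protein) in grams, via standard energy densities."""
        return (self.kcal * self.carb_frac / 4.0,
                self.kcal * self.fat_frac / 9.0,
                self.kcal * self.protein_frac / 4.0)


@dataclass(frozen=True)
class RegimenSegment:
    dose_mg: float
    schedule: str  # qd | bid
    n_days: int

    def __post_init__(self):
        if self.dose_mg < 0.0:
            raise ValidationError("dose must be non-negative")
        if self.schedule not in (QD, BID):
            raise ValidationError(f"unknown schedule token {self.schedule!r}")
        if self.n_days < 1:
            raise ValidationError("segment must span at least one day")


@dataclass(frozen=True)
class Regimen:
    """Contiguous dosing segments for one drug, e.g. the classic escalation
    500 mg qd x 7 d, 500 mg bid x 7 d, 1000 mg bid x 14 d."""

    drug: str
    segments: tuple[RegimenSegment, ...]
    morning_time: float = 9.0   # clock h; evening dose is 12 h later for bid

    @property
    def n_days(self) -> int:
        return sum(s.n_days for s in self.segments)


@dataclass(frozen=True)
class DoseEvent:
    t: float        # absolute time, h
    drug: str
    dose_mg: float


@dataclass(frozen=True)
class OgttEvent:
    """An oral glucose load, flagged so endpoints know the test window."""

    glucose_g: float
    day: int
    clock_time: float = 7.0

    def __post_init__(self):
        if self.glucose_g <= 0.0:
            raise ValidationError("OGTT glucose load must be positive")
        if not 0.0 <= self.clock_time < 24.0:
            raise ValidationError("OGTT clock time must be in [0, 24)")

    @property
    def t(self) -> float:
        return 24.0 * self.day + self.clock_time


def build_regimen(segments, drug: str = "metformin",
                  morning_time: float = 9.0) -> list[DoseEvent]:
    """Expand dosing segments into timed dose events.

    ``segments`` is an iterable of ``(dose_mg, schedule, n_days)`` tuples or
    :class:`RegimenSegment`.  qd doses fall at the morning clock time; bid
    adds a second dose 12 h later.  Segments are contiguous starting day 0.
    """
    segs = [s if isinstance(s, RegimenSegment) else RegimenSegment(*s)
            for s in segments]
    events: list[DoseEvent] = []
    day = 0
    for seg in segs:
        for d in range(day, day + seg.n_days):
            t0 = 24.0 * d + morning_time
            events.append(DoseEvent(t0, drug, seg.dose_mg))
            if seg.schedule == BID:
                events.append(DoseEvent(t0 + 12.0, drug, seg.dose_mg))
        day += seg.n_days
    events.sort(key=lambda e: (e.t, e.drug))
    return events


def build_ogtt(glucose_g: float, day: int, clock_time: float = 7.0,
               duration_days: int | None = None) -> OgttEvent:
    """A flagged oral glucose bolus on the given protocol day."""
    ev = OgttEvent(glucose_g, day, clock_time)
    if duration_days is not None and not (0 <= day <= duration_days):
        raise ValidationError(
            f"OGTT day {day} outside protocol duration {duration_days} d")
    return ev


@dataclass
class Protocol:
    """Complete description of one simulated study arm."""

    duration_days: int
    meals: tuple[Meal, ...] = ()
    regimens: tuple[Regimen, ...] = ()
    ogtts: tuple[OgttEvent, ...] = ()
    outputs: tuple[str, ...] = DEFAULT_OUTPUTS
    output_interval: float = 0.1          # h
    run_in_days: int = 4                  # meal-only days before day 0
    ogtt_auc_window: float = 3.0          # h after the load
    ogtt_meal_suspension: float = 3.0     # h meals are deferred post-load
    sampling_clock_time: float = 7.0      # fasting FPG/FPI sampling, clock h

    def __post_init__(self):
        if self.duration_days < 1:
            raise ValidationError("protocol duration must be at least one day")
        if len(self.meals) > 3:
            raise ValidationError("at most three meals per day")
        if self.output_interval <= 0.0:
            raise ValidationError("output interval must be positive")
        for r in self.regimens:
            if r.n_days > self.duration_days:
                raise ValidationError(
                    f"regimen for {r.drug!r} spans {r.n_days} d, protocol only "
                    f"{self.duration_days} d")
        for o in self.ogtts:
            if not 0 <= o.day <= self.duration_days:
                raise ValidationError(
                    f"OGTT on day {o.day} outside protocol duration")

    # -- timeline ------------------------------------------------------------
    @property
    def t_start(self) -> float:
        return -24.0 * self.run_in_days

    @property
    def t_end(self) -> float:
        return 24.0 * self.duration_days

    def dose_events(self) -> list[DoseEvent]:
        events: list[DoseEvent] = []
        for r in self.regimens:
            events.extend(build_regimen(r.segments, r.drug, r.morning_time))
        events.sort(key=lambda e: (e.t, e.drug))
        return events

    def ogtt_on_day(self, day: int) -> OgttEvent | None:
        for o in self.ogtts:
            if o.day == day:
                return o
        return None

    def meal_events(self) -> list[tuple[float, Meal]]:
        """(absolute time, meal) for every day, with OGTT-morning deferral."""
        out: list[tuple[float, Meal]] = []
        for day in range(-self.run_in_days, self.duration_days):
            ogtt = self.ogtt_on_day(day)
            for m in self.meals:
                t = 24.0 * day + m.time
                if ogtt is not None:
                    t_load = ogtt.t
                    if t_load <= t < t_load + self.ogtt_meal_suspension:
                        t = t_load + self.ogtt_meal_suspension
                out.append((t, m))
        out.sort(key=lambda x: x[0])
        return out


@dataclass
class Endpoints:
    """Clinical endpoints for one measurement day of a protocol."""

    day: int
    FPG: float                      # fasting plasma glucose, mM
    FPI: float                      # fasting plasma insulin, pM
    FPI_pct_change: float | None = None   # vs the reference day
    AUC_glucose: float | None = None      # OGTT window total AUC, mM*h
    G_2h_post_ogtt: float | None = None   # mM

    def __post_init__(self):
        if self.FPG <= 0.0:
            raise DomainError("FPG must be positive")
        if self.AUC_glucose is not None and self.AUC_glucose < 0.0:
            raise DomainError("AUC must be non-negative")


def auc_trapezoid(times: np.ndarray, values: np.ndarray,
                  window: tuple[float, float]) -> float:
    """Trapezoid AUC over ``window`` with linear interpolation at the edges."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    a, b = window
    if b <= a:
        raise DomainError(f"empty AUC window ({a}, {b})")
    if a < times[0] - 1e-9 or b > times[-1] + 1e-9:
        raise DomainError(
            f"AUC window ({a}, {b}) wider than data range "
            f"({times[0]}, {times[-1]})")
    mask = (times > a) & (times < b)
    ts = np.concatenate(([a], times[mask], [b]))
    vs = np.concatenate(([np.interp(a, times, values)],
                         values[mask],
                         [np.interp(b, times, values)]))
    return float(np.trapezoid(vs, ts))


def compute_endpoints(result, protocol: Protocol, day: int,
                      reference_day: int | None = 0) -> Endpoints:
    """Endpoints for one measurement day of a simulated protocol.

    FPG and FPI are read at the morning sampling time of ``day`` (pre-dose,
    pre-meal by the protocol's construction).  If an OGTT is flagged on that
    day, the total glucose AUC over the protocol's window and the 2-h
    post-load glucose are computed; requesting them on a day without a
    flagged OGTT is an error.
    """
    for var in ("G_plasma", "I_plasma"):
        if var not in result:
            raise DomainError(f"required output variable {var!r} missing from result")
    t_sample = 24.0 * day + protocol.sampling_clock_time
    fpg = result.interp("G_plasma", t_sample)
    fpi = result.interp("I_plasma", t_sample)

    pct = None
    if reference_day is not None:
        t_ref = 24.0 * reference_day + protocol.sampling_clock_time
        fpi_ref = result.interp("I_plasma", t_ref)
        pct = 100.0 * (fpi - fpi_ref) / fpi_ref

    auc = g2h = None
    ogtt = protocol.ogtt_on_day(day)
    if ogtt is not None:
        t0 = ogtt.t
        auc = auc_trapezoid(result.times, result["G_plasma"],
                            (t0, t0 + protocol.ogtt_auc_window))
        g2h = result.interp("G_plasma", t0 + 2.0)
    return Endpoints(day=day, FPG=fpg, FPI=fpi, FPI_pct_change=pct,
                     AUC_glucose=auc, G_2h_post_ogtt=g2h)


def require_ogtt_auc(endpoints: Endpoints) -> float:
    """AUC accessor that raises when the day carried no flagged OGTT."""
    if endpoints.AUC_glucose is None:
        raise DomainError(
            f"day {endpoints.day} has no flagged OGTT; AUC is undefined")
    return endpoints.AUC_glucose


# -- standard building blocks -------------------------------------------------

def standard_meals(kcal: tuple[float, float, float] = (600.0, 700.0, 800.0),
                   times: tuple[float, float, float] = (8.0, 13.0, 19.0),
                   fracs: tuple[float, float, float] = (0.45, 0.35, 0.20),
                   ) -> tuple[Meal, ...]:
    """Three mixed meals per day (carb/fat/protein energy fractions)."""
    return tuple(Meal(t, k, *fracs) for t, k in zip(times, kcal))


def metformin_escalation_protocol(
    duration_days: int = 29,
    ogtt_days: tuple[int, ...] = (0, 7, 14, 28),
    ogtt_glucose_g: float = 75.0,
    auc_window: float = 2.0,
) -> Protocol:
    """The 28-day escalating metformin study arm: 500 mg qd x 7 d,
    500 mg bid x 7 d, 1000 mg bid x 14 d, with OGTTs at the start of each
    dose level and after the final week.

    The 2-h total-AUC window is the convention fixed at day-0 calibration and
    reused for every later test of the same arm.
    """
    reg = Regimen("metformin", (
        RegimenSegment(500.0, QD, 7),
        RegimenSegment(500.0, BID, 7),
        RegimenSegment(1000.0, BID, 14),
    ))
    ogtts = tuple(build_ogtt(ogtt_glucose_g, d, 7.0, duration_days)
                  for d in ogtt_days)
    return Protocol(
        duration_days=duration_days,
        meals=standard_meals(),
        regimens=(reg,),
        ogtts=ogtts,
        ogtt_auc_window=auc_window,
    )


def monotherapy_protocol(drug: str, dose_mg: float, n_days: int = 14,
                         schedule: str = QD,
                         ogtt_days: tuple[int, ...] = (0, 14),
                         ogtt_glucose_g: float = 75.0,
                         auc_window: float = 2.0,
                         duration_days: int | None = None) -> Protocol:
    """Fixed-dose arm with baseline and end-of-treatment OGTTs."""
    duration = duration_days if duration_days is not None else n_days + 1
    regimens = ()
    if dose_mg > 0.0:
        regimens = (Regimen(drug, (RegimenSegment(dose_mg, schedule, n_days),)),)
    ogtts = tuple(build_ogtt(ogtt_glucose_g, d, 7.0, duration)
                  for d in ogtt_days)
    return Protocol(duration_days=duration, meals=standard_meals(),
                    regimens=regimens, ogtts=ogtts, ogtt_auc_window=auc_window)


def combination_protocol(arms: dict[str, tuple[float, str]], n_days: int = 14,
                         ogtt_days: tuple[int, ...] = (0, 14),
                         ogtt_glucose_g: float = 75.0,
                         auc_window: float = 2.0) -> Protocol:
    """Several drugs dosed simultaneously: ``arms`` maps drug -> (dose, schedule)."""
    duration = n_days + 1
    regimens = tuple(
        Regimen(drug, (RegimenSegment(dose, sched, n_days),))
        for drug, (dose, sched) in sorted(arms.items()) if dose > 0.0
    )
    ogtts = tuple(build_ogtt(ogtt_glucose_g, d, 7.0, duration)
                  for d in ogtt_days)
    return Protocol(duration_days=duration, meals=standard_meals(),
                    regimens=regimens, ogtts=ogtts, ogtt_auc_window=auc_window)


# -- structured-text (de)serialization ----------------------------------------

def protocol_to_dict(p: Protocol) -> dict:
    """Plain-data encoding (YAML/JSON-safe, lossless floats)."""
    return {
        "duration_days": p.duration_days,
        "meals": [{"time": m.time, "kcal": m.kcal, "carb_frac": m.carb_frac,
                   "fat_frac": m.fat_frac, "protein_frac": m.protein_frac}
                  for m in p.meals],
        "regimens": [{"drug": r.drug, "morning_time": r.morning_time,
                      "segments": [{"dose_mg": s.dose_mg, "schedule": s.schedule,
                                    "n_days": s.n_days} for s in r.segments]}
                     for r in p.regimens],
        "ogtts": [{"glucose_g": o.glucose_g, "day": o.day,
                   "clock_time": o.clock_time} for o in p.ogtts],
        "outputs": list(p.outputs),
        "output_interval": p.output_interval,
        "run_in_days": p.run_in_days,
        "ogtt_auc_window": p.ogtt_auc_window,
        "ogtt_meal_suspension": p.ogtt_meal_suspension,
        "sampling_clock_time": p.sampling_clock_time,
    }


def protocol_from_dict(d: dict) -> Protocol:
    try:
        meals = tuple(Meal(**m) for m in d.get("meals", []))
        regimens = tuple(
            Regimen(r["drug"],
                    tuple(RegimenSegment(**s) for s in r["segments"]),
                    r.get("morning_time", 9.0))
            for r in d.get("regimens", []))
        ogtts = tuple(OgttEvent(**o) for o in d.get("ogtts", []))
        return Protocol(
            duration_days=d["duration_days"], meals=meals, regimens=regimens,
            ogtts=ogtts, outputs=tuple(d.get("outputs", DEFAULT_OUTPUTS)),
            output_interval=d.get("output_interval", 0.1),
            run_in_days=d.get("run_in_days", 4),
            ogtt_auc_window=d.get("ogtt_auc_window", 3.0),
            ogtt_meal_suspension=d.get("ogtt_meal_suspension", 3.0),
            sampling_clock_time=d.get("sampling_clock_time", 7.0),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed protocol definition: {exc}") from exc
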