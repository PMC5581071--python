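"""Dose accounting and phantom cross-calibration for ¹⁸F studies.

Implements the arithmetic that turns a syringe measurement into the
decay-corrected dose actually on board at scan time, and the phantom
conversion factor that maps scanner readings (kBq/ml) onto dose-per-gram
units (μCi/g).

Clock times are kept as integer hour/minute pairs.  Study logs commonly
write times in a decimal ``HH.MM`` encoding (10.05 = five past ten); parsing
goes through strings so that encoding is exact, with no float round-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "F18_HALF_LIFE_MIN",
    "DECAY_LOG2",
    "ClockTime",
    "DoseRecord",
    "ConversionFactor",
    "clock_to_minutes",
    "decay_factor",
    "injected_dose",
    "scan_dose",
    "conversion_factor",
]

#: ¹⁸F half-life in minutes, as used throughout the dose formulas.
F18_HALF_LIFE_MIN = 109.8

#: The ln 2 approximation used in the printed decay formulas.  Kept at the
#: three-digit 0.693 so the package reproduces the published arithmetic
#: digit-for-digit; pass ``exact_ln2=True`` to decay routines for ln 2.
DECAY_LOG2 = 0.693

MINUTES_PER_DAY = 24 * 60


@dataclass(frozen=True, order=True)
class ClockTime:
    """A time of day as integer hour and minute.

    Ordering and arithmetic operate on total minutes past midnight, so
    ``ClockTime(9, 30) < ClockTime(10, 5)`` behaves as expected.
    """

    hour: int
    minute: int

    def __post_init__(self) -> None:
        if not (isinstance(self.hour, int) and isinstance(self.minute, int)):
            raise TypeError("hour and minute must be integers")
        if self.hour < 0:
            raise ValueError(f"hour must be >= 0, got {self.hour}")
        if not 0 <= self.minute <= 59:
            raise ValueError(f"minute must be in 0..59, got {self.minute}")

    @classmethod
    def parse(cls, value: "str | float | ClockTime") -> "ClockTime":
        """Parse ``"HH.MM"``, ``"HH:MM"`` or a decimal-encoded float.

        Floats are formatted to two decimals first, so 10.05 parses to
        (10, 5) exactly despite binary float representation.
        """
        if isinstance(value, ClockTime):
            return value
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            if value < 0:
                raise ValueError("clock time must be non-negative")
            value = f"{value:.2f}"
        if not isinstance(value, str):
            raise TypeError(f"cannot parse clock time from {type(value).__name__}")
        text = value.strip().replace(":", ".")
        if "." not in text:
            text += ".00"
        hh, _, mm = text.partition(".")
        mm = (mm + "00")[:2]
        return cls(hour=int(hh), minute=int(mm))

    @property
    def total_minutes(self) -> int:
        return 60 * self.hour + self.minute

    def __str__(self) -> str:  # "09:05"
        return f"{self.hour:02d}:{self.minute:02d}"


def clock_to_minutes(t: "ClockTime | str | float") -> int:
    """Minutes past midnight for a clock time.

    Equivalent to the decimal-encoding identity
    ``100*(H - INT(H)) + 60*INT(H)`` evaluated exactly on integer fields.
    """
    return ClockTime.parse(t).total_minutes


def decay_factor(
    delta_minutes: float,
    *,
    half_life: float = F18_HALF_LIFE_MIN,
    exact_ln2: bool = False,
    wrap_midnight: bool = False,
) -> float:
    """Fraction of ¹⁸F activity remaining after ``delta_minutes``.

    Computes ``exp(-0.693 * dt / 109.8)`` by default.  Negative intervals
    are an error unless ``wrap_midnight`` is set, in which case 24 h is
    added (a count finished after midnight).
    """
    if delta_minutes < 0:
        if not wrap_midnight:
            raise ValueError(
                f"negative decay interval {delta_minutes} min; "
                "enable wrap_midnight if the interval crossed midnight"
            )
        delta_minutes += MINUTES_PER_DAY
    log2 = math.log(2.0) if exact_ln2 else DECAY_LOG2
    return math.exp(-log2 * delta_minutes / half_life)


@dataclass(frozen=True)
class DoseRecord:
    """Everything needed to decay-correct a dose for one animal.

    Attributes
    ----------
    initial_dose : float
        Syringe activity C (μCi) measured at ``initial_time``.
    residual_dose : float
        Activity F (μCi) left in the syringe after injection, measured at
        ``injection_time``.
    initial_time, injection_time, scan_time : ClockTime
        Assay, injection and scan-start clock times (same day, in order).
    weight : float
        Animal weight W in grams.
    """

    initial_dose: float
    residual_dose: float
    initial_time: ClockTime
    injection_time: ClockTime
    scan_time: ClockTime
    weight: float

    def __post_init__(self) -> None:
        for name in ("initial_time", "injection_time", "scan_time"):
            object.__setattr__(self, name, ClockTime.parse(getattr(self, name)))
        if not self.initial_time <= self.injection_time <= self.scan_time:
            raise ValueError(
                "times must satisfy initial <= injection <= scan "
                f"(got {self.initial_time}, {self.injection_time}, {self.scan_time})"
            )
        if not 0 <= self.residual_dose < self.initial_dose:
            raise ValueError("need 0 <= residual dose < initial dose")
        if self.weight <= 0:
            raise ValueError("animal weight must be positive")

    def injected_dose(self, **kw) -> float:
        return injected_dose(self, **kw)

    def scan_dose(self, **kw) -> float:
        return scan_dose(self.injected_dose(**kw), self.injection_time, self.scan_time, **kw)


def injected_dose(rec: DoseRecord, *, exact_ln2: bool = False) -> float:
    """Net injected dose G (μCi).

    The syringe activity is decayed from assay to injection time and the
    residual (measured at injection time, hence not decayed) is subtracted:
    ``G = C * decay(E - D) - F``.
    """
    dt = rec.injection_time.total_minutes - rec.initial_time.total_minutes
    g = rec.initial_dose * decay_factor(dt, exact_ln2=exact_ln2) - rec.residual_dose
    if g <= 0:
        raise ValueError(
            f"inconsistent dose record: net injected dose {g:.4g} μCi <= 0"
        )
    return g


def scan_dose(
    g: float,
    injection_time: "ClockTime | str | float",
    scan_time: "ClockTime | str | float",
    *,
    exact_ln2: bool = False,
) -> float:
    """Dose on board at scan time, I = G * decay(H - E) (μCi)."""
    e = ClockTime.parse(injection_time)
    h = ClockTime.parse(scan_time)
    dt = h.total_minutes - e.total_minutes
    if dt < 0:
        raise ValueError("scan time precedes injection time")
    return g * decay_factor(dt, exact_ln2=exact_ln2)


@dataclass(frozen=True)
class ConversionFactor:
    """Scanner calibration CF = B1/B2/B3 with its phantom provenance.

    B1 is the phantom dose (μCi), B2 the phantom weight (g), B3 the mean
    scanner reading of the phantom (kBq/ml); CF carries units
    (μCi/g)/(kBq/ml).  For an ideally calibrated scanner reading true
    concentration, CF is exactly 1/37 (1 μCi = 37 kBq).
    """

    cf: float
    phantom_dose: float
    phantom_weight: float
    phantom_reading: float

    def __post_init__(self) -> None:
        if min(self.phantom_dose, self.phantom_weight, self.phantom_reading) <= 0:
            raise ValueError("phantom dose, weight and reading must all be positive")

    def __float__(self) -> float:
        return self.cf


def conversion_factor(b1: float, b2: float, b3: float) -> ConversionFactor:
    """Build the phantom conversion factor CF = B1/B2/B3."""
    if min(b1, b2, b3) <= 0:
        raise ValueError("B1, B2, B3 must all be positive")
    return ConversionFactor(cf=b1 / b2 / b3, phantom_dose=b1, phantom_weight=b2, phantom_reading=b3)
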