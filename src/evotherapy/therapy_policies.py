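"""Treatment regimens as drug-status policies, plus dose accounting.

Four regimens are modelled, all sharing the same pre-therapy phase (no
drug until serum PSA first reaches 80% of its untreated equilibrium, the
point at which a physician would call the disease castrate-resistant and
start abiraterone):

* ``UNTREATED``  -- never any drug (natural history).
* ``MTD``        -- continuous maximum-tolerated dose from the trigger on.
* ``METRONOMIC`` -- a long fixed "induction" block of continuous drug
  (default 240 days) followed by a predetermined on/off cycle that ignores
  tumor state.
* ``ADAPTIVE``   -- the trial rule: stop the drug when PSA falls to 50% of
  its pre-abiraterone baseline, restart when it climbs back to baseline.
  The two thresholds form a hysteresis band, so the status never chatters.

Decisions may be evaluated continuously (the idealized simulations) or
only at scheduled monitoring visits (default every 28 days, mimicking
4-weekly labs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

__all__ = [
    "RegimenKind",
    "Monitoring",
    "RegimenSpec",
    "DoseLedger",
    "drug_status",
    "dose_fraction",
]


class RegimenKind(str, Enum):
    UNTREATED = "untreated"
    MTD = "mtd"
    METRONOMIC = "metronomic"
    ADAPTIVE = "adaptive"


class Monitoring(str, Enum):
    CONTINUOUS = "continuous"
    INTERVAL = "interval"


@dataclass(frozen=True)
class RegimenSpec:
    """One of the four treatment policies with its parameters.

    ``trigger_fraction`` is the PSA fraction of the untreated equilibrium
    that initiates therapy; ``adaptive_lower``/``adaptive_upper`` are the
    stop/restart PSA fractions of the pre-abiraterone baseline.  The
    metronomic cycle defaults to 28 days on / 84 days off (25% on-time).
    """

    kind: RegimenKind = RegimenKind.ADAPTIVE
    trigger_fraction: float = 0.8
    adaptive_lower: float = 0.5
    adaptive_upper: float = 1.0
    induction_days: float = 240.0
    metronomic_on_days: float = 28.0
    metronomic_off_days: float = 84.0
    monitoring: Monitoring = Monitoring.CONTINUOUS
    monitoring_interval_days: float = 28.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", RegimenKind(self.kind))
        object.__setattr__(self, "monitoring", Monitoring(self.monitoring))
        if not 0 < self.trigger_fraction <= 1:
            raise ValueError("trigger_fraction must lie in (0, 1]")
        if not 0 < self.adaptive_lower < self.adaptive_upper:
            raise ValueError("need 0 < adaptive_lower < adaptive_upper")
        if self.induction_days < 0:
            raise ValueError("induction_days must be non-negative")
        if self.metronomic_on_days <= 0 or self.metronomic_off_days <= 0:
            raise ValueError("metronomic cycle lengths must be positive")
        if self.monitoring_interval_days <= 0:
            raise ValueError("monitoring_interval_days must be positive")

    # -- convenience constructors ------------------------------------
    @classmethod
    def untreated(cls, **kw) -> "RegimenSpec":
        return cls(kind=RegimenKind.UNTREATED, **kw)

    @classmethod
    def mtd(cls, **kw) -> "RegimenSpec":
        return cls(kind=RegimenKind.MTD, **kw)

    @classmethod
    def metronomic(cls, **kw) -> "RegimenSpec":
        return cls(kind=RegimenKind.METRONOMIC, **kw)

    @classmethod
    def adaptive(cls, **kw) -> "RegimenSpec":
        return cls(kind=RegimenKind.ADAPTIVE, **kw)

    def with_monitoring(self, monitoring: Monitoring,
                        interval_days: float | None = None) -> "RegimenSpec":
        kw = {"monitoring": monitoring}
        if interval_days is not None:
            kw["monitoring_interval_days"] = interval_days
        return replace(self, **kw)

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind.value,
            "trigger_fraction": self.trigger_fraction,
            "adaptive_lower": self.adaptive_lower,
            "adaptive_upper": self.adaptive_upper,
            "induction_days": self.induction_days,
            "metronomic_on_days": self.metronomic_on_days,
            "metronomic_off_days": self.metronomic_off_days,
            "monitoring": self.monitoring.value,
            "monitoring_interval_days": self.monitoring_interval_days,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegimenSpec":
        return cls(**d)


def drug_status(spec: RegimenSpec, t: float, psa: float, baseline_psa: float,
                trigger_time: float | None, currently_on: bool) -> bool:
    """Drug on/off decision at time ``t``.

    ``baseline_psa`` is the PSA at the moment therapy was triggered (the
    pre-abiraterone value the adaptive thresholds refer to).  Before the
    trigger every regimen is off.  Under INTERVAL monitoring the caller is
    responsible for evaluating this function only at monitoring visits;
    the decision rule itself is identical.
    """
    if spec.kind is RegimenKind.UNTREATED:
        return False
    if trigger_time is None or t < trigger_time:
        return False
    if spec.kind is RegimenKind.MTD:
        return True
    if spec.kind is RegimenKind.METRONOMIC:
        phase = t - trigger_time
        if phase < spec.induction_days:
            return True
        # the induction ends with a long on-block, so the cycle starts off
        cycle = spec.metronomic_off_days + spec.metronomic_on_days
        return (phase - spec.induction_days) % cycle >= spec.metronomic_off_days
    # ADAPTIVE: two-threshold hysteresis on PSA relative to baseline
    if baseline_psa <= 0:
        raise ValueError("baseline_psa must be positive for adaptive therapy")
    if psa <= spec.adaptive_lower * baseline_psa:
        return False
    if psa >= spec.adaptive_upper * baseline_psa:
        return True
    return currently_on


@dataclass(frozen=True)
class DoseLedger:
    """Disjoint, sorted drug-on intervals within an accounting window."""

    on_intervals: tuple[tuple[float, float], ...]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi < lo:
            raise ValueError("window end must not precede its start")
        intervals = tuple(
            (float(a), float(b)) for a, b in self.on_intervals if b > a
        )
        prev_end = lo
        for a, b in intervals:
            if a < prev_end - 1e-9 or b > hi + 1e-9:
                raise ValueError(
                    "on-intervals must be disjoint, sorted and inside the window"
                )
            prev_end = b
        object.__setattr__(self, "on_intervals", intervals)

    @property
    def on_days(self) -> float:
        return sum(b - a for a, b in self.on_intervals)

    @property
    def fraction(self) -> float:
        lo, hi = self.window
        if hi == lo:
            raise ValueError("zero-length accounting window")
        return self.on_days / (hi - lo)

    def clipped(self, end: float) -> "DoseLedger":
        """Ledger truncated to ``[window start, end]``."""
        lo, _ = self.window
        ivs = tuple(
            (a, min(b, end)) for a, b in self.on_intervals if a < end
        )
        return DoseLedger(on_intervals=ivs, window=(lo, end))

    def to_intervals_frame(self) -> pd.DataFrame:
        """Alternating on/off intervals covering the window, as a 3-column
        (start_day, end_day, status) table."""
        lo, hi = self.window
        rows, cursor = [], lo
        for a, b in self.on_intervals:
            if a > cursor:
                rows.append((cursor, a, "off"))
            rows.append((a, b, "on"))
            cursor = b
        if cursor < hi:
            rows.append((cursor, hi, "off"))
        return pd.DataFrame(rows, columns=["start_day", "end_day", "status"])


def dose_fraction(ledger: DoseLedger) -> float:
    """Cumulative drug exposure as a percentage of continuous dosing over
    the ledger's window (MTD over its own window is exactly 100%)."""
    return 100.0 * ledger.fraction
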