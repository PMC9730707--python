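"""Experiment phase calendar and irrigation-treatment labels.

The deficit-irrigation experiment runs in three ordered phases: a
well-irrigated baseline, a progressive drought (irrigation withheld), and a
water-recovery phase after rewatering. Each pot carries one of three
treatment labels: CK (well-watered control throughout), WR_theta (rewatered
the moment soil moisture reaches the variety's critical value θ_cri) and
WR_SD (rewatered only at severe drought / wilting).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

__all__ = ["PHASES", "TREATMENTS", "PhaseDesign"]

PHASES = ("well_irrigated", "progressive_drought", "water_recovery")
TREATMENTS = ("CK", "WR_theta", "WR_SD")


@dataclass
class PhaseDesign:
    """Non-overlapping, ordered phase calendar plus per-pot treatment labels.

    ``phases`` maps phase name -> (start_date, end_date), half-open on the
    end date; a phase may be absent (e.g. a CK pot never enters drought).
    """

    phases: dict[str, tuple[_dt.date, _dt.date]]
    treatments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")
        for name, (start, end) in self.phases.items():
            if end < start:
                raise ValueError(f"phase {name}: end before start")
        ordered = [self.phases[p] for p in PHASES if p in self.phases]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 < e1:
                raise ValueError("phases must be non-overlapping and in canonical order")
        bad = {p: t for p, t in self.treatments.items() if t not in TREATMENTS}
        if bad:
            raise ValueError(f"unknown treatment labels: {bad}")

    def phase_of(self, day: _dt.date) -> str | None:
        """Phase containing ``day`` (start inclusive, end exclusive), or None."""
        for name in PHASES:
            if name in self.phases:
                start, end = self.phases[name]
                if start <= day < end:
                    return name
        return None

    def days_in(self, phase: str) -> list[_dt.date]:
        start, end = self.phases[phase]
        return [start + _dt.timedelta(days=i) for i in range((end - start).days)]
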