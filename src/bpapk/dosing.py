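"""Dosing schedules (route, per-dose amount, timing)."""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ModelParameters

__all__ = ["DoseSchedule"]


@dataclass
class DoseSchedule:
    """One or more bolus doses of d6-BPA.

    ``dose_per_kg`` is in μg/kg body weight per administration;
    ``dose_times`` in hours, strictly increasing.  ``daily`` builds a
    repeated once-daily schedule (dose at the start of each 24 h interval).
    """

    route: str  # "iv" | "oral"
    dose_per_kg: float
    dose_times: list[float] = field(default_factory=lambda: [0.0])

    def __post_init__(self) -> None:
        if self.route not in ("iv", "oral"):
            raise ValueError(f"unknown route {self.route!r}; use 'iv' or 'oral'")
        if self.dose_per_kg < 0:
            raise ValueError("dose must be non-negative")
        times = list(self.dose_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        self.dose_times = times

    @classmethod
    def single(cls, route: str, dose_per_kg: float, at: float = 0.0) -> "DoseSchedule":
        return cls(route=route, dose_per_kg=dose_per_kg, dose_times=[at])

    @classmethod
    def daily(cls, route: str, dose_per_kg: float, n_days: int) -> "DoseSchedule":
        return cls(route=route, dose_per_kg=dose_per_kg,
                   dose_times=[24.0 * d for d in range(n_days)])

    @property
    def n_doses(self) -> int:
        return len(self.dose_times)

    def dose_amount_nmol(self, p: ModelParameters) -> float:
        """Amount of one bolus in nmol for this parameter set's body weight."""
        micrograms = self.dose_per_kg * p.physiology.body_weight
        return micrograms / p.chemical.molecular_weight_parent * 1000.0

    def total_dose_nmol(self, p: ModelParameters) -> float:
        return self.n_doses * self.dose_amount_nmol(p)
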