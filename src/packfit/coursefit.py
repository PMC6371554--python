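"""Course fitting: for one package and one regimen, decide applicability
and find the leftover-minimizing way to complete the course.

All unit arithmetic runs on integer half-unit counts; public results are
floats that are exact multiples of 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .domain import (
    CourseFit,
    DomainError,
    DrugPackage,
    Regimen,
    half_units_per_dose,
)


@dataclass(frozen=True)
class FitPolicy:
    """Knobs for resolving flexible regimens.

    ``duration_tiebreak`` picks among durations attaining the minimal
    leftover (after minimizing package count); ``dose_candidates`` decides
    whether a dose range is tried at its printed endpoints only or at every
    constructible option.  Full adherence is assumed and asserted.
    """

    duration_tiebreak: str = "shortest"
    dose_candidates: str = "endpoints"
    adherence: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_tiebreak not in ("shortest", "longest"):
            raise DomainError(f"unknown duration_tiebreak {self.duration_tiebreak!r}")
        if self.dose_candidates not in ("endpoints", "all_constructible"):
            raise DomainError(f"unknown dose_candidates {self.dose_candidates!r}")
        if self.adherence != 1.0:
            raise DomainError("only 100% adherence is supported")


DEFAULT_POLICY = FitPolicy()

_NOT_APPLICABLE = CourseFit(applicable=False, inapplicability_reason="none")


def applicability(package: DrugPackage, regimen: Regimen) -> tuple:
    """Decide whether *regimen* can be audited against *package*.

    Returns ``(True, "none")`` or ``(False, reason)`` with reason one of
    substance_not_named, formulation_mismatch, unit_mismatch,
    dose_not_constructible (checked in that order).
    """
    f = package.formulation
    if f.substance != regimen.substance:
        return False, "substance_not_named"
    if regimen.variant_required and f.variant != regimen.variant_required:
        return False, "formulation_mismatch"
    if regimen.dose.unit != f.strength_unit:
        return False, "unit_mismatch"
    if all(half_units_per_dose(d, f) is None for d in regimen.dose.options):
        return False, "dose_not_constructible"
    return True, "none"


def course_units(
    dose_amount: float, doses_per_day: int, days: int, formulation
) -> float:
    """Units needed for a full course: units/dose x doses/day x days."""
    if days < 1:
        raise DomainError("days must be >= 1")
    if doses_per_day < 1:
        raise DomainError("doses_per_day must be >= 1")
    k = half_units_per_dose(dose_amount, formulation)
    if k is None:
        raise DomainError(
            f"dose {dose_amount:g} not constructible from "
            f"{formulation.strength_value:g} {formulation.strength_unit}"
        )
    return k * doses_per_day * days / 2.0


def fit_fixed(
    package: DrugPackage, dose_amount: float, doses_per_day: int, days: int
) -> tuple:
    """(min_packages, extra_units) for a fixed dose and duration."""
    half_course = _half_course(package, dose_amount, doses_per_day, days)
    return _fit_half(package.units_per_package, half_course)


def _half_course(package, dose_amount, doses_per_day, days) -> int:
    if days < 1 or doses_per_day < 1:
        raise DomainError("doses_per_day and days must be >= 1")
    k = half_units_per_dose(dose_amount, package.formulation)
    if k is None:
        raise DomainError("dose not constructible; check applicability first")
    return k * doses_per_day * days


def _fit_half(units_per_package: int, half_course: int) -> tuple:
    half_pack = 2 * units_per_package
    min_packages = -(-half_course // half_pack)  # ceil
    extra_half = min_packages * half_pack - half_course
    return min_packages, extra_half / 2.0


def _candidate_doses(package: DrugPackage, regimen: Regimen, policy: FitPolicy) -> list:
    opts = regimen.dose.options
    if policy.dose_candidates == "endpoints" and len(opts) > 2:
        opts = (opts[0], opts[-1])
    return [d for d in opts if half_units_per_dose(d, package.formulation) is not None]


def fit_course(
    package: DrugPackage, regimen: Regimen, policy: FitPolicy = DEFAULT_POLICY
) -> CourseFit:
    """Fit *regimen* from copies of *package*, minimizing leftover units.

    Every (candidate dose, integer day in the duration interval)
    combination is evaluated; the winner minimizes extra units, then
    package count, then duration per ``policy.duration_tiebreak``, then
    dose amount.
    """
    ok, reason = applicability(package, regimen)
    if not ok:
        return CourseFit(applicable=False, inapplicability_reason=reason)
    best = None
    for dose in _candidate_doses(package, regimen, policy):
        k = half_units_per_dose(dose, package.formulation)
        for days in regimen.duration.days():
            half_course = k * regimen.doses_per_day * days
            min_packages, extra = _fit_half(package.units_per_package, half_course)
            day_rank = days if policy.duration_tiebreak == "shortest" else -days
            key = (extra, min_packages, day_rank, dose)
            if best is None or key < best[0]:
                best = (key, dose, days, half_course, min_packages, extra)
    _, dose, days, half_course, min_packages, extra = best
    return CourseFit(
        applicable=True,
        chosen_dose=dose,
        chosen_days=days,
        units_per_course=half_course / 2.0,
        min_packages=min_packages,
        extra_units=extra,
        matched=extra == 0,
    )


def brute_force_oracle(
    package: DrugPackage, regimen: Regimen, policy: FitPolicy = DEFAULT_POLICY
) -> CourseFit:
    """Exhaustive-search reference for :func:`fit_course` (tests only).

    Counts out the course dose by dose and finds the minimal package count
    by linear search instead of ceiling arithmetic, so it shares no code
    path with the production fit.
    """
    ok, reason = applicability(package, regimen)
    if not ok:
        return CourseFit(applicable=False, inapplicability_reason=reason)
    candidates = []
    for dose in _candidate_doses(package, regimen, policy):
        k = half_units_per_dose(dose, package.formulation)
        for days in regimen.duration.days():
            half_course = 0
            for _day in range(days):
                for _administration in range(regimen.doses_per_day):
                    half_course += k
            p = 1
            while p * 2 * package.units_per_package < half_course:
                p += 1
            extra = (p * 2 * package.units_per_package - half_course) / 2.0
            day_rank = days if policy.duration_tiebreak == "shortest" else -days
            candidates.append(((extra, p, day_rank, dose), dose, days, half_course, p, extra))
    candidates.sort(key=lambda c: c[0])
    _, dose, days, half_course, p, extra = candidates[0]
    return CourseFit(
        applicable=True,
        chosen_dose=dose,
        chosen_days=days,
        units_per_course=half_course / 2.0,
        min_packages=p,
        extra_units=extra,
        matched=extra == 0,
    )
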