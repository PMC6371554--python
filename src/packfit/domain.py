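"""Core domain types and dose-construction arithmetic.

Quantities of drug are counted in *units* (tablets, capsules, sachets).
Half-units arise only when a formulation is divisible into two equal
halves; all arithmetic is carried out on integer half-unit counts so that
equality tests (``extra_units == 0``) are exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

FORMS = ("tablet", "capsule", "other-solid")
UNITS = ("mg", "IU")
REIMBURSEMENT_STATES = ("current", "former", "none")
SOURCES = ("ISKRA", "NICE", "IDSA", "SmPC")
INDICATIONS = ("sore_throat", "uti", "other")

INAPPLICABILITY_REASONS = (
    "none",
    "substance_not_named",
    "unit_mismatch",
    "dose_not_constructible",
    "formulation_mismatch",
)


class DomainError(ValueError):
    """Invalid domain value."""


def format_amount(value: float) -> str:
    """Render a strength/dose amount without scientific notation."""
    if value == int(value):
        return str(int(value))
    return f"{value:g}"


# ---------------------------------------------------------------------------
# substance canonicalization
# ---------------------------------------------------------------------------

#: synonym -> canonical substance name (keys are whitespace-normalized,
#: lowercase).  Canonical names map to themselves so the function is
#: idempotent by construction.
_SYNONYMS = {
    "co-amoxiclav": "amoxicillin-clavulanate",
    "coamoxiclav": "amoxicillin-clavulanate",
    "amoxicillin and clavulanic acid": "amoxicillin-clavulanate",
    "amoxicillin with clavulanic acid": "amoxicillin-clavulanate",
    "amoxicillin/clavulanic acid": "amoxicillin-clavulanate",
    "amoxicillin-clavulanate": "amoxicillin-clavulanate",
    "penicillin v": "phenoxymethylpenicillin",
    "phenoxymethylpenicillin": "phenoxymethylpenicillin",
    "sulfametoxazole, trimethoprim": "co-trimoxazole",
    "sulfamethoxazole, trimethoprim": "co-trimoxazole",
    "sulfametoxazole/trimethoprim": "co-trimoxazole",
    "sulfamethoxazole/trimethoprim": "co-trimoxazole",
    "sulfamethoxazole-trimethoprim": "co-trimoxazole",
    "co-trimoxazole": "co-trimoxazole",
    "fosfomycinum": "fosfomycin",
    "nitroxolin": "nitroxoline",
    "flucloxacilin": "flucloxacillin",
}


def canonicalize_substance(raw_name: str) -> str:
    """Return the canonical lowercase substance name for *raw_name*.

    Lowercases, collapses internal whitespace, strips the ends, and applies
    a synonym table so registry and guideline spellings join on the same
    key.  Idempotent.

    Raises
    ------
    DomainError
        If *raw_name* is empty or whitespace only.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise DomainError("substance name must be a nonempty string")
    name = re.sub(r"\s+", " ", raw_name.strip().lower())
    return _SYNONYMS.get(name, name)


# ---------------------------------------------------------------------------
# value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Formulation:
    """A dosage form of one substance at one strength.

    ``divisible`` marks formulations that can be split into two equal
    halves (scored tablets); only tablets may be divisible.  ``variant``
    carries a release-form qualifier such as ``"extended release"`` and is
    empty for ordinary immediate-release products.
    """

    substance: str
    form: str
    strength_value: float
    strength_unit: str
    divisible: bool = False
    variant: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "substance", canonicalize_substance(self.substance))
        if self.form not in FORMS:
            raise DomainError(f"unknown form {self.form!r}")
        if not self.strength_value > 0:
            raise DomainError("strength_value must be positive")
        if self.strength_unit not in UNITS:
            raise DomainError(f"unknown strength unit {self.strength_unit!r}")
        if self.divisible and self.form != "tablet":
            raise DomainError("only tablets may be divisible")


@dataclass(frozen=True)
class DrugPackage:
    """One marketed package: a formulation packed as a unit count."""

    formulation: Formulation
    units_per_package: int
    atc_code: str = ""
    reimbursement: str = "none"

    def __post_init__(self) -> None:
        if not (isinstance(self.units_per_package, int) and self.units_per_package >= 1):
            raise DomainError("units_per_package must be an integer >= 1")
        if self.reimbursement not in REIMBURSEMENT_STATES:
            raise DomainError(f"unknown reimbursement state {self.reimbursement!r}")

    @property
    def package_label(self) -> str:
        f = self.formulation
        return f"{self.units_per_package}x{format_amount(f.strength_value)} {f.strength_unit}"


@dataclass(frozen=True)
class DoseSpec:
    """Discrete candidate per-administration doses.

    A fixed dose is a single-element list; a printed range like
    "250-500 mg" is stored as its endpoints.
    """

    options: tuple
    unit: str

    def __post_init__(self) -> None:
        opts = tuple(float(o) for o in self.options)
        object.__setattr__(self, "options", opts)
        if not opts:
            raise DomainError("dose options must be nonempty")
        if any(o <= 0 for o in opts):
            raise DomainError("dose options must be positive")
        if list(opts) != sorted(set(opts)):
            raise DomainError("dose options must be strictly increasing")
        if self.unit not in UNITS:
            raise DomainError(f"unknown dose unit {self.unit!r}")

    @property
    def text(self) -> str:
        amounts = "-".join(format_amount(o) for o in self.options)
        return f"{amounts} {self.unit}"


@dataclass(frozen=True)
class DurationSpec:
    """Treatment duration in days; fixed durations have min == max."""

    min_days: int
    max_days: int

    def __post_init__(self) -> None:
        if not (isinstance(self.min_days, int) and isinstance(self.max_days, int)):
            raise DomainError("durations must be integers")
        if not (1 <= self.min_days <= self.max_days):
            raise DomainError("need 1 <= min_days <= max_days")

    @property
    def fixed(self) -> bool:
        return self.min_days == self.max_days

    @property
    def text(self) -> str:
        if self.fixed:
            return f"{self.min_days} day" + ("s" if self.min_days != 1 else "")
        return f"{self.min_days}-{self.max_days} days"

    def days(self) -> range:
        return range(self.min_days, self.max_days + 1)


@dataclass(frozen=True)
class Regimen:
    """One drug-specific guideline recommendation."""

    id: str
    source: str
    indication: str
    substance: str
    dose: DoseSpec
    doses_per_day: int
    duration: DurationSpec
    note: str = ""
    variant_required: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "substance", canonicalize_substance(self.substance))
        if self.source not in SOURCES:
            raise DomainError(f"unknown source {self.source!r}")
        if self.indication not in INDICATIONS:
            raise DomainError(f"unknown indication {self.indication!r}")
        if not (isinstance(self.doses_per_day, int) and self.doses_per_day >= 1):
            raise DomainError("doses_per_day must be an integer >= 1")

    @property
    def text(self) -> str:
        return f"{self.doses_per_day}x{self.dose.text}, {self.duration.text}"


@dataclass(frozen=True)
class CourseFit:
    """Outcome of fitting one regimen from copies of one package.

    For applicable fits ``extra_units = min_packages * units_per_package -
    units_per_course`` and ``0 <= extra_units < units_per_package``; all
    unit quantities are exact multiples of 0.5 in original-formulation
    units.  Inapplicable fits carry a reason and empty numeric fields.
    """

    applicable: bool
    inapplicability_reason: str = "none"
    chosen_dose: Optional[float] = None
    chosen_days: Optional[int] = None
    units_per_course: Optional[float] = None
    min_packages: Optional[int] = None
    extra_units: Optional[float] = None
    matched: bool = False

    def __post_init__(self) -> None:
        if self.inapplicability_reason not in INAPPLICABILITY_REASONS:
            raise DomainError(
                f"unknown inapplicability reason {self.inapplicability_reason!r}"
            )
        if self.applicable and self.inapplicability_reason != "none":
            raise DomainError("applicable fit cannot carry a reason")
        if not self.applicable and self.matched:
            raise DomainError("inapplicable fit cannot be matched")


# ---------------------------------------------------------------------------
# dose construction
# ---------------------------------------------------------------------------


def half_units_per_dose(dose_amount: float, formulation: Formulation) -> Optional[int]:
    """Number of half-units of *formulation* that make up one dose, or None.

    Returns the smallest positive integer ``k`` with ``(k/2) * strength ==
    dose_amount``.  For non-divisible formulations ``k`` must be even (whole
    units only).  ``None`` means the dose cannot be constructed from this
    formulation.
    """
    if not dose_amount > 0:
        raise DomainError("dose amount must be positive")
    ratio = Fraction(dose_amount) / Fraction(formulation.strength_value)
    k = ratio * 2
    if k.denominator != 1:
        return None
    k = int(k)
    if not formulation.divisible and k % 2 != 0:
        return None
    return k


def units_per_dose(dose_amount: float, formulation: Formulation) -> Optional[float]:
    """Units of *formulation* per administration (multiple of 0.5), or None."""
    k = half_units_per_dose(dose_amount, formulation)
    return None if k is None else k / 2.0
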