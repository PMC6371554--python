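"""Registry ingest: parsing a drug-registry extract and applying the
inclusion/exclusion workflow that yields the audit-ready package list.

Exclusion rules fire in a fixed order and an entry is logged only under the
first rule it fails, so per-rule box counts are well defined.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import yaml

from .domain import (
    DomainError,
    DoseSpec,
    DrugPackage,
    DurationSpec,
    Formulation,
    Regimen,
    canonicalize_substance,
)

REGISTRY_COLUMNS = (
    "trade_name",
    "atc_code",
    "substance",
    "form",
    "strength_value",
    "strength_unit",
    "divisible",
    "package_sizes",
    "marketing_status",
    "dose_prespecified",
    "paediatric",
)

REIMBURSEMENT_COLUMNS = (
    "substance",
    "strength_value",
    "strength_unit",
    "units_per_package",
    "status",
)

MARKETING_STATES = ("marketed", "not_marketed", "discontinued")

#: order in which exclusion rules are applied
RULE_ORDER = ("atc_prefix", "marketing_status", "oral_form", "dose_prespecified", "paediatric")

# dosage forms that count as oral solids with a prespecified unit
_SOLID_FORM_MAP = {"tablet": "tablet", "capsule": "capsule"}


class RegistryFormatError(ValueError):
    """The registry/reimbursement file violates its column contract."""


@dataclass(frozen=True)
class RawRegistryEntry:
    """One parsed registry row, before any filtering."""

    row_id: int
    trade_name: str
    atc_code: str
    substance: str
    form: str
    strength_value: float
    strength_unit: str
    divisible: bool
    package_sizes: tuple
    marketing_status: str
    dose_prespecified: bool
    paediatric: bool


@dataclass(frozen=True)
class FilterConfig:
    atc_prefix: str = "J01"
    oral_only: bool = True
    require_prespecified_dose: bool = True
    max_units_exclusive: Optional[int] = None
    include_paediatric: bool = False

    def __post_init__(self) -> None:
        if self.max_units_exclusive is not None and self.max_units_exclusive < 1:
            raise DomainError("max_units_exclusive must be >= 1 when set")


@dataclass
class ExclusionLog:
    """Which entries were excluded, and under which (first-failing) rule."""

    entries: list = field(default_factory=list)  # (row_id, rule)

    def record(self, row_id: int, rule: str) -> None:
        self.entries.append((row_id, rule))

    @property
    def counts(self) -> dict:
        return dict(Counter(rule for _, rule in self.entries))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ParseResult:
    entries: list
    errors: list  # (row number, message)

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_bool(raw: str, column: str, row: int):
    v = raw.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(f"row {row}: column {column!r} has non-boolean value {raw!r}")


def parse_registry(stream: Union[str, TextIO]) -> ParseResult:
    """Parse a registry CSV into raw entries.

    Malformed rows are collected in the result's ``errors`` list rather
    than silently dropped; a missing required column raises
    :class:`RegistryFormatError` naming the column.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    for col in REGISTRY_COLUMNS:
        if col not in header:
            raise RegistryFormatError(f"registry is missing required column {col!r}")
    entries, errors = [], []
    for i, row in enumerate(reader, start=2):  # 1-based, after header
        try:
            sizes = tuple(
                int(tok) for tok in row["package_sizes"].split(";") if tok.strip()
            )
            if not sizes or any(s < 1 for s in sizes):
                raise ValueError(f"row {i}: invalid package_sizes {row['package_sizes']!r}")
            status = row["marketing_status"].strip()
            if status not in MARKETING_STATES:
                raise ValueError(f"row {i}: unknown marketing_status {status!r}")
            strength = float(row["strength_value"])
            if strength <= 0:
                raise ValueError(f"row {i}: strength_value must be positive")
            entries.append(
                RawRegistryEntry(
                    row_id=i,
                    trade_name=row["trade_name"].strip(),
                    atc_code=row["atc_code"].strip(),
                    substance=row["substance"].strip(),
                    form=row["form"].strip().lower(),
                    strength_value=strength,
                    strength_unit=row["strength_unit"].strip(),
                    divisible=_parse_bool(row["divisible"], "divisible", i),
                    package_sizes=sizes,
                    marketing_status=status,
                    dose_prespecified=_parse_bool(
                        row["dose_prespecified"], "dose_prespecified", i
                    ),
                    paediatric=_parse_bool(row["paediatric"], "paediatric", i),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append((i, str(exc)))
    return ParseResult(entries=entries, errors=errors)


def _is_oral(form: str) -> bool:
    return form in _SOLID_FORM_MAP or form in ("granules", "other-solid") or "oral" in form


def filter_registry(
    entries: Iterable[RawRegistryEntry], config: FilterConfig
) -> tuple:
    """Apply the exclusion workflow; returns (kept entries, exclusion log)."""
    kept, log = [], ExclusionLog()
    for e in entries:
        rule = None
        if config.atc_prefix and not e.atc_code.startswith(config.atc_prefix):
            rule = "atc_prefix"
        elif e.marketing_status != "marketed":
            rule = "marketing_status"
        elif config.oral_only and not _is_oral(e.form):
            rule = "oral_form"
        elif config.require_prespecified_dose and not e.dose_prespecified:
            rule = "dose_prespecified"
        elif not config.include_paediatric and e.paediatric:
            rule = "paediatric"
        if rule is None:
            kept.append(e)
        else:
            log.record(e.row_id, rule)
    return kept, log


def expand_and_merge(
    entries: Iterable[RawRegistryEntry], config: FilterConfig
) -> list:
    """Expand each entry to one package per size and merge duplicates.

    Packages are keyed by (canonical substance, strength, unit, size)
    irrespective of trade name; a key is divisible if any merged entry is.
    Output order is (substance, strength, size).
    """
    merged = {}
    for e in entries:
        substance = canonicalize_substance(e.substance)
        form = _SOLID_FORM_MAP.get(e.form, "other-solid")
        for size in e.package_sizes:
            if config.max_units_exclusive is not None and size >= config.max_units_exclusive:
                continue
            key = (substance, e.strength_value, e.strength_unit, size)
            prev = merged.get(key)
            divisible = e.divisible and form == "tablet"
            if prev is not None:
                divisible = divisible or prev[1]
                form = prev[0] if prev[1] else form
            merged[key] = (form, divisible, e.atc_code)
    packages = []
    for (substance, strength, unit, size) in sorted(merged):
        form, divisible, atc = merged[(substance, strength, unit, size)]
        packages.append(
            DrugPackage(
                formulation=Formulation(
                    substance=substance,
                    form=form,
                    strength_value=strength,
                    strength_unit=unit,
                    divisible=divisible,
                ),
                units_per_package=size,
                atc_code=atc,
            )
        )
    return packages


# ---------------------------------------------------------------------------
# reimbursement
# ---------------------------------------------------------------------------


def parse_reimbursement(stream: Union[str, TextIO]) -> dict:
    """Parse a reimbursement CSV into a {(substance, strength, unit, size):
    status} mapping."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    header = reader.fieldnames or []
    for col in REIMBURSEMENT_COLUMNS:
        if col not in header:
            raise RegistryFormatError(f"reimbursement table is missing column {col!r}")
    table = {}
    for i, row in enumerate(reader, start=2):
        status = row["status"].strip()
        if status not in ("current", "former"):
            raise RegistryFormatError(f"row {i}: unknown reimbursement status {status!r}")
        key = (
            canonicalize_substance(row["substance"]),
            float(row["strength_value"]),
            row["strength_unit"].strip(),
            int(row["units_per_package"]),
        )
        table[key] = status
    return table


def annotate_reimbursement(packages: Iterable[DrugPackage], table: dict) -> list:
    """Return packages with their reimbursement field set from *table*;
    packages absent from the table default to 'none'."""
    out = []
    for p in packages:
        f = p.formulation
        key = (f.substance, f.strength_value, f.strength_unit, p.units_per_package)
        status = table.get(key, "none")
        out.append(
            DrugPackage(
                formulation=f,
                units_per_package=p.units_per_package,
                atc_code=p.atc_code,
                reimbursement=status,
            )
        )
    return out


# ---------------------------------------------------------------------------
# guideline regimen files
# ---------------------------------------------------------------------------


def load_regimens(stream: Union[str, TextIO]) -> list:
    """Load a guideline-regimen YAML document into Regimen objects.

    The document is a list of records with keys: id, source, indication,
    substance, doses (list of amounts), unit, doses_per_day, min_days,
    max_days, and optional note / variant_required.  Validation errors are
    raised as :class:`RegistryFormatError` naming the offending record.
    """
    data = yaml.safe_load(stream)
    if data is None:
        return []
    if not isinstance(data, list):
        raise RegistryFormatError("regimen file must contain a list of records")
    regimens = []
    for i, rec in enumerate(data):
        try:
            regimens.append(
                Regimen(
                    id=str(rec["id"]),
                    source=rec["source"],
                    indication=rec["indication"],
                    substance=rec["substance"],
                    dose=DoseSpec(options=tuple(rec["doses"]), unit=rec["unit"]),
                    doses_per_day=int(rec["doses_per_day"]),
                    duration=DurationSpec(
                        min_days=int(rec["min_days"]), max_days=int(rec["max_days"])
                    ),
                    note=rec.get("note", "") or "",
                    variant_required=rec.get("variant_required", "") or "",
                )
            )
        except (KeyError, TypeError, DomainError) as exc:
            raise RegistryFormatError(f"regimen record {i}: {exc}") from exc
    ids = [r.id for r in regimens]
    if len(ids) != len(set(ids)):
        raise RegistryFormatError("regimen ids must be unique")
    return regimens
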