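"""Cross-referencing packages against regimens and aggregating the
matched/mismatched counts, overall and stratified by reimbursement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .coursefit import DEFAULT_POLICY, FitPolicy, fit_course
from .domain import CourseFit, DrugPackage, Regimen, format_amount

REPORT_COLUMNS = (
    "substance",
    "package_label",
    "reimbursement",
    "source",
    "indication",
    "regimen_text",
    "applicable",
    "reason",
    "chosen_dose",
    "chosen_days",
    "units_per_course",
    "min_packages",
    "extra_units",
    "matched",
)

_STRATA = ("all", "current", "current_or_former")


@dataclass(frozen=True)
class ComboRow:
    """One audited (package, regimen) pair."""

    package: DrugPackage
    regimen: Regimen
    fit: CourseFit

    @property
    def package_id(self) -> str:
        return f"{self.package.formulation.substance}|{self.package.package_label}"

    @property
    def regimen_id(self) -> str:
        return self.regimen.id


@dataclass(frozen=True)
class MatchSummary:
    source: Optional[str]
    indication: Optional[str]
    reimbursement: str
    n_applicable_combos: int
    n_matched: int
    n_mismatched: int
    n_inapplicable: int
    package_level_matched: int


def _package_sort_key(p: DrugPackage):
    f = p.formulation
    return (f.substance, f.strength_unit, f.strength_value, p.units_per_package)


def audit(
    packages: Iterable[DrugPackage],
    regimens: Iterable[Regimen],
    policy: FitPolicy = DEFAULT_POLICY,
) -> list:
    """Audit every same-substance (package, regimen) pair.

    The output order is deterministic — (substance, strength, size) for
    packages, then the regimen file order — so reports are byte-stable
    regardless of input ordering.
    """
    regimens = list(regimens)
    regimen_rank = {r.id: i for i, r in enumerate(regimens)}
    rows = []
    for package in sorted(packages, key=_package_sort_key):
        for regimen in regimens:
            if regimen.substance != package.formulation.substance:
                continue
            rows.append(ComboRow(package, regimen, fit_course(package, regimen, policy)))
    rows.sort(key=lambda r: (_package_sort_key(r.package), regimen_rank[r.regimen.id]))
    return rows


def _in_stratum(package: DrugPackage, stratum: str) -> bool:
    if stratum == "all":
        return True
    if stratum == "current":
        return package.reimbursement == "current"
    if stratum == "current_or_former":
        return package.reimbursement in ("current", "former")
    raise ValueError(f"unknown reimbursement stratum {stratum!r}")


def _select(rows, source, indication, reimbursement):
    return [
        r
        for r in rows
        if (source is None or r.regimen.source == source)
        and (indication is None or r.regimen.indication == indication)
        and _in_stratum(r.package, reimbursement)
    ]


def summarize(
    rows: Iterable[ComboRow],
    source: Optional[str] = None,
    indication: Optional[str] = None,
    reimbursement: str = "all",
    count_na_as_mismatch: bool = False,
) -> MatchSummary:
    """Aggregate matched/mismatched counts over the selected rows.

    Combo-level counts count (package, regimen) pairs; the package-level
    count collapses over regimens in scope.  Inapplicable combos are
    excluded from both classes unless ``count_na_as_mismatch`` is set.
    """
    selected = _select(list(rows), source, indication, reimbursement)
    applicable = [r for r in selected if r.fit.applicable]
    inapplicable = [r for r in selected if not r.fit.applicable]
    matched = [r for r in applicable if r.fit.matched]
    mismatched = [r for r in applicable if not r.fit.matched]
    if count_na_as_mismatch:
        mismatched += inapplicable
    return MatchSummary(
        source=source,
        indication=indication,
        reimbursement=reimbursement,
        n_applicable_combos=len(applicable),
        n_matched=len(matched),
        n_mismatched=len(mismatched),
        n_inapplicable=len(inapplicable),
        package_level_matched=len({r.package_id for r in matched}),
    )


def national_accordance(rows: Iterable[ComboRow]) -> tuple:
    """Accordance with the national (ISKRA) guidelines over both
    indications.

    Returns (matched_total, combo_total, matched_reimbursed,
    combo_total_reimbursed), where combo totals count applicable
    combinations and the reimbursed variant is restricted to currently
    reimbursed packages.
    """
    rows = list(rows)
    matched_total = combo_total = matched_reimb = combo_reimb = 0
    for indication in ("sore_throat", "uti"):
        s = summarize(rows, source="ISKRA", indication=indication)
        matched_total += s.n_matched
        combo_total += s.n_applicable_combos
        s = summarize(rows, source="ISKRA", indication=indication, reimbursement="current")
        matched_reimb += s.n_matched
        combo_reimb += s.n_applicable_combos
    return matched_total, combo_total, matched_reimb, combo_reimb


def package_rollup(
    rows: Iterable[ComboRow],
    source: Optional[str] = None,
    indication: Optional[str] = None,
    reimbursement: str = "all",
) -> dict:
    """Per-substance (packages in scope, packages matching >= 1 regimen).

    A package is in scope if it has at least one combo row under the
    filter, applicable or not.
    """
    selected = _select(list(rows), source, indication, reimbursement)
    in_scope, matched_any = {}, {}
    for r in selected:
        sub = r.package.formulation.substance
        in_scope.setdefault(sub, set()).add(r.package_id)
        if r.fit.applicable and r.fit.matched:
            matched_any.setdefault(sub, set()).add(r.package_id)
    return {
        sub: (len(in_scope[sub]), len(matched_any.get(sub, set())))
        for sub in sorted(in_scope)
    }


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def format_units(x: Optional[float]) -> str:
    """Half-units print as '0.5'; whole counts print without a decimal."""
    if x is None:
        return ""
    return str(int(x)) if x == int(x) else f"{x:.1f}"


def report_frame(rows: Iterable[ComboRow]) -> pd.DataFrame:
    """Flatten audit rows into the report table (fixed column order)."""
    records = []
    for r in rows:
        fit = r.fit
        records.append(
            {
                "substance": r.package.formulation.substance,
                "package_label": r.package.package_label,
                "reimbursement": r.package.reimbursement,
                "source": r.regimen.source,
                "indication": r.regimen.indication,
                "regimen_text": r.regimen.text,
                "applicable": fit.applicable,
                "reason": "" if fit.applicable else fit.inapplicability_reason,
                "chosen_dose": "" if fit.chosen_dose is None else format_amount(fit.chosen_dose),
                "chosen_days": "" if fit.chosen_days is None else fit.chosen_days,
                "units_per_course": format_units(fit.units_per_course),
                "min_packages": "" if fit.min_packages is None else fit.min_packages,
                "extra_units": format_units(fit.extra_units),
                "matched": fit.matched,
            }
        )
    return pd.DataFrame.from_records(records, columns=list(REPORT_COLUMNS))


def summary_tree(rows: Iterable[ComboRow]) -> dict:
    """Nested {source: {indication: {stratum: counts}}} summary."""
    rows = list(rows)
    tree = {}
    sources = sorted({r.regimen.source for r in rows})
    for source in sources:
        tree[source] = {}
        indications = sorted(
            {r.regimen.indication for r in rows if r.regimen.source == source}
        )
        for indication in indications:
            tree[source][indication] = {}
            for stratum in _STRATA:
                s = summarize(rows, source, indication, stratum)
                tree[source][indication][stratum] = {
                    "applicable": s.n_applicable_combos,
                    "matched": s.n_matched,
                    "mismatched": s.n_mismatched,
                    "inapplicable": s.n_inapplicable,
                    "packages_matched": s.package_level_matched,
                }
    m, t, mr, tr = national_accordance(rows)
    tree["national_accordance"] = {
        "matched": m,
        "applicable": t,
        "matched_reimbursed": mr,
        "applicable_reimbursed": tr,
    }
    return tree


def render_tables(rows: Iterable[ComboRow]) -> str:
    """Render per-substance accordance tables as plain text.

    Flexible-duration fits annotate the chosen duration as
    ``"p (d days)"``; inapplicable combos render as ``"n/a"``.
    """
    rows = list(rows)
    lines = []
    by_substance = {}
    for r in rows:
        by_substance.setdefault(r.package.formulation.substance, []).append(r)
    for substance in sorted(by_substance):
        lines.append(substance)
        lines.append("=" * len(substance))
        for r in by_substance[substance]:
            fit = r.fit
            if not fit.applicable:
                cell = "n/a | n/a"
            else:
                packages = str(fit.min_packages)
                if not r.regimen.duration.fixed:
                    packages += f" ({fit.chosen_days} days)"
                cell = f"{packages} | {format_units(fit.extra_units)}"
            lines.append(
                f"{r.package.package_label:>16}  {r.regimen.source:<6}"
                f"{r.regimen.text:<34} {cell}"
            )
        lines.append("")
    return "\n".join(lines)
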