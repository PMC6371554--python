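"""Packaged reference dataset and synthetic registry/regimen generation.

``paper_fixture`` loads the versioned data files shipped with the package
(checked against a manifest of content hashes).  ``generate`` builds random
registries and regimen sets with planted match/mismatch ground truth so the
whole pipeline can be verified end to end without the engine in the loop.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass
from importlib import resources

from .domain import (
    DomainError,
    DoseSpec,
    DrugPackage,
    DurationSpec,
    Formulation,
    Regimen,
)
from .registry import (
    FilterConfig,
    annotate_reimbursement,
    expand_and_merge,
    filter_registry,
    load_regimens,
    parse_registry,
    parse_reimbursement,
)

_DATA_FILES = ("packages.csv", "regimens.yaml", "reimbursement.csv", "expected_cells.csv")


class FixtureError(RuntimeError):
    """The packaged dataset is missing or corrupted."""


class GenerationError(ValueError):
    """The synthetic-data specification cannot be satisfied."""


def _data_text(name: str) -> str:
    text = (resources.files("packfit") / "data" / name).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n")


def _manifest() -> dict:
    return json.loads(_data_text("manifest.json"))


def verify_fixture() -> None:
    """Raise :class:`FixtureError` if any data file fails its checksum."""
    try:
        manifest = _manifest()
    except (FileNotFoundError, json.JSONDecodeError) as exc:
        raise FixtureError(f"fixture manifest unreadable: {exc}") from exc
    for name in _DATA_FILES:
        digest = hashlib.sha256(_data_text(name).encode("utf-8")).hexdigest()
        if manifest.get(name) != digest:
            raise FixtureError(f"fixture file {name!r} fails its checksum")


def paper_fixture() -> tuple:
    """Load the packaged dataset: (packages, regimens, reimbursement table).

    The registry file is run through the standard ingest pipeline (with the
    default filter configuration and no package-size cap, which the printed
    tables require), then annotated with reimbursement flags.
    """
    verify_fixture()
    parsed = parse_registry(_data_text("packages.csv"))
    if not parsed.ok:
        raise FixtureError(f"fixture registry has malformed rows: {parsed.errors}")
    config = FilterConfig()
    kept, _log = filter_registry(parsed.entries, config)
    packages = expand_and_merge(kept, config)
    table = parse_reimbursement(_data_text("reimbursement.csv"))
    packages = annotate_reimbursement(packages, table)
    regimens = load_regimens(_data_text("regimens.yaml"))
    return packages, regimens, table


#: substances whose recommendations come from product labels only
SMPC_ONLY_SUBSTANCES = (
    "cefpodoxime",
    "doxycycline",
    "flucloxacillin",
    "linezolid",
    "moxifloxacin",
    "nitroxoline",
    "telithromycin",
)


def expected_cells() -> list:
    """Published per-cell expectations keyed by (substance, package label,
    regimen id).  ``expect`` is 'fit' or 'na'; numeric fields are None when
    the source does not print them."""
    import csv
    import io

    verify_fixture()
    out = []
    for row in csv.DictReader(io.StringIO(_data_text("expected_cells.csv"))):
        out.append(
            {
                "substance": row["substance"],
                "package_label": row["package_label"],
                "regimen_id": row["regimen_id"],
                "expect": row["expect"],
                "min_packages": int(row["min_packages"]) if row["min_packages"] else None,
                "extra_units": float(row["extra_units"]) if row["extra_units"] else None,
                "chosen_days": int(row["chosen_days"]) if row["chosen_days"] else None,
            }
        )
    return out


# ---------------------------------------------------------------------------
# synthetic generation with planted ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_substances: int = 20
    strengths: tuple = (100.0, 125.0, 250.0, 500.0, 1000.0)
    size_range: tuple = (1, 40)
    divisibility_prob: float = 0.5
    match_fraction: float = 0.5
    duration_range_prob: float = 0.3
    dose_range_prob: float = 0.3
    max_days: int = 28

    def __post_init__(self) -> None:
        for name in ("divisibility_prob", "match_fraction", "duration_range_prob", "dose_range_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {p}")
        if self.n_substances < 1:
            raise GenerationError("n_substances must be >= 1")
        if not self.strengths or any(s <= 0 for s in self.strengths):
            raise GenerationError("strengths must be positive")
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise GenerationError("size_range must satisfy 1 <= lo <= hi")
        if self.max_days < 2:
            raise GenerationError("max_days must be >= 2")


def _divisors(n: int, lo: int, hi: int) -> list:
    return [d for d in range(lo, hi + 1) if n % d == 0]


def generate(spec: SyntheticSpec) -> tuple:
    """Generate (packages, regimens, truth_table) reproducibly from a seed.

    One package and one regimen are planted per substance.  For a planted
    match the package size divides the course unit count, so zero leftover
    is certain; for a planted mismatch the size is rejection-sampled so
    that *no* admissible (dose, duration) combination fills whole packages
    exactly.  Expected matched status is therefore known without running
    the fit engine.
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.size_range
    packages, regimens, truth = [], [], []
    for i in range(spec.n_substances):
        substance = f"drug{i:03d}"
        strength = rng.choice(spec.strengths)
        divisible = rng.random() < spec.divisibility_prob
        form = "tablet" if divisible else rng.choice(("capsule", "tablet"))
        formulation = Formulation(
            substance=substance,
            form=form,
            strength_value=strength,
            strength_unit="mg",
            divisible=divisible,
        )
        # admissible per-dose half-unit counts for this formulation
        half_choices = [2, 4, 6] + ([1, 3] if divisible else [])
        k = rng.choice(half_choices)
        doses_per_day = rng.randint(1, 3)
        if rng.random() < spec.duration_range_prob:
            d0 = rng.randint(1, spec.max_days - 1)
            d1 = rng.randint(d0 + 1, spec.max_days)
        else:
            d0 = d1 = rng.randint(1, spec.max_days)
        want_match = rng.random() < spec.match_fraction
        if want_match and (k * doses_per_day) % 2 != 0 and all(
            d % 2 != 0 for d in range(d0, d1 + 1)
        ):
            k *= 2  # every course would be a half-unit total; no size can match
        dose_ks = [k]
        if rng.random() < spec.dose_range_prob:
            dose_ks.append(2 * k)
        dose_options = [dk * strength / 2.0 for dk in dose_ks]
        combo_list = [
            (dk, days, dk * doses_per_day * days)
            for dk in dose_ks
            for days in range(d0, d1 + 1)
        ]

        if want_match:
            # pick a size dividing some whole-unit course exactly
            feasible = []
            for dk, days, half_course in combo_list:
                if half_course % 2 == 0:
                    feasible.extend(
                        (s, dk, days) for s in _divisors(half_course // 2, lo, hi)
                    )
            if not feasible:
                raise GenerationError(
                    f"no package size in {spec.size_range} can match {substance}"
                )
            size, wk, wdays = rng.choice(sorted(feasible))
            witness = {"dose": wk * strength / 2.0, "days": wdays,
                       "packages": (wk * doses_per_day * wdays) // (2 * size)}
        else:
            sizes = [
                s
                for s in range(lo, hi + 1)
                if all(half_course % (2 * s) != 0 for _, _, half_course in combo_list)
            ]
            if not sizes:
                raise GenerationError(
                    f"every package size in {spec.size_range} matches {substance}; "
                    "cannot plant a mismatch"
                )
            size = rng.choice(sizes)
            witness = None
        package = DrugPackage(formulation=formulation, units_per_package=size)
        regimen = Regimen(
            id=f"syn-{i:03d}",
            source="ISKRA",
            indication="other",
            substance=substance,
            dose=DoseSpec(options=tuple(sorted(dose_options)), unit="mg"),
            doses_per_day=doses_per_day,
            duration=DurationSpec(min_days=d0, max_days=d1),
        )
        packages.append(package)
        regimens.append(regimen)
        truth.append(
            {
                "package_id": f"{substance}|{package.package_label}",
                "regimen_id": regimen.id,
                "expected_matched": want_match,
                "witness": witness,
            }
        )
    return packages, regimens, truth
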