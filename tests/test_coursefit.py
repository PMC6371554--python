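import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from packfit.coursefit import (
    FitPolicy,
    applicability,
    brute_force_oracle,
    course_units,
    fit_course,
    fit_fixed,
)
from packfit.domain import (
    DomainError,
    DoseSpec,
    DrugPackage,
    DurationSpec,
    Formulation,
    Regimen,
)


def make_package(substance="cefuroxime", strength=500.0, size=10, divisible=False,
                 unit="mg", variant=""):
    return DrugPackage(
        formulation=Formulation(
            substance=substance,
            form="tablet" if divisible else "capsule",
            strength_value=strength,
            strength_unit=unit,
            divisible=divisible,
            variant=variant,
        ),
        units_per_package=size,
    )


def make_regimen(substance="cefuroxime", doses=(500.0,), unit="mg", per_day=2,
                 min_days=10, max_days=None, variant_required=""):
    return Regimen(
        id="r",
        source="ISKRA",
        indication="uti",
        substance=substance,
        dose=DoseSpec(options=tuple(doses), unit=unit),
        doses_per_day=per_day,
        duration=DurationSpec(min_days=min_days, max_days=max_days or min_days),
        variant_required=variant_required,
    )


class TestApplicability:
    def test_substance_mismatch(self):
        ok, reason = applicability(make_package(), make_regimen(substance="amoxicillin"))
        assert (ok, reason) == (False, "substance_not_named")

    def test_unit_mismatch(self):
        pack = make_package(
            substance="phenoxymethylpenicillin", strength=1000000, unit="IU",
            divisible=True, size=30,
        )
        reg = make_regimen(
            substance="penicillin V", doses=(250.0,), unit="mg", per_day=4
        )
        assert applicability(pack, reg) == (False, "unit_mismatch")

    def test_dose_not_constructible(self):
        pack = make_package(substance="azithromycin", strength=1000, size=1)
        reg = make_regimen(substance="azithromycin", doses=(500.0,), per_day=1, min_days=3)
        assert applicability(pack, reg) == (False, "dose_not_constructible")

    def test_variant_requirement(self):
        pack = make_package(substance="ciprofloxacin", strength=500)
        reg = make_regimen(
            substance="ciprofloxacin", doses=(1000.0,), per_day=1, min_days=7,
            variant_required="extended release",
        )
        assert applicability(pack, reg) == (False, "formulation_mismatch")

    def test_exact_match_applicable(self):
        assert applicability(make_package(), make_regimen()) == (True, "none")


class TestCourseUnits:
    def test_whole_units(self):
        f = make_package().formulation
        assert course_units(500, 2, 10, f) == 20

    def test_half_units(self):
        f = make_package(strength=500, divisible=True).formulation
        assert course_units(750, 1, 5, f) == 7.5

    def test_zero_days_rejected(self):
        with pytest.raises(DomainError):
            course_units(500, 2, 0, make_package().formulation)

    def test_unconstructible_dose_rejected(self):
        with pytest.raises(DomainError):
            course_units(250, 2, 10, make_package(strength=500).formulation)


class TestFitFixed:
    def test_exact_fill(self):
        pack = make_package(substance="amoxicillin-clavulanate", strength=1000, size=14)
        assert fit_fixed(pack, 1000, 2, 7) == (1, 0)

    def test_penicillin_iu(self):
        pack = make_package(
            substance="phenoxymethylpenicillin", strength=1000000, unit="IU",
            divisible=True, size=30,
        )
        assert fit_fixed(pack, 1500000, 3, 10) == (2, 15)

    def test_clindamycin_multi_unit_dose(self):
        pack = make_package(substance="clindamycin", strength=150, size=16)
        assert fit_fixed(pack, 300, 3, 10) == (4, 4)

    def test_course_equals_package(self):
        pack = make_package(size=10)
        assert fit_fixed(pack, 500, 2, 5) == (1, 0)


class TestFitCourse:
    def test_flexible_duration_picks_least_extra(self):
        pack = make_package(substance="amoxicillin-clavulanate", strength=1000, size=16)
        reg = make_regimen(
            substance="co-amoxiclav", doses=(1000.0,), per_day=2, min_days=10, max_days=14
        )
        fit = fit_course(pack, reg)
        assert (fit.min_packages, fit.extra_units, fit.chosen_days) == (2, 4, 14)

    def test_flexible_duration_prefers_fewer_packages(self):
        pack = make_package(substance="amoxicillin-clavulanate", strength=1000, size=21)
        reg = make_regimen(
            substance="co-amoxiclav", doses=(1000.0,), per_day=2, min_days=10, max_days=14
        )
        fit = fit_course(pack, reg)
        assert (fit.min_packages, fit.extra_units, fit.chosen_days) == (1, 1, 10)

    def test_dose_range_picks_least_extra(self):
        pack = make_package(substance="clarithromycin", strength=250, size=14)
        reg = make_regimen(
            substance="clarithromycin", doses=(250.0, 500.0), per_day=2, min_days=5
        )
        fit = fit_course(pack, reg)
        assert (fit.chosen_dose, fit.min_packages, fit.extra_units) == (250.0, 1, 4)

    def test_inapplicable_has_empty_numbers(self):
        fit = fit_course(make_package(), make_regimen(substance="amoxicillin"))
        assert not fit.applicable
        assert fit.min_packages is None and fit.extra_units is None
        assert fit.units_per_course is None and not fit.matched

    def test_longest_tiebreak_policy(self):
        # 1000 mg for 5 days and 500 mg for 10 days both take exactly one
        # 10-unit pack; only the duration tiebreak separates them
        pack = make_package(size=10)
        reg = make_regimen(doses=(500.0, 1000.0), per_day=1, min_days=5, max_days=10)
        shortest = fit_course(pack, reg, FitPolicy(duration_tiebreak="shortest"))
        longest = fit_course(pack, reg, FitPolicy(duration_tiebreak="longest"))
        assert shortest.matched and longest.matched
        assert shortest.min_packages == longest.min_packages == 1
        assert (shortest.chosen_days, shortest.chosen_dose) == (5, 1000.0)
        assert (longest.chosen_days, longest.chosen_dose) == (10, 500.0)

    def test_adherence_fixed(self):
        with pytest.raises(DomainError):
            FitPolicy(adherence=0.8)


# --- property tests against the brute-force oracle -------------------------

packages = st.builds(
    make_package,
    strength=st.sampled_from([100.0, 125.0, 250.0, 500.0, 1000.0]),
    size=st.integers(min_value=1, max_value=40),
    divisible=st.booleans(),
)


@st.composite
def regimens(draw):
    strength = draw(st.sampled_from([100.0, 125.0, 250.0, 500.0, 1000.0]))
    ks = draw(
        st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=2, unique=True)
    )
    doses = tuple(sorted(k * strength / 2.0 for k in ks))
    min_days = draw(st.integers(min_value=1, max_value=28))
    max_days = draw(st.integers(min_value=min_days, max_value=min(min_days + 8, 30)))
    return make_regimen(
        doses=doses,
        per_day=draw(st.integers(min_value=1, max_value=4)),
        min_days=min_days,
        max_days=max_days,
    )


@settings(max_examples=300, deadline=None)
@given(package=packages, regimen=regimens())
def test_fit_course_equals_oracle(package, regimen):
    fit = fit_course(package, regimen)
    oracle = brute_force_oracle(package, regimen)
    assert fit == oracle


@settings(max_examples=300, deadline=None)
@given(package=packages, regimen=regimens())
def test_fit_invariants(package, regimen):
    fit = fit_course(package, regimen)
    if not fit.applicable:
        return
    size = package.units_per_package
    assert 0 <= fit.extra_units < size
    assert fit.extra_units == fit.min_packages * size - fit.units_per_course
    assert fit.matched == (fit.extra_units == 0)
    # min_packages is the unique smallest feasible package count
    assert fit.min_packages * size >= fit.units_per_course
    assert (fit.min_packages - 1) * size < fit.units_per_course


@settings(max_examples=150, deadline=None)
@given(package=packages, regimen=regimens())
def test_widening_duration_never_increases_min_extra(package, regimen):
    narrow = fit_course(package, regimen)
    wide = fit_course(
        package,
        Regimen(
            id=regimen.id, source=regimen.source, indication=regimen.indication,
            substance=regimen.substance, dose=regimen.dose,
            doses_per_day=regimen.doses_per_day,
            duration=DurationSpec(
                regimen.duration.min_days, regimen.duration.max_days + 3
            ),
        ),
    )
    if narrow.applicable:
        assert wide.extra_units <= narrow.extra_units


@settings(max_examples=150, deadline=None)
@given(package=packages, regimen=regimens())
def test_chosen_single_dose_reproduces_fit(package, regimen):
    fit = fit_course(package, regimen)
    if not fit.applicable:
        return
    pinned = Regimen(
        id=regimen.id, source=regimen.source, indication=regimen.indication,
        substance=regimen.substance,
        dose=DoseSpec(options=(fit.chosen_dose,), unit=regimen.dose.unit),
        doses_per_day=regimen.doses_per_day,
        duration=regimen.duration,
    )
    assert fit_course(package, pinned) == fit


def test_oracle_with_unit_packs():
    pack = make_package(size=1)
    reg = make_regimen(per_day=2, min_days=10)
    oracle = brute_force_oracle(pack, reg)
    assert oracle.min_packages == 20 and oracle.extra_units == 0


def test_oracle_cefuroxime_28_days():
    pack = make_package(size=8)
    reg = make_regimen(per_day=2, min_days=28)
    oracle = brute_force_oracle(pack, reg)
    assert (oracle.min_packages, oracle.extra_units) == (7, 0)
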