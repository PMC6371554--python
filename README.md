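# packfit

Audit of antibiotic package sizes against guideline treatment regimens.

Given a drug-package registry (one row per marketed package: substance,
ATC code, form, strength, units per package, divisibility, reimbursement)
and a set of guideline regimens (dose or dose range, doses per day, fixed
or flexible duration), `packfit` computes for every applicable
(package, regimen) pair the minimal number of packages needed to complete
the course at 100% adherence and the leftover units, classifies each pair
as matched (zero leftover) or mismatched, and aggregates the counts by
guideline source, indication and reimbursement stratum.

Key modeling rules:

- doses are built from whole units, or exact half-units for divisible
  (scored) tablets; leftovers are reported in original-formulation units,
  so half-unit leftovers like 0.5 are exact, never rounded;
- no mg/IU conversion exists: a regimen denominated in mg is inapplicable
  to an IU-denominated package;
- for dose ranges and flexible duration intervals, the (dose, duration)
  combination leaving the fewest extra units wins, with ties broken by
  fewer packages, then shorter duration, then smaller dose;
- all half-unit arithmetic runs on scaled integers, so `extra_units == 0`
  is an exact test.

A complete reference dataset (83 packages, 55 regimens, reimbursement
flags and the per-cell expected outcomes) ships inside the package and is
loaded with `packfit.paper_fixture()` / `packfit.expected_cells()`.
A synthetic generator (`packfit.generate`) plants match/mismatch ground
truth by construction so the whole pipeline can be verified independently
of the fit engine.

## Command-line interface

```
packfit audit    --fixture --out out/           # combo CSV + summary JSON
packfit audit    --registry reg.csv --regimens regs.yaml \
                 --reimbursement reimb.csv --out out/
packfit tables   --fixture                      # plain-text accordance tables
packfit simulate --seed 1 --n-substances 30 --out sim/
packfit fixture  --out dump/                    # dump the packaged dataset
```

Exit codes: `0` success, `2` unreadable input, `3` schema/format violation,
`4` infeasible simulation spec. Logs go to stderr, data to files/stdout.

Registry CSV columns: `trade_name, atc_code, substance, form,
strength_value, strength_unit, divisible, package_sizes` (semicolon
separated), `marketing_status, dose_prespecified, paediatric`.
Reimbursement CSV columns: `substance, strength_value, strength_unit,
units_per_package, status` (`current` or `former`).
Regimen YAML records: `id, source, indication, substance, doses, unit,
doses_per_day, min_days, max_days` plus optional `note` /
`variant_required`.

## Library quick start

```python
from packfit import audit, paper_fixture, summarize, national_accordance

packages, regimens, _ = paper_fixture()
rows = audit(packages, regimens)
summarize(rows, source="ISKRA", indication="sore_throat")   # 7 matched / 16 mismatched
national_accordance(rows)                                   # (30, 104, 18, 53)
```

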