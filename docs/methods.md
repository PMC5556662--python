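# Methods

## Identification model

Claims are consumed on the calendar-quarter grid: German outpatient
diagnoses are only quarter-resolved, so all window arithmetic uses the
linear quarter index `4·year + (quarter − 1)`.  Dated events map onto the
grid as follows: inpatient stays by **discharge date** (the main-discharge
diagnosis reflects the reason for hospitalisation), procedures and deaths
by their own dates.

Diagnosis qualification differs by context:

| context      | outpatient certainty | inpatient type            |
|--------------|----------------------|---------------------------|
| index        | G                    | main discharge            |
| lookback     | G, Z                 | main discharge, ancillary |
| confirmation | G, Z                 | main discharge, ancillary |

V (suspected) and A (excluded) markers never qualify anywhere.

For each cohort member and site, only the **earliest** qualifying 2013
quarter is evaluated as the index: any later 2013 index would necessarily
fail its lookback against the earlier qualifying diagnosis, since
index-qualifying diagnoses are a subset of lookback-qualifying ones.
Windows (inclusive, in quarters): lookback `[index − 4L, index − 1]`;
second-diagnosis confirmation `[index + 1, index + C]` — a same-quarter
record never confirms, because at quarter resolution it cannot be
distinguished from the index record itself; death and surgery confirmation
`[index, index + C]` — a person dying or operated in the index quarter
cannot produce a later second diagnosis, and excluding them would
systematically drop fulminant cases.  In the surgery-required variants the
surgery is read as necessary *and* sufficient; for colorectal cancer,
endoscopy or colorectal surgery each qualifies.  Prostate cancer has no
surgical confirmatory class, so the `-su` variants are undefined for it
and are skipped (or raise, when requested explicitly).

A person can contribute one case per site (breast+colorectal for women,
prostate+colorectal for men) but never two cases within one site.

## Cohort rule

Eligibility on the reference date (2013-01-01) requires the window
`[reference − required_years, reference]` to be covered by insurance
spells such that every uncovered run of days is ≤ 28 days, including runs
at the window edges, and the reference date itself is covered.  Gap length
is the count of wholly uncovered calendar days between covered days — the
literal reading of "gaps of more than 28 days break continuity".
Exclusions are attributed first-failing-rule in the fixed order
continuity → missing sex → missing birth year → missing/invalid state →
foreign residence, so the tally is deterministic and partitions the
excluded persons.  Eligibility is assessed only on the pre-reference
window; disenrollment during 2013–2014 does not remove a person from the
denominator.  The sensitivity-analysis regimes re-derive the cohort with
`required_years = 1` and with `required_years = L` per lookback length.

## Incidence estimation

CCI = 10⁵ · cases / persons on person-count denominators (no person-time —
the design is cumulative incidence over one calendar year).  ACI uses
direct standardisation with the 1976 European Standard Population in its
18-band form (0–4, 5–9, …, 80–84, 85+; weights 8000, 7000 ×10, 6000, 5000,
4000, 3000, 2000, 1000, 1000 per 100,000 — asserted to sum to 100,000 at
load time).  Age is `2013 − birth_year`, since claims carry only the birth
year; this can differ by up to one year from age at diagnosis, a small
known discrepancy relative to registry conventions.  Sex-specific sites
use sex-specific denominators; colorectal is reported overall and by sex.
All arithmetic is done unrounded; reporting rounds half-away-from-zero to
one decimal only at the display layer.  Empty age bands contribute zero to
the weighted sum (with a warning); a band with more cases than persons is
a data error.

## Synthetic-claims generator

The generator's purpose is to reproduce the *structural* features that the
algorithm grid is designed around, with ground-truth labels per person ×
site (`INCIDENT_2013`, `INCIDENT_OTHER_YEAR`, `PREVALENT_AT_START`,
`RECURRENT`, `SUSPECTED_ONLY`, `NONE`) so that sensitivity and PPV become
computable.  Each person owns a private random stream seeded by
`SeedSequence([seed, person_index])`; output is bit-identical across runs
and independent of iteration order.

Mechanisms and defaults (all configurable, YAML-loadable; see
`examples/default_sim.yaml`):

- **Demographics**: 55% women; birth years 1919–2008 in 5-year bands
  shaped like an insured adult population (mean age ≈ 51 in 2013); federal
  states at population shares; small rates of missing sex (2·10⁻⁴),
  missing birth year (10⁻³), missing state (4·10⁻³) and foreign residence
  (3·10⁻³) so the exclusion tally is exercised.
- **Enrollment**: 85% insured over the whole 2006–2014 span, the rest
  entering uniformly before 2013; 8% have one coverage gap with geometric
  length (mean 30 days), so roughly half of the gaps break the 28-day
  rule.
- **Disease**: per-site stepwise per-quarter onset hazards by age (sized
  to give plausible German incidence magnitudes: breast ≈ 0.25%/year for
  women 50+, prostate ≈ 0.24%/year for men 50+, colorectal ≈ 0.1%/year
  overall), prevalent-at-start fractions (1.5% / 1.2% / 0.6%), recurrence
  (12–15% after a geometric latency, mean 8–10 quarters), per-quarter case
  fatality (higher for colorectal, 2.8%, than breast/prostate — the
  mechanism behind death-confirmation mattering most for colorectal
  cancer), and background Gompertz mortality.
- **Coding**: onset quarter coded with probability 0.95 (35% as inpatient
  main discharge), per-quarter G coding 0.8 during four treatment
  quarters, then Z "status post" surveillance coding; prevalent cases are
  coded only **sporadically** (12% per quarter, half G half Z) — this is
  what lets short lookbacks admit them as false positives while long
  lookbacks screen them out; a watchful-waiting fraction of prostate cases
  (25%) codes at 0.35× the normal rate; disease-free persons receive a
  suspected-only V diagnosis with probability 0.01, chosen so that the
  share of unconfirmed outpatient cancer diagnoses lands in the 16–32%
  range reported for real German claims; a small stray-code rate (10⁻³
  per quarter) models outright coding errors.
- **Surgery**: 75% of breast and 85% of colorectal onsets receive a
  qualifying procedure after a short geometric delay; recurrences less
  often (30–35%); prostate never (no surgical confirmatory class).

Events are clipped to insured, pre-death quarters.  Death dates are
clamped to not precede the first insurance spell (a rare corner of the
sampling order).  Ground-truth label precedence: a 2013 onset is always
`INCIDENT_2013` (the label is an iff with the onset year); otherwise a
case with a recurrence event is `RECURRENT`; otherwise pre-2006 onsets are
`PREVALENT_AT_START` and in-span onsets `INCIDENT_OTHER_YEAR`;
`SUSPECTED_ONLY` requires an actually emitted V record.

**What the simulator does not model** — and hence what passing tests do
not establish about real data: realistic German age-pyramid and regional
calibration, multi-episode insurance biographies, tumour stage and its
effect on coding intensity, second primaries within a site, cost/billing
fields, and real OPS/EBM procedure codes (procedures carry abstract
classes; a mapping hook would be needed for real extracts).  Validation
metrics on synthetic data demonstrate that the *implementation* orders the
algorithms correctly, not that any particular sensitivity/PPV value holds
in real claims.

A registry-style benchmark table is derived directly from ground-truth
2013 onsets over **all** valid persons (the registry sees the population,
not the insured cohort), standardised with the same ESP 1976 weights.

## Numerical and design choices

- Quarters serialise as `YYYYQn`, dates as ISO-8601; all five claims
  tables are UTF-8 CSV with header rows, and a write→read→write round
  trip is byte-identical.
- ICD matching is on the 3-character category, case- and dot-insensitive.
- The reader drops invariant-violating rows with per-row diagnostics
  rather than failing the whole file; a missing column is a schema error.
- The identification engine indexes events per person once per site and
  evaluates each algorithm with binary searches; a brute-force oracle
  (plain loops over persons × quarters × records, kept in the test suite)
  checks equivalence on hundreds of random small populations.
- Problem sizes: the default simulation scenario uses 50,000 persons
  (≈ 10 s end to end); the shared test fixture uses 12,000; oracle
  equivalence uses 500 random 12-person populations in the test suite and
  100 in the acceptance script.

## Known limitations

- ACI magnitudes from the simulator depend on its stylised age structure
  and are not calibrated to reproduce published German rates; the package
  reproduces published *derived* quantities (CCI from printed counts,
  percent differences) exactly, but absolute ACI values on synthetic data
  are scenario properties.
- With ~50–130 true incident cases per site at the default scale, the
  sensitivity loss from longer lookbacks (driven by rare stray prior
  codes) is often zero; the lookback's main measurable effect is the
  removal of false positives (PPV).
- Whether the original study admitted a same-quarter inpatient record as
  confirmation of an outpatient index, or counted deaths strictly after
  the index quarter, is not stated in its text; the conventions above were
  fixed once and documented.
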