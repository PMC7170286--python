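# Methods

## The plan model and the sidecar

The engine consumes a vendor-neutral in-memory plan context assembled from
standard DICOM-RT objects plus one YAML sidecar.  The sidecar exists
because several quantities an initial chart check needs live only in the
treatment-planning-system database, not in DICOM exports: course name and
intent, plan approval status, DRR presence and overlay state, calculation
model and leaf-motion-calculator names, imager positions for setup fields,
reference points and verification-plan linkage.  Which fields a given TPS
exposes through which channel varies by vendor and version, so the schema
(`docs/sidecar.md`) is deliberately a superset; it is documented as this
package's interface, not as a faithful copy of any one database layout.

Conventions: positions in mm in the DICOM patient coordinate system,
angles IEC 61217 normalised to [0, 360), doses in Gy, metersets in MU.
Cumulative meterset weights are renormalised to [0, 1] by the final
cumulative weight.  The loader hard-rejects only *structural* defects
(non-monotone cumulative weights, MLC bank A behind bank B, out-of-range
angles) — anything a downstream checker is supposed to find (a 3-control-
point static beam, a missing tolerance-table label) must load, or the
checker could never report it.  A sidecar field that is absent stays
"unknown", and every checker that depends on it flags with an
"insufficient data" message: a checker never certifies what it cannot see.

## The check engine

A run configuration lists enabled checkers in display order plus
per-checker parameters; omitted parameters fall back to registry defaults
and are noted.  Checkers are mutually independent: results for any
sub-profile equal the restriction of the full profile's results, and an
exception inside one checker yields a FLAG result carrying the diagnostic
for that checker only (a QA tool must fail safe, and a crashed check must
surface as "needs attention", never as silence).  Four compliance states
are modelled — pass, flag, report, manual — with `manual` supported by the
engine but unused in the shipped profile.  Tolerance comparisons use `<=`
at the boundary throughout: a value exactly at tolerance passes.

Two checker rules deserve note because the field uses the terms loosely:

* **Dynamic-MLC deliverability** is defined here as two screens: every
  in-field leaf pair must be open at least the minimum dynamic gap
  (default 0.5 mm; a pair closed to within 0.1 mm *and* parked behind a
  jaw is exempt), and the leaf speed required between adjacent control
  points, `|Δposition| · dose_rate / (ΔMU · 60)` mm/s, must not exceed
  the machine maximum (default 25 mm/s).  These are the two standard
  mechanical failure modes of sliding-window and arc deliveries; both
  limits are configuration.
* **Tolerance tables** can only be partially automated: a label on the
  forbidden list (e.g. `TEST`) can never be clinical and flags outright,
  but any clinically plausible label is *reported* for the reviewer,
  because the correct table depends on the treatment site.
* **"Unusual warnings"** has no crisp definition; it is implemented as a
  configurable pattern list over the plan's recorded calculation warnings.

The QA-plan row is a composite of ten sub-checks (verification plan in a
QA course; EPID naming; EPID reference-image SID; gated EPID MU/CP
comparison; gated MapCheck existence; MapCheck gantry at 0°; tolerance
tables defined; treatment time defined; EPID status; MapCheck status).
The published rule table prints the tolerance-table and treatment-time
requirements on one line; this package counts them as two sub-checks,
which is its own decomposition of the ten constituents.  Applicability
gates (the EPID comparison applies only to single-fraction IMRT/VMAT at
6X/15X; the MapCheck requirement only to single-fraction IMRT/VMAT at
6X-FFF) resolve to "not applicable", which counts as a pass so that the
flag count stays meaningful.

All shipped thresholds — naming regexes, machine/energy dose-rate tables,
couch windows, grid default of 2.5 mm, reference-point limit multiplier
1.07, MU tolerance 0.1 — are illustrative policy, not published values,
and are expected to be replaced per institution.

## Audit statistics

Issues recorded by human plan checkers in two periods (before and after
the tool entered clinical use) are classified into a fixed 17-category
taxonomy, 9 categories unrelated and 8 related to the automated checks.
Percentages are of the period's grand total and follow the printed
conventions: half-up rounding, one decimal for categories, two for
subtotals.

**Fisher's exact test.** The 2×2 table is period × {unrelated, related}.
The two-sided p-value uses the minimum-likelihood convention — the sum of
hypergeometric probabilities of all tables with the observed margins that
are at most as probable as the observed table — which is the dominant
convention in standard statistical software.  The implementation works on
exact integers (binomial coefficients), so there is no cancellation error
for any margins this package will meet; a degenerate margin returns
p = 1.0 with a warning.  On the bundled dataset, (150, 50 | 114, 13)
gives p = 8.83 × 10⁻⁴.

**Mann–Whitney U.** Midranks for ties; the normal deviate uses the
tie-corrected variance `(n₁n₂/12)[(n+1) − Σ(t³−t)/(n(n−1))]` with a 0.5
continuity correction toward the mean.  The continuity correction is a
convention, not a property of the data, so it is a switch
(`continuity=False` disables it); raw per-check durations behind the
bundled summaries were never published, so the original z-scores cannot be
re-derived either way.  For `n₁·n₂ ≤ 400` an exact conditional permutation
p-value (two-sided as `2·min(P(U≤u), P(U≥u))`, capped at 1) is computed by
a subset-sum dynamic program over doubled midranks — exact integer counts,
no sampling — and reported alongside.  For all-tied samples the defined
result is `U = n₁n₂/2, p = 1` with a warning.

A caution from exhaustive enumeration: the normal approximation is poor
for very small samples even with tie and continuity corrections.  Over all
no-tie rank configurations the worst |p_normal − p_exact| is 0.129 at
(n₁,n₂) = (1,3), 0.088 at (2,2), 0.031 at (4,4), and only falls below
0.02 once min(n₁,n₂) ≥ 5.  Use the exact p for small samples; the package
computes it automatically.

Timing summaries report per-person and overall n/mean/median per period
and with/pre ratios computed from the unrounded summaries and rounded
half-up to two decimals; a person observed in only one period gets blank
ratios.  On the bundled summaries the overall ratios are 0.80 (means
49.4 → 39.3 min) and 0.78 (medians 45 → 35 min), a 20% mean decrease.
The bundled issue counts also imply an overall issue ratio of 127/200 =
0.635 — a 36.5% reduction in recorded issues of all sorts (many of them
outside the tool's scope, so that figure confounds the tool with
concurrent practice changes; the relatedness *proportion* is the cleaner
endpoint, which is why the Fisher test is run on proportions).

## The synthetic generator

Five templates: a 2-field conventional static plan, a 5-field
sliding-window IMRT plan, a 2-arc VMAT plan, and two single-fraction
stereotactic VMAT templates carrying an EPID (6X) or MapCheck (6X-FFF)
verification plan.  Sizes were chosen for fast iteration while remaining
clinically shaped: 40 MLC leaf pairs, 15 control points per IMRT field,
60 per arc, metersets and couch positions drawn from plausible ranges.
The contract is that every template passes every default check at every
seed; apertures and speeds are therefore generated with wide margins to
the configured limits (e.g. worst-case required leaf speed under ~17 mm/s
against the 25 mm/s limit).  Generation is byte-reproducible: fixed dates,
UIDs derived from (template, seed), and values rounded before writing.

What the plans are *not*: there is no anatomy, no computed dose, no
realistic fluence.  Passing tests therefore demonstrate that the rules
fire on the right fields with the right thresholds and tolerances — not
that the thresholds themselves are clinically optimal, which is
institution policy by design.

The defect catalog holds 31 mutations, each editing one aspect of a clean
fixture (DICOM tag or sidecar key) and mapped to the checker expected to
flag it.  Defects are constructed to be orthogonal: across the corpus the
mapped checker flags (sensitivity 1.0) and no *other* checker changes
status relative to the clean baseline.  Two couplings were designed away
explicitly: the overlay checker skips beams whose DRR is absent (that is
the DRR-created checker's finding), and marking a course non-clinical
moves the clinical-status checker to "not applicable" (still a pass)
rather than flipping it.

The audit-log simulator draws per-category issue counts as
Binomial(n_checks, rate) and per-check durations from per-person
log-normals; its defaults *are* the bundled study conditions — 187/186
checks, rates equal to the empirical category proportions, and log-normal
parameters fitted to each person's printed mean/median pair via
`μ = ln(median)`, `σ = √(2 ln(mean/median))` (log-normal because durations
are strictly positive and right-skewed).  A Monte-Carlo calibration of the
Fisher test under these defaults gives a rejection rate of ≈ 0.55 at
α = 0.001 over 300 replicates — unsurprising, since the expected table
sits almost exactly at p = 0.001 — and the regression test asserts a
conservative ≥ 0.40 over 200 seeded replicates.

## Problem sizes and numerical choices

The default test run uses seeds 0–2 for the clean contract and 50 seeds
per defect for the full detection sweep; `scripts/acceptance.py` uses 20
seeds per defect, all derived from `--seed`.  Isocenter equality uses a
0.01 mm tolerance (float-safe equality, not a clinical statement); the
dose-grid resolution is the *maximum* axis pitch (conservative: any axis
coarser than policy is a violation); weight comparisons in the QA MU/CP
sub-check use 10⁻⁴ on normalised cumulative weights.

## Known limitations

* The sidecar schema is an interface of this package, not a validated
  mirror of any TPS database.
* Bolus HU evaluation relies on an assigned-value property in the
  structure set; without one the bolus is reported "not evaluable" rather
  than guessed from CT (no image data is modelled).
* The engine reports and exits non-zero on flags; it does not block any
  workflow — enforcement is left to the surrounding process.
* Plan-quality evaluation (DVH metrics, segmentation review) and
  cross-system consistency checks (R&V, EMR, scheduling) are out of scope.
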