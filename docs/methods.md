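# Methods

This note documents the statistical procedure implemented by `cdsaqc`,
the conventions and defaults that were genuinely open choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## 1. Screening model

The unit of analysis is the (health facility, clinical sign) pair.
Individual-worker attribution is deliberately out of scope: login
sharing on shared tablets makes worker-level data unreliable, so all
statistics aggregate at facility level.

For a facility *h* and sign *s*, over the consultations where the sign
is prompted (its *eligible* set):

* `missing_frac` — share of eligible consultations without a usable
  value. "Not feasible" ticks and "estimated" weights both count as
  missing; only measured values enter any other statistic.
* `modal_frac`, `top3` — frequencies on the sign's recording grid
  (0.1 °C, 0.1 cm, 0.1 kg, 1 beat/min, 1 breath/min, 1 %). Frequencies
  are only meaningful on the grid the device records.
* `mean`, `median`, `iqr` — of measured values.
* `extreme_z_frac` — for the three growth indicators, share of raw
  z-scores strictly below −2 or above 2.

The reference for every comparison is the pooled all-facility summary
("ALL"), computed by the identical code path over the union of all
records, the facility under test included. Pooling-in the tested
facility is intentional: with 16 facilities the self-contribution
attenuates a true excess by about 1/16, which is negligible against the
band widths, and leave-one-out references would make the reference
differ per facility and complicate auditability.

### Pattern types and severity bands

| pattern | trigger statistic | applies to |
|---|---|---|
| skipper | excess `missing_frac` | MUAC, height, HR, RR, SpO₂ |
| mono-repeater | excess `modal_frac`, or IQR shrinkage | temperature, MUAC, HR, RR, SpO₂ |
| multi-repeater | excess top-3 frequency, or IQR shrinkage | temperature, MUAC, HR, RR, SpO₂ |
| wrongly evaluated | excess `extreme_z_frac` (z-indicators); implausible mean (temperature, MUAC, vitals) | z-indicators; temperature, MUAC, HR, RR, SpO₂ |

Raw weight carries no pattern at all: it has no not-feasible option
(skipping is impossible by construction), and its distribution is so
strongly age-driven that raw heaping or outlier rules would mostly
detect case-mix. Wrong evaluation of weight and height is instead
detected through the z-score indicators they feed. Temperature is
excluded from the skipper pattern even though its missingness is
tabulated: when temperature is not measured the application substitutes
a feels-hot question, so its "missing" mechanism differs in kind from
the other signs. (The summary table still reports temperature
missingness; only the classifier ignores it.)

Severity bands on frequency-type excesses default to
5–10 / 10–30 / >30 percentage points. Two reading choices deserve
record:

* **"X% more frequent than the reference"** is read as an *absolute
  percentage-point difference* of fractions. The alternative relative
  reading (ratio to the reference) is implemented behind the
  `relative_excess` switch, but the absolute reading is the default
  because the same 5/10/30 scheme is applied to statistics whose
  reference levels differ by an order of magnitude (missingness ~5%,
  SpO₂ modal frequency ~25%), and a ratio reading would make the bands
  wildly asymmetric across signs.
* **IQR shrinkage** is measured relative to the *facility's own* IQR,
  `(IQR_ref − IQR_hc)/IQR_hc`, because a shrinkage of "more than 100%"
  is impossible when normalized by the reference; under this reading
  >100% means the facility's IQR is less than half the reference.
  A facility IQR of exactly zero with a positive reference is treated
  as infinite shrinkage (severe).

Band edges: an excess *e* maps to mild for t₁ ≤ *e* < t₂, moderate for
t₂ ≤ *e* ≤ t₃ and severe strictly above t₃. Putting the upper edge in
the moderate band follows the band wording ("10–30%" moderate, ">30%"
severe) and matters in practice: on the 1-unit SpO₂ grid the IQR
shrinkage lands exactly on 100% for realistic heaping.

The frequency and IQR criteria for repeaters combine by OR, with the
final severity the maximum of the two — the two rows of the severity
definition are treated as independent sufficient conditions. When both
mono and multi frequency bands are met, mono wins only if the single
modal excess accounts for at least 60% of the top-3 excess
(`mono_dominance`); without this dominance requirement any strong
2–3-value heap would be labeled mono, because a spike of 15 points on
each of three values already pushes the modal excess through a band.
If only the IQR criterion fires, the same dominance ratio decides the
subtype.

Implausible-mean detection uses configurable plausibility ranges
(defaults: temperature 35–40.5 °C, MUAC 8–25 cm, HR 55–185 bpm,
RR 12–80 bpm, SpO₂ 88–100%). These are screening bounds on a *facility
mean*, not clinical alert thresholds for a child, and they are
config-exposed precisely because they are judgment calls.

A facility-sign cell with fewer than 20 measured values is reported as
"insufficient data" and never classified; below that size a single
consultation moves frequencies by ≥5 points, the width of the mild
band.

### Selection rule

A facility is shortlisted for in-person observation when it has flags
on at least two distinct signs and at least one flag is moderate or
severe. The rule is evaluated on distinct *signs*, so two pattern types
on one sign do not qualify alone.

## 2. Z-score engine

The LMS transform `z = ((x/M)^L − 1)/(L·S)` (with the `ln(x/M)/S`
limit at L = 0) is evaluated against a bundled table of (L, M, S) by
indicator, sex and key (age in days, or height in cm for
weight-for-height, tabulated in 0.5 cm steps); parameters are linearly
interpolated between keys. Z-scores are computed only for ages
2 months–5 years, the convention of the growth standards; outside that
window the z columns are empty. The integer display form rounds half
away from zero and clips to [−3, 3] — whether the original application
rounded or truncated is not documented, so the raw z is kept alongside
the integer to allow auditing either convention. Extreme-value
fractions always use the raw z.

The bundled reference is **synthetic**: smooth piecewise-linear medians
anchored at familiar pediatric magnitudes with constant L and S per
indicator, constructed so that median weight-for-height composed with
the median height of an age equals median weight-for-age (a median
child is median under every indicator). It is adequate because every
analysis in the package is relative to the bundled table; it must not
be used for clinical assessment against official growth standards.

## 3. Synthetic cohort generator

The generator emulates the statistical structure of multi-facility
consultation data: children aged 1 day–14 years (65% under five), sex
balanced, 40% presenting with a respiratory complaint (which gates HR,
RR and SpO₂); MUAC prompted above six months. Temperature and vitals
draw from truncated normals (temperature N(36.8, 0.5) on [35, 41] °C;
HR N(115, 22); RR N(38, 11); SpO₂ N(97.3, 1.7) capped at 100 — its
mass concentrates on 96–99, the realistic heaping substrate).
Anthropometry is drawn *coherently from the same curves that back the
z-score reference*: a shared latent growth factor links height, weight
(via weight-for-height at the child's simulated height) and MUAC, so
baseline extreme-z fractions are stable across facilities (~5% for
MUAC-for-age and weight-for-height; ~10% for weight-for-age, whose
z-variance compounds height and weight dispersion). Baseline
not-feasible rates (2–12% by sign) are plausible placeholders, not
field-calibrated values.

Behavior injection semantics:

* **skipper** — intensity adds to the missing rate (a facility at 5%
  baseline with intensity 0.35 lands at 40%).
* **mono/multi-repeater** — intensity is the probability mass *moved
  onto* the target values; internally values are replaced with
  probability `intensity/(1 − p̂)` where p̂ is the targets' existing
  mass, so the resulting excess frequency matches the intensity scale
  of the severity bands. Targets should be popular or round values —
  that is the phenomenon (habitual numbers, digit preference).
* **wrongly evaluated** — for weight/MUAC, a fraction `intensity` of
  measurements is replaced by values whose z-score magnitude is drawn
  uniformly from 2.6–4.5 (direction random), so the extreme-z excess
  equals the intensity; for temperature/vitals the intensity is a
  systematic bias in the sign's own units (the archetype is a
  miscalibrated or misused instrument shifting the facility mean).

Raw values are drawn first, behaviors applied on the raw scale, and
quantization to the recording grid happens last, so heaps land on
representable values. Everything is deterministic given (config, seed);
injection is local (untargeted facilities are bit-identical) and
monotone (at fixed seed, the targeted statistic never decreases with
intensity, because selection uses nested uniform thresholds).

What the generator does **not** emulate: seasonal and day-of-week
structure, within-facility worker heterogeneity, correlation between
complaint and vital-sign values (a child with pneumonia has a higher
RR), age-dependent vital-sign norms, and simultaneous interacting
behaviors on one sign. Passing calibration therefore shows that the
classifier detects the *statistical signatures* at the stated effect
sizes under clean conditions — not that real facilities with skill gaps
will separate this cleanly.

## 4. Calibration experiments

* **Null calibration** — 20 seeded behavior-free cohorts of
  16 facilities × 20,000 consultations; every flag is a false positive.
  Acceptance requires ≥95% of facility-sign pairs flag-free (observed:
  ~100%), and facility summaries within 0.03 of the pooled reference
  on missing and modal fractions.
* **Injection recovery** — 50 seeded cohorts of 16 × 2,000, one
  behavior each at the center of a severity band (0.075, 0.20, and
  0.45 as the representative point of the open severe band), cycling
  deterministically over pattern × sign × severity combinations.
  Acceptance requires the correct (sign, pattern type) in ≥90% of runs
  and the correct severity band in ≥80% (observed: ~92–96% for both).
  These rates are calibration properties of this implementation under
  the generator's conditions. Wrong-evaluation injections into weight
  are scored as recovered when the flag lands on weight-for-age or
  weight-for-height. The 2,000-consultation facility size mirrors a
  year of routine volume (16 facilities ≈ 32,000 consultations);
  residual misses are band-edge noise on the smallest eligible
  subgroups (respiratory-complaint vitals, ~800 records).

## 5. Observation analysis

The prospective module is purely descriptive: per-sign
performed/skipped/sufficient/insufficient tallies with per-sign
denominators, multi-select reason prevalences (denominator = records in
the category, so sums may exceed 100%), and per-method sufficiency for
respiratory rate. Percentages round half away from zero to integers,
matching the source presentation. The bundled fixture is a record-level
expansion of published marginal counts; reason co-occurrence within a
record is not reported in the source and is assigned by a deterministic
rotation, so any statistic that depends on co-occurrence (none of the
shipped ones do) would be fixture artifact. Denominators for the
sub-group signs are not printed in the source and were chosen to be
consistent with its reported percentages and the 39 + 39 method split;
they are parameters of the fixture, not published facts.

## 6. Numerical conventions

* Quantiles: linear interpolation between order statistics
  (`numpy.percentile` default); IQR = Q75 − Q25.
* Modal ties break toward the smallest value.
* Truncated normal sampling via inverse-CDF (`ndtri`), exact and
  deterministic.
* Facility-sign cells with zero eligible records yield an explicit
  empty-summary marker, never a division by zero.
* Figure output is SVG with a fixed hash salt and no embedded date, so
  identical inputs give byte-identical files.

## 7. Limitations

The pooled reference assumes most facilities measure adequately; a
system-wide failure mode (every facility heaping on the same value)
is invisible by construction. Severity bands and plausibility ranges
are screening heuristics, not estimates with sampling theory behind
them; no inferential statistics are attached to the flags, by design.
The retrospective and prospective components are not linked at the
record level. The bundled growth reference is synthetic, and the
generator's baseline rates are placeholders where field values are
unavailable — conclusions about real data require re-running the
pipeline on real consultation extracts with locally appropriate
plausibility ranges.
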