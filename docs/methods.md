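# Methods

## The audit model

The unit of analysis is one point-of-care glucose test. Its reference
value is the integer mg/dL stored in the meter and uploaded at docking;
this value is taken as correct (measurement error of the device itself
is out of scope — the audit targets the *copying* step). Each test may
have been hand-copied into up to two documentation streams: a paper log
(technicians) and the EMR vital-signs flow sheet (nurses). Three
outcomes are derived per test and source:

* **undocumented** — no entry with the same visit identification number
  (VIN), the same calendar date as the test, and a transcription
  timestamp within the matching window after the test;
* **correct** — the matched entry equals the meter value exactly;
* **transcription error** — any nonzero signed difference
  (transcribed − meter), with no tolerance band.

Per-source error rates use documented-test denominators; the joint
("both sources wrong") category is evaluated among tests documented in
both sources, whose count obeys the inclusion–exclusion identity
`n − missₚ − miss_f + miss_both`.

### Record linkage

The window rule is: same VIN, same calendar date, offset
`entry_time − test_time` in `[0, 60]` minutes. Forward-only is the
default because a transcription cannot precede the test it copies; a
symmetric window is available as a sensitivity option. A consequence of
the same-date clause is that a test at 23:30 transcribed at 00:10 the
next day counts as undocumented; this is a property of the rule itself
and is kept deliberately.

When several tests on one patient-day compete for entries, matching is
resolved as a one-to-one rectangular assignment per (VIN, date) group:
maximise the number of matched records, then minimise the total offset,
ties to the lexicographically earlier entry id. This is deterministic
and is verified against a brute-force enumeration oracle on small
instances. A simpler greedy-by-ascending-offset rule was considered and
rejected: it can strand a record that a feasible assignment would match,
which breaks count conservation against the oracle.

### Insulin evaluation

A sliding-scale protocol is an ordered list of half-open glucose bands
`[lo, hi)` mapping to subcutaneous doses in units, covering the
reportable range (default 10–600 mg/dL), non-decreasing above an
optional hold-and-notify hypoglycemia threshold. An **insulin error**
is `dose(transcribed) ≠ dose(meter)`; this subsumes "not giving insulin
when due" (a due dose read as a no-dose value gives a negative
discrepancy). Discrepancies within one band are, by construction, never
insulin errors — the protocol's band width is the audit's clinical
tolerance. Errors are counted per test, not per administration event;
a wrong value that informed several decisions still counts once.

ICU protocols are not standardised and the audited unit's scale is
configuration; the shipped default (0 U below 150; 2/4/6/8 U per
50 mg/dL band from 150; 10 U at ≥350; hold below 70) makes the
evaluation executable out of the box. Note its doses are all even, so
odd-unit discrepancies require supplying a protocol with odd doses.

### Statistics

* Shift comparison: Pearson χ² on the 2×2 errors-by-shift table with
  the Yates continuity correction on by default (`|O−E|` reduced by 0.5,
  floored at 0). Both variants are implemented from the closed form and
  cross-checked against `scipy.stats.chi2_contingency` in the tests.
* Test-count comparison (diabetic vs nondiabetic): unequal-variance
  Welch t from summary statistics with Welch–Satterthwaite df
  (fractional, also reported rounded); the pooled-variance Student
  variant is provided for sensitivity. Welch is the default because the
  group variances differ by an order of magnitude in data of this shape.
* Quartiles everywhere use linear interpolation between order
  statistics (numpy's default), oracle-tested against a sort-and-index
  implementation.
* mg/dL → mmol/L divides by 18.016 and rounds half-up to one decimal;
  signed discrepancies convert their absolute magnitude and reattach
  the sign.
* p-values are reported to two decimals in rendered tables; full
  precision is retained internally.

## Sampling design

`stratified_sample` draws `floor(fraction · stratum)` tests per shift
stratum uniformly without replacement (day = [07:00, 19:00) by default,
boundaries configurable, half-open so every instant has exactly one
shift). `expand_episodes` then closes the sample over admission
episodes: every test sharing a VIN with a sampled test is included, so
per-patient error counts are complete. Expansion is idempotent and
never removes records. The stratum of a test is the shift of its *test
time* — the workload context in which the transcription act happened.

## The synthetic study

The generator emulates the structure of a four-month single-unit audit;
its defaults are the study conditions, not tuning knobs:

| quantity | default | basis |
|---|---|---|
| episodes | 234 | cohort size |
| diabetes mix (yes/no/unknown) | 44/93/97 of 234 | cohort table |
| tests per episode | NB(mean 60, SD 126) diabetic; NB(19, 40) nondiabetic; NB(6.6, 12) unknown | per-status summaries; the unknown-status mean solves 44·60 + 93·19 + 97·m ≈ 5049 total tests |
| glucose | lognormal, median 140 mg/dL, σ=0.35, truncated to 10–600, integer | realistic ICU skew; shape not load-bearing |
| undocumented (paper/flow/joint) | 12.04% / 40.88% / 4.73% | per-source and joint rates, drawn as one coupled four-cell categorical per test |
| transcription errors (paper/flow/joint) | 2.21% / 8.11% / 1.64% | joint rate far exceeds independence (0.18%), modelled as P(flow wrong │ paper wrong) = joint/paperₑ — nurses sometimes copy the technician's wrong value (then the wrong value itself is copied with probability 0.8) |
| error magnitude | per source: uniform ±1..15 (paper) or ±1..6 (flow) slips with P(neg) 0.62/0.45, plus a digit-transposition tail (15%/10%), capped at ±115 mg/dL and kept in range | calibrated so quartile brackets and ranges resemble the reported −12..7 / −3..4 patterns and ±92 / −110..80 extremes |
| transcription delay | uniform 2–58 min; with probability 0.004 a late entry at 61–120 min (counted as undocumented by the window rule) | most entries land within the window; a small tail beyond it |
| docking latency | lognormal, median 5.5 h, σ chosen so the untruncated mean is 8 h, resampled above 60 h | reported median/mean/max ordering; truncation pulls the realised mean to ≈7.8 h |
| shift mix | 62% of tests on the day shift | via a piecewise-linear clock warp |
| post-discharge entries | 40 extra anomalous entries after discharge | injected as *additional* entries (phantom documentation), not by shifting real ones, so the configured missingness rates stay intact |

Ground truth records, per test and source: transcribed or not, the
entry id, whether an error was injected and its signed delta, and
whether the realised entry timestamp is matchable under the window rule
(`within_window`). The expected undocumented probability the recovery
tests compare against is therefore `miss + (1 − miss)·late`.

**Exact recoverability.** Two structural constraints make the injected
labels provably recoverable: same-patient tests are spaced ≥ ~2 h apart
(a patient whose drawn count needs more room gets a longer stay — the
meter-stream generator returns the adjusted episode table), and entries
are timestamped on the same calendar date as their test (clamped at
23:59:59 and at discharge). Under forward-only matching no entry is
then feasible for any record but its own, so the pipeline recovers
every label exactly; the test suite asserts this at full study size.

**What passing does not show.** Real streams have same-hour repeat
tests, date-crossing transcriptions, clock skew between systems, and
missingness correlated with workload. The exact-recovery result
validates the pipeline's bookkeeping, not its behaviour under those
ambiguities; the matcher's collision behaviour is tested separately
against the assignment oracle. The generator also makes no claim about
the true distributional forms of error magnitudes or latencies — only
ranges and quartiles were available as calibration targets.

## Numerical and degenerate-input choices

* Empty discrepancy collections return an explicit empty-summary
  sentinel rather than NaNs; an empty meter stream is a config error in
  the generator and an empty sample is a valid empty result in sampling.
* A zero marginal makes the χ² test undefined and raises; two zero
  variances make the t test degenerate and raise.
* Records lacking a dock time are counted separately, never silently
  dropped; a dock time before its test raises a data-integrity error
  naming the records.
* CSV readers collect *all* invalid rows into one error instead of
  failing on the first or dropping them.
* Seeds: one integer seed is split via `numpy.random.SeedSequence` into
  independent per-stage streams; a fixed seed reproduces the dataset
  byte-for-byte.

## Problem sizes used in the checks

The shared synthetic study used by the heavier tests and by the
acceptance script is the full default configuration (234 episodes,
≈5000–6500 tests depending on seed — the total is itself random with
SD ≈ 900 driven by the heavy-tailed diabetic counts). Oracle suites run
on deliberately small instances (≤6 records for the assignment
enumeration, ≤20 values for quartiles, all 591 integer glucose values
for the protocol scan).

## Known limitations

* VIN equality is the only identity resolution; no fuzzy matching.
* Continuous insulin-drip titration is not modelled — only discrete
  sliding-scale decisions in whole units.
* Clinical consequences of insulin errors (hypoglycemia events,
  outcomes) are out of scope.
* The cohort's length-of-stay distribution is distorted for episodes
  with very high test counts (stays are extended to hold the spacing
  guarantee), so cohort descriptives from the generator should not be
  read as calibrated.
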