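# Methods

## Measurement model

A trial is one loading of a cushion by one buttock model at one applied
mass. The physical procedure applies two conditioning loads, holds the test
load for 90 s, and records calibrated pressures at 1 Hz; a `TrialRecord`
stores the per-trial aggregate of each channel. `aggregate_samples`
collapses a per-sample series with the arithmetic mean of its last 30
samples (the recording duration after the hold is not fixed by the
procedure; 30 s of settled data is this package's default, configurable per
call).

The sensor registry is fixed: twelve surface channels at six axisymmetric
(left/right mirrored) locations, of which channels 1, 2, 7, 8, 9 and 10 lie
under the substructure's protuberances ("bony"), and three internal
channels on the substructure whose individual roles never matter because
the magnitude parameter only uses their sum. Pairs are role-homogeneous,
which is what makes single-channel outlier recovery possible.

## Parameters and pooling

Per trial, `%Bony` = (sum over bony channels) / (sum over all twelve), and
`SumInt` = sum of the three internal channels. Both are pooled across the
full battery — six trials at each of two loads, nominally n = 12 — into a
single sample with interval

    mean ± z * sd / sqrt(n),      sd with the n-1 denominator.

Pooling the loads into one sample is a design feature, not sloppiness: a
cushion whose performance shifts with load contributes that shift to the
sample SD and is penalised with a wider interval.

`ci_multiplier` (z) defaults to 1.0 — the interval form the procedure
operates with — and can be set to 1.96 or a t quantile for conventional
95% coverage. The benchmark tables' printed intervals are reproduced by
classification regardless of this choice, because the printed bounds are
used as inputs there; for fresh data the choice changes interval width and
therefore borderline behaviour, and should be fixed before testing.

## Ratio interval

The magnitude parameter is the ratio of the test cushion's mean `SumInt`
to a reference foam's, with three interval methods:

* **fieller** (default) — Fieller's construction for a ratio of
  independent normal means, using the same z. Exact under normality and
  respects positivity. When the reference mean is not significantly
  different from zero at z (g = z²·SEM_ref²/mean_ref² ≥ 1) the construction
  is unbounded; the estimate is returned with infinite bounds and flagged,
  and the classifier records a warning and assigns Comparable, since an
  unbounded interval can establish neither superiority nor inferiority.
* **delta** — first-order propagation,
  ρ·(1 ± z·sqrt(cv_test²/n_test + cv_ref²/n_ref)).
* **bootstrap** — seeded percentile interval over 2000 resamples of the
  trial-level values, taken at the two-sided normal coverage implied by z
  (for z = 1, the 15.87/84.13 percentiles).

At this procedure's noise level (CVs of a few percent, n = 12) the three
agree to within a few percent of half-width; the test suite asserts
agreement within 10% of their consensus over 100 seeded replicates. Fieller
is the default because it is the exact construction under the model's
assumptions; the other two exist as independent cross-checks.

Whether a reference battery should be cleaned the same way as a test
battery was an open choice; this package applies the identical outlier
pipeline to both (symmetric treatment).

## Classification

Redistribution uses strict inequalities (entire interval strictly below
the criterion is High, strictly above is Low, otherwise Moderate), so an
interval bound exactly on the criterion is Moderate. Magnitude uses
non-strict inequalities (interval entirely ≤ LEL is Superior, ≥ UEL is
Inferior). The asymmetry is deliberate and mirrors the criteria's
definitions (< / > for redistribution, "less/greater than or equal" for the
equivalence limits).

The overall matrix is searched highest tier first with short-circuit.
GeneralUse states only a magnitude criterion (no redistribution
requirement), as the matrix defines it. A cushion never compared against
the 2″ reference cannot be assigned GeneralUse or BelowMinimum; no
inference is made from a 3″ comparison to a 2″ one even though the 3″
standard is stricter. If the available comparisons cannot settle any tier,
the result is Indeterminate.

Borderline flagging reports every criterion whose nearest interval bound
lies within `borderline_tolerance` (default 0.02 — one printed-precision
unit above the 0.01 overshoot of the benchmark's knife-edge comparable
case). The retest suggester emits `add_trials` for any borderline flag and
`compare_vs_3in` when a cushion beats the 2″ reference on some model but
has no 3″ comparison.

## Outlier handling

Within one (cushion, model, load) condition, each surface channel's median
across the repeated trials is the reference; a datapoint is flagged when
|x − median| ≥ 0.5·median (≥, so exactly 50% deviation is flagged). The
median scope is per channel within a condition — the only scope under which
the procedure's datapoint accounting (12 channels × 6 trials × 2 loads × 2
models = 288 per cushion) is coherent — and the median of an even count is
the mean of the two central values. Internal channels are exempt: the rule
targets a surface-sensor artefact of discontinuous cushion surfaces.
Flagged values are replaced by the axisymmetric partner's value from the
same trial; if both members of a pair are flagged, the trial is excluded
from parameter computation and a warning is logged. With fewer than two
trials in a condition the median rule is meaningless and detection raises
an error.

## Synthetic-trial generator

The simulator emulates the study conditions — 6 trials × 2 loads × 2
models per battery — from designed quantities: per-model bony fraction β,
per-model internal ratio ρ against a reference preset, and a total surface
budget (default 13.2·load mmHg, i.e. a nominal 55 mmHg per sensor at
50 kg). Noise-free allocation is exact: bony channels share β·budget
equally, non-bony channels share (1−β)·budget, internal channels share
ρ·reference-mean; hence noise-free `%Bony` equals β and noise-free
`SumInt`/reference equals ρ exactly, which the tests assert.

Noise is a per-channel unit-mean lognormal factor with class-specific CV
(defaults: surface 0.05, internal 0.02). These defaults keep per-condition
`SumInt` CVs under 4% and total-surface CVs under 7% — the bench
repeatability envelope of the physical procedure — in ≥ 95% of seeded
replicates. Multiplicative noise was chosen over additive because
nonnegativity is then automatic and bench repeatability is characterised
as a CV. Optional features: `load_shift` (change in β per +10 kg) to
exercise the pooling penalty, and outlier injection (probability per
surface datapoint, default multiplier 2.0) to exercise the cleaning stage.

Reference foam presets encode the bench characterisation of the two
standards: noise-free bony fractions 0.50/0.56 (elliptical/trigonometric)
for the 3″ block and 0.52/0.64 for the 2″ block, and expected internal
sums of 210/240 mmHg (3″) versus 270/310 mmHg (2″) — the thinner block
bottoms out more, so the same cushion scores a lower ratio against it.
The internal-sum magnitudes are nominal values on the scale of
bony-prominence loading under a seated model; only their ordering and the
designed ratios against them matter to the pipeline.

What the generator does not model: per-sensor spatial structure beyond
role-class sums (the redistribution parameter only sees class sums),
sensor drift, hysteresis/creep, and contact mechanics. Tests passing on
synthetic data therefore validate the statistics and decision logic, not
the physical fidelity of any cushion model.

## Equivalence-limit derivation

`derive_equivalence_limit` averages 1.96·SEM/mean over a table of
published interface-pressure results (mean, SD, n per cushion). The source
data behind the published average of 0.153 (nine cushions, 62 subjects) is
not public, so the package bundles a synthetic stand-in table —
`data/ipm_literature_synthetic.csv`, nine records with plausible
peak-pressure means (46–70 mmHg) and cohort sizes summing to 62 —
constructed so its average reproduces 0.153. It demonstrates and tests the
derivation; it is not the original dataset.

## Problem sizes and determinism

Every stochastic check is seeded and uses the study's native scale: n = 12
trials per parameter, 100-seed replication for the simulation studies and
method-agreement checks, 200 replicates for the repeatability envelope,
10⁴ random intervals for the trichotomy properties. The full test suite
runs in a few seconds; the acceptance script in about one second. Report
JSON is deterministic given inputs, configuration and seed (the seed only
matters for the bootstrap ratio method).

## Known limitations

* The simulator's equal within-class allocation makes per-channel medians
  very clean; real cushions show per-sensor spread, which would make the
  outlier median reference noisier than simulated.
* Fieller and delta intervals assume approximately normal trial means;
  with n = 12 and few-percent CVs this is comfortable, but heavy-tailed
  sensor noise would push the methods apart (the bootstrap is the fallback).
* The classification of a cushion Comparable vs 3″ but unmeasured vs 2″
  stops at Level3-or-above tiers; no General Use inference is attempted.
* A formal equivalence test (TOST p-values) is deliberately not provided;
  the procedure adopts the equivalence-band geometry, not its inferential
  machinery.
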