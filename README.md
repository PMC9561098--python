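# cushionbench

Bench-test evaluation and classification of wheelchair cushion
pressure-management performance.

## The problem

Wheelchair cushions are prescribed, among other reasons, to protect tissue
at risk of pressure ulcers, yet the reimbursement categories they are sold
under are based on an immersion test that says little about how a cushion
actually manages pressure. A more valid procedure loads an instrumented
compliant buttock model — an elastomer shell over a rigid substructure that
abstracts the ischial tuberosities, trochanters and coccyx — onto the
cushion and measures calibrated pressures (mmHg) at 12 surface sensors and
3 internal sensors. Two model shapes are used (an *elliptical* profile for
typical tissue bulk, a peaked *trigonometric* profile for atrophied
buttocks), each at two applied loads (50 and 60 kg for 41–43 cm wide
cushions), six repeated trials per load.

`cushionbench` implements the complete analysis behind that procedure, plus
a seeded synthetic-trial simulator that stands in for the physical rig, so
the whole pipeline can be exercised, tested, and studied without hardware.

## The statistics

Two performance parameters are computed per trial:

* **Pressure redistribution** — the fraction of total surface pressure
  under the bony sensor set,

  `%Bony = (p1 + p2 + p7 + p8 + p9 + p10) / Σ(p1..p12)`,

  classified **High / Moderate / Low** by whether the pooled confidence
  interval falls below, includes, or lies above a criterion (0.50
  elliptical, 0.55 trigonometric).

* **Pressure magnitude** — the sum of the three internal sensors
  (`SumInt`), analysed as the ratio ρ of the test-cushion mean to a flat
  HR45 reference-foam mean, with an interval from Fieller's construction
  (delta-method and seeded bootstrap available as cross-checks). The ratio
  interval is held against equivalence limits LEL = 0.9 and UEL = 1.1:
  entirely ≤ LEL is **Superior**, entirely ≥ UEL is **Inferior**, otherwise
  **Comparable**. A 3″ foam block is the (stricter) skin-protection
  reference; a 2″ block the general-use reference.

All 12 trials (both loads pooled) form one sample with interval
`μ ± z·σ/√n` (z = 1 by default, configurable). Per-model classes then feed
a five-tier matrix: **Level1** (High + Superior on both models vs 3″),
**Level2** (≥ Moderate + ≥ Comparable on both), **Level3** (elliptical model
only), **GeneralUse** (≥ Comparable vs 2″ on the elliptical model) and
**BelowMinimum** (Inferior vs 2″). Intervals that graze a criterion are
flagged borderline and trigger a suggestion to add trials.

Cleaning follows the procedure's outlier rule: a surface datapoint
differing from its channel's median (within one model-load condition) by
≥ 50% of the median is flagged and replaced by its axisymmetric partner's
value; a trial is dropped only if both partners are flagged.

## Worked example

Design a virtual cushion that redistributes well (bony fractions
0.46/0.53) and carries 80% of the reference foam's internal pressure, then
evaluate it against a simulated 3″ reference battery:

```
$ python - <<'EOF'
from cushionbench import BModel
from cushionbench.simdata import cushion_spec
spec = cushion_spec(
    "demo_cushion",
    {BModel.ELLIPTICAL: 0.46, BModel.TRIGONOMETRIC: 0.53},
    {m: 0.80 for m in BModel},
    reference="foam_3in",
    seed=11,
)
spec.to_json("spec.json")
EOF
$ cushionbench simulate --spec spec.json --out trials.csv
$ python -c "
from cushionbench import make_reference
from cushionbench.io import write_trials
write_trials(make_reference('foam_3in', seed=111), 'ref3.csv')"
$ cushionbench classify --trials trials.csv --ref3 ref3.csv \
      --out report.json --markdown report.md
demo_cushion: Level1
$ cat report.md
## Cushion: demo_cushion

| Model | %Bony mean | CI- | CI+ | Redistribution | Ratio vs 3" | Class vs 3" | Ratio vs 2" | Class vs 2" |
|---|---|---|---|---|---|---|---|---|
| elliptical | 0.461 | 0.460 | 0.463 | High | 0.798 | Superior | - | - |
| trigonometric | 0.531 | 0.527 | 0.534 | High | 0.802 | Superior | - | - |

**Overall level:** Level1

Borderline criteria:
- redistribution (trigonometric): threshold 0.55, distance 0.016

Retest suggestions: add_trials
```

Both models recover the designed bony fractions (pooled means 0.461 and
0.531) and the designed internal ratio (0.798, 0.802 vs the designed 0.80);
every interval lies clear of its criterion except the trigonometric
redistribution interval, whose upper bound comes within 0.016 of the 0.55
criterion — close enough to be flagged borderline, so the report suggests
running additional trials before trusting the knife-edge High class.

`cushionbench derive-el` prints the average normalized confidence-interval
half-width (1.96·SEM/mean) of a literature interface-pressure table — the
quantity used to justify the 0.9/1.1 equivalence limits. With no `--ipm`
argument it uses the bundled synthetic nine-cushion table and prints
`0.153`.

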