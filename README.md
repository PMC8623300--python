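# phenoscore

Quantitative phenological scoring of herbarium specimens, evaluation of
automated organ-detection output, and PI-controlled phenoclimatic
modelling.

## The problem

Herbarium sheets record *when* a plant was collected and *what* it was
doing reproductively — bearing flower buds, open flowers, immature fruits,
or mature fruits. Counting those organs lets us place each sheet on a
quantitative phenological scale, and collections spanning a century let us
estimate how flowering time responds to climate and how fast it has
shifted. Object-detection models can automate the counting, but they
systematically *undercount*; this package provides the machinery to ask
whether that matters for the ecology.

## The Phenological Index

Each organ class carries an index value: buds = 1, flowers = 2, immature
fruits = 3, mature fruits = 4. With `P_x` the proportion of a sheet's
reproductive structures in class `i`, the Phenological Index is

```
PI = Σ_{i=1..4} P_x · i        ∈ [1, 4]
```

A sheet with only buds scores exactly 1; only mature fruits, exactly 4.
Because the PI depends on *proportions*, a detector that finds a constant
fraction of every class still estimates it well even when its raw counts
are far too low.

On top of the PI the package implements:

- **detector evaluation** — per-class signed counting errors
  (`e = predicted − manual`), MAE, Pearson/OLS concordance (the slope's
  reciprocal is the "1 detected per N manual organs" ratio),
  abundance-binned error distributions, and specimen-age effects on error
  (log10(|e|+1) and √|ΔPI| responses regressed on collection year);
- **phenological models** — OLS fits of
  `DOY ~ year + PI + elevation + latitude + longitude` (temporal shift) and
  `DOY ~ PI + winter_ppt + spring_tmax` (climate sensitivity), with 95%
  t-based CIs and per-term partial R², plus derived quantities:
  days/century of flowering-date shift, days per PI unit of phenological
  progression, and the full 3-unit bud-to-ripe-fruit cycle length;
- **model comparison** — closed-interval CI overlap between fits using
  manually derived vs detector-derived PIs;
- **a synthetic-collection generator** — seed-reproducible specimens with
  a latent reproductive stage, stage-driven organ composition,
  negative-binomial totals, climate-and-stage-driven collection dates, and
  a binomially thinning detector, so the whole chain runs with no
  external data.

## Worked example

```
$ phenoscore simulate -n 709 --seed 1 -o demo.csv
$ phenoscore evaluate demo.csv -o eval.csv
buds: n=709 MAE=23.24 r=0.96 slope=0.16; 1 detected per 6.3 manual
flowers: n=709 MAE=21.55 r=0.93 slope=0.22; 1 detected per 4.6 manual
immature_fruits: n=709 MAE=7.46 r=0.91 slope=0.31; 1 detected per 3.2 manual
mature_fruits: n=709 MAE=9.12 r=0.96 slope=0.28; 1 detected per 3.6 manual
pi: n=707 MAE=0.13 r=0.99 slope=0.97
$ phenoscore report demo.csv
flowering-date shift: 7.1 to 16.3 days per century
progression: 14.2 to 17.9 days per PI unit
full cycle (3 PI units): 42.5 to 53.8 days
```

The simulated detector finds only one bud for every ~6 a human counts
(slope 0.16), yet the PI concordance is near-perfect (r = 0.99): the
undercounting is roughly proportional across classes, so composition — and
hence the PI — survives. The report lines are the ecological payoff: the
fitted models say flowering advanced roughly 7–16 days per century and
that a plant needs about 43–54 days to move from its first bud to its last
ripe fruit. `phenoscore model` additionally confirms that models built on
detector-derived PIs give CIs overlapping the manual-PI models, so the
automated scores support the same ecological conclusions.

A TOML-driven `phenoscore pipeline` subcommand runs
simulate/score/evaluate/model/report end-to-end into an artifact
directory, and `phenoscore coco-counts` reduces a COCO-style instance
annotation JSON to per-image organ counts.

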