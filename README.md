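# trifret

Analysis of RNA three-way junction conformers from single-molecule FRET
trajectories and EMSA binding titrations, with a ground-truth-labelled
synthetic-data generator so the whole pipeline is testable without any
experimental data.

The scientific setting is the yeast U4/U6 di-snRNP: the base-paired
U4/U6 snRNA duplex forms a three-way junction between stem I, stem II
and the U4 5′ stem-loop, onto which the proteins Snu13, Prp31 and
Prp3/4 (plus the Sm/LSm rings) assemble. Two questions drive the
analysis this package implements:

1. **Junction geometry.** Which two helices of the junction coaxially
   stack? smFRET between dye-labelled helix ends gives the apparent
   efficiency E = I_A/(I_A + I_D), converted to an inter-label distance
   via the Förster relation R = R₀·((1−E)/E)^{1/6} (R₀ = 60 Å for
   Cy3/Cy5) and compared against A-form contour lengths
   (2.8 Å per base pair). A 0.2-FRET peak corresponds to ~76 Å, the sum
   of the stem I (10 bp → 28 Å) and stem II (17 bp → 48 Å) contour
   lengths — the signature of collinear coaxial stacking.
2. **Conformer populations and protein-driven shifts.** Trajectories
   from junction-labelled constructs fall into a few static,
   non-interconverting FRET states. The pipeline QC-selects molecules by
   single-step photobleaching, truncates at the first bleach, pools
   pre-bleach frames into histograms, fits Gaussian components
   (two-stage: per-population means first, then the overall histogram),
   assigns molecules to components, and compares population fractions
   across protein conditions with Welch's t-test over pseudo-replicate
   ensembles.

EMSA titrations are fit with the Hill isotherm
θ = (a−b)/(1+(K_d,app/[protein])ⁿ) + b by bounded multi-start least
squares, and replicate fits are combined as an inverse-variance
weighted mean.

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

Reproduce the coaxial-stacking inference on a synthetic 108-molecule
ensemble with a single 0.2-FRET state:

```sh
trifret repro figure2 --seed 1
```

```
== summary ==
 measured_fret  published_fret  distance_A  published_distance_A best_stacked_pair best_family  best_residual_A
      0.200523             0.2   75.554096                  76.0  stem I / stem II           A         0.045904
== hypotheses ==
          stacked_pair family  predicted_A  residual_A
      stem I / stem II      A         75.6    0.045904
 5' stem-loop / stem I      B         53.2    1.024875
5' stem-loop / stem II      C         72.8    1.024875
```

The fitted FRET peak (0.2005) maps to 75.6 Å; the stem I/stem II
collinear model predicts 75.6 Å (28 + 47.6), so that hypothesis ranks
first with a residual of 0.05 Å — a family-A junction — while the bent
alternatives leave ≥1 Å unexplained.

Conformer-population recovery for the stem II / 5′ stem-loop construct
(three states at 0.2/0.3/0.4 FRET, ~102 molecules per condition):

```sh
trifret repro figure3 --seed 1
```

```
== fractions ==
 condition  component  state_fret  recovered_pct  true_pct  published_pct  published_err
     naked          0         0.2      37.362637 41.176471           44.0            7.0
     naked          1         0.3      50.549451 48.039216           45.0            7.0
     naked          2         0.4      12.087912 10.784314           11.0            3.0
    +Prp31          0         0.2      29.787234 27.102804           28.0            5.0
   +Prp3/4          0         0.2      56.666667 58.095238           58.0            7.0
   ...
```

`recovered_pct` is the pipeline's estimate, `true_pct` the realized
composition of that simulated ensemble (a ~100-molecule multinomial
draw fluctuates by ~5 points around the configured weights), and
`published_pct` the reference value the condition emulates. Recovery
tracks the realized truth to a couple of points, and the
protein-induced shift of population 1 (44% → 28% with Prp31,
44% → 58% with Prp3/4) is reproduced.

The affinity table round-trip (`trifret repro table1 --seed 1`) refits
all 15 published (K_d,app, n) pairs from noiseless synthetic titrations
to three significant figures.

Other entry points: `trifret simulate traces|titration`,
`trifret analyze traces`, `trifret populations fit|compare`,
`trifret geometry rank`, `trifret emsa fit`, `trifret pipeline`.
Everything is importable as a library (`import trifret`).

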