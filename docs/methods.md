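# Methods

`trifret` analyses two kinds of data from an RNA-protein assembly
study: single-molecule FRET (smFRET) trajectories that report the
geometry of an RNA three-way junction, and electrophoretic mobility
shift (EMSA) titrations that report equilibrium binding of proteins to
the RNA. Because such raw data are rarely portable, the package ships a
synthetic-data generator that emulates the statistical structure both
analyses assume, so every stage can be exercised and validated offline
against known ground truth.

## Trajectory model and simulator

Each surface-immobilized molecule carries a donor/acceptor dye pair and
occupies one of a small number of *static, non-interconverting*
conformational states, each characterized by an apparent FRET
efficiency E in [0, 1]. Per frame the expected channel intensities are

    I_A = E * T,      I_D = (1 - E) * T,

with T the total emission rate (photons/frame). Both dyes photobleach
irreversibly after exponentially distributed lifetimes. After acceptor
bleach the donor recovers the full intensity T (energy transfer lost);
after donor bleach both channels drop to a zero-mean background.
Additive Gaussian noise of constant sigma is applied per channel
(an optional mode scales sigma with the square root of the expected
signal); negative samples are retained, because clipping at zero would
bias the FRET estimator. State assignment across an ensemble is a
multinomial draw on the configured weights. Dye blinking, spectral
crosstalk, the gamma factor and camera digitization are not modelled.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| frame interval | 0.1 s | typical TIRF/EMCCD frame time; observation scale of minutes |
| frames per movie | 1000 | ~100 s movies; most molecules bleach in-window |
| total intensity T | 100 photons/frame | round reference level; only T/sigma matters |
| channel noise sigma | 6.5 | gives per-frame FRET sd ~0.05 (see below) |
| donor bleach lifetime | 300 frames | ~4% of molecules survive the window |
| acceptor bleach lifetime | 450 frames | ~40% of bleach-first events are acceptor-first |

First-order propagation of the two channel noises through
E = I_A/(I_A + I_D) gives a per-frame FRET standard deviation

    sd(E) ~= sigma * sqrt(E^2 + (1-E)^2) / T,

which for sigma = 6.5, T = 100 is 0.050-0.058 across E in [0.2, 0.5].
This matches the regime in which histogram peaks 0.1 FRET apart are
resolvable but meaningfully overlapping, which is what the analysis has
to cope with.

The titration simulator draws fraction-bound values from the Hill
isotherm (below) with additive Gaussian noise, truncated to [0, 1.2] to
mimic gel-band integration overshoot.

## Trace analysis

Apparent FRET is computed per frame as I_A/(I_A + I_D); frames whose
total intensity falls below 3x the estimated background sigma are
flagged invalid rather than dropped (this avoids 0/0 after donor
bleach). No gamma, crosstalk or background-trend corrections are
applied: all downstream quantities are *apparent* FRET on the same
footing as the values they are compared against.

Photobleach steps are found by exact penalized least-squares
change-point segmentation (optimal partitioning with PELT pruning;
penalty 5 * sigma^2 * log n, sigma estimated robustly from first
differences, floored at a tiny positive value so noiseless signals
segment minimally). The inner dynamic program is JIT-compiled with
numba, with an identical pure-Python fallback.

A molecule passes QC iff its total-intensity signal shows a single
dominant downward step to background (the single-molecule criterion),
or two steps whose first is an acceptor bleach (acceptor drops while
the donor rises). Aggregates produce multiple downward total steps and
fail. Molecules whose acceptor is indistinguishable from background
over the whole pre-bleach window (donor-only molecules, e.g. acceptor
bleached within the first frames) are rejected: they carry no FRET
information and masquerade as a spurious ~0-FRET state. The FRET record
is truncated at the first bleach event of either dye, and the
pre-bleach mean FRET is the molecule's summary statistic.

A QC-passed molecule is *dynamic* if some change point in its
pre-bleach FRET separates segments whose means differ by at least 0.1
(the resolvable peak spacing) with both dwells at least 10 frames;
molecules with fewer than 20 pre-bleach frames are indeterminate and
excluded from population analysis.

## Population analysis

Pre-bleach frames of all QC-passed static molecules are pooled into a
density-normalized histogram (bin width 0.02 over [-0.2, 1.2], which
puts ~5 bins between peaks 0.1 apart). Fitting proceeds in two stages:

1. Molecules are separated by pre-bleach mean FRET using exact 1-D
   k-means (dynamic programming on the sorted means — deterministic,
   no initialization sensitivity), and a single Gaussian is fit to each
   sub-population's pooled-frame histogram.
2. The per-population means are then used, held fixed, to fit the peak
   widths and areas of the overall histogram.

Stage 2 deliberately does not free the centers: for Gaussians ~2 sigma
apart a free least-squares histogram fit is weakly identified and a
single broad component can absorb two peaks (observed empirically:
free-fit weights 0.69/0.12/0.19 against a 0.44/0.47/0.10 truth, versus
0.44/0.45/0.11 with fixed means). Histogram-level least squares was
chosen over frame-level EM to mirror how such data are conventionally
reduced; `fit_mixture` remains available directly with free centers
seeded (not constrained) by `init_means`.

Each molecule is assigned to the component with the highest Gaussian
density at its mean FRET (ties to the lower mean, for determinism);
molecules more than 3 sigma from every component land in an explicit
"unassigned" bucket. Fractions are counts over assigned molecules;
uncertainties are a 1000-resample bootstrap over molecules with a fixed
seed, computed from the sorted assignment labels so the estimate is
invariant under permutation of the input order.

Conditions are compared with Welch's two-sample t-test on replicate
fraction estimates (significance stars at 0.05/0.01/0.001). The
replicate unit is a pseudo-replicate ensemble: an independently
simulated and fully re-analysed ensemble at the same molecule count
(~100 molecules gives a replicate sd of ~5 percentage points by
multinomial sampling alone). Identical degenerate replicate sets are
reported as t = 0, p = 1.

## Junction geometry

Distances come from the Förster relation R = R0 * ((1-E)/E)^(1/6) with
R0 = 60 Å for the Cy3/Cy5 pair; the kappa-squared orientation factor
and dye linker offsets are not modelled, so distances are label-position
estimates consistent with using apparent FRET. Standard errors of
component means propagate to first order through dR/dE (verified
against Monte-Carlo resampling in the tests).

Arms are ideal A-form duplexes with a rise of 2.8 Å per base pair
(10 bp -> 28 Å, 17 bp -> 47.6 Å). A coaxial-stacking hypothesis places
two arms collinear — predicted tip-to-tip label distance equal to the
sum of their contour lengths — while the third arm pivots in the
junction plane with one free angle, fit on a 0.05 degree grid to
minimize the summed absolute residual against the measured distances.
The free arm's angle is restricted to [20, 160] degrees: at exactly 180
degrees the "bent" alternative degenerates into coaxial stacking of the
measured pair and all hypotheses would tie. Hypotheses are ranked by
residual with deterministic name-based tie-breaking, and the mapping
from stacked pair to Lescoute-Westhof junction family (A/B/C) is
supplied as configuration, defaulting to: stems I/II -> A, stem I/5'
stem-loop -> B, stem II/5' stem-loop -> C.

## Binding analysis

Fraction bound is theta = bound/(bound + unbound) from integrated gel
band signals. The Hill isotherm

    theta = (a - b) / (1 + (K_d,app / [protein])^n) + b

is fit by bounded nonlinear least squares (lmfit) with K_d,app > 0,
n in (0.3, 6), a in (0.5, 1.5), b in (-0.2, 0.5), multi-started from 5
log-spaced K_d seeds spanning the titration range; the lowest-residual
solution wins, and a K_d more than 10x outside the titrated range is
flagged. Reference affinity rows whose Hill coefficient is printed as
exactly 1 with no uncertainty are fit with n fixed at 1; rows with an
uncertainty are fit with n free. Replicates are combined by an
inverse-variance weighted mean (weights from fit standard errors; a
zero/undefined error triggers a flagged unweighted fall-back) with the
weighted standard deviation of replicate estimates as the reported
uncertainty.

## Problem sizes used in tests and the acceptance script

Population-recovery checks simulate ensembles at the published molecule
counts (102-108 molecules, 1000 frames) over 20 independent seeds per
fixture. Recovery is judged against the *realized* composition of each
simulated ensemble (its ground-truth state labels): at n ~ 100 the
multinomial draw itself fluctuates by ~5 percentage points, so the
realized composition — not the configured weights — is the truth the
pipeline actually sees. The acceptance script reports population
percentages as the mean over 20 replicate ensembles for the same
reason: the replicate mean estimates the pipeline's expected recovery
of the underlying proportions with a standard error of ~1 point,
separating pipeline bias from single-draw sampling noise. Hill-fit
robustness uses 100 noisy titrations (theta sd 0.05).

## What passing tests do and do not show

The generator realizes exactly the statistical assumptions the analysis
makes (static states, Gaussian noise, exponential bleaching, Hill
binding). Passing recovery tests therefore demonstrates correctness of
the estimators under those assumptions, and the QC tests demonstrate
rejection of the failure modes that are modelled (aggregates, no-bleach
molecules, donor-only molecules). They do not probe camera
nonlinearity, dye blinking, gamma/crosstalk miscalibration, baseline
drift, interconverting states, or gel densitometry artifacts — on real
data those effects must be handled upstream or accepted as caveats.

## Known limitations

- The change-point penalty (5 sigma^2 log n) is conservative; very
  short dwells (< ~5 frames) or steps below ~2 sigma can be missed.
- Histogram-level mixture fitting discards frame-level information; an
  EM cross-check at the frame level is a natural extension.
- The planar junction model ignores out-of-plane geometry; with three
  measured distances it is exactly identified, and more labels would be
  needed to over-determine it.
- Bootstrap uncertainties on fractions capture assignment and sampling
  variability within an ensemble, not between-movie variability; the
  pseudo-replicate t-test machinery exists for the latter.
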