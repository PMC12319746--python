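# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of the package, in the order data flows through
the pipeline.

## Study design generator

`make_design` produces the two-session associative design the analyses
assume: `n_objects` unique objects (default 160), each bound to one of
`n_scenes` recurring scenes (default 4; half high-reward, half
low-reward, assignment randomized per subject), encoded twice within
one of `n_runs` runs (default 4, giving 320 encoding trials), and cued
once each for scene recall the "next day" (160 retrieval trials over 4
runs). Two ordering constraints are enforced by construction: every
scene occurs equally often in every run of both phases, and within an
encoding run all object–scene pairs appear once before any repetition.
Onsets use uniform inter-trial intervals of 1.75–5.75 s with stimulus
durations of 3.75 s (encoding) and 3 s (retrieval). `n_objects` must be
divisible by `n_scenes × n_runs` (and `n_scenes` must be even) or the
generator refuses with a message naming the constraint.

Behavioral simulation: each encoding repetition is answered correctly
with probability `p_encoding_correct` (default 0.97, near-ceiling);
each object's scene is recalled with probability `p_remember_high` =
0.537 or `p_remember_low` = 0.513 by reward (the observed recall
rates the generator emulates). Errors split between "don't know" and a
uniformly random wrong scene with weight `p_dont_know` (default 0.5 —
the split is not constrained by any reported value, so it is an
explicit parameter rather than an assertion). Confidence and response
times are generated for realism but carry no planted structure.

## Generative pattern model

For a subject with `V` voxels (default 150, a typical anatomical ROI
after vectorization), the generator draws unit-norm scene prototypes
`P[s]` (encoding), unit-norm retrieval prototypes `Q[s]` orthogonalized
against all of `P`, and unit-norm object components `O[o]`:

    x_enc(o, s)  = g_enc · P[s] + g_obj · O[o] + ε
    x_ret(o, s)  = g_reinst(remembered) · P[s]
                 + g_conv(reward) · Q[s] + g_obj · O[o] + ε

with i.i.d. Gaussian voxel noise ε of standard deviation `noise_sd`.
The orthogonalization of `Q` against `P` guarantees that planted
convergence (RRS) shares no variance with planted reinstatement (ERS),
so the two claims are dissociable by construction.

Defaults (calibrated once against the target operating point — ≥90%
detection of each planted effect at n = 40 subjects and 150 voxels with
off-target tests at the false-positive rate — and then frozen):

| parameter | default | meaning |
|---|---|---|
| `encoding_scene_gain` | 0.7 | scene signal at encoding |
| `object_gain` | 0.5 | item-specific signal, both phases |
| `noise_sd` | 0.08 | per-voxel noise; total noise magnitude ≈ 1 at 150 voxels, on the order of the structured components |
| `reinstatement_gain_remembered` (phc_like) | 0.02 | scene reinstatement on remembered trials |
| `convergence_gain_high/low` (mpfc_like) | 0.15 | reward-independent convergence |
| `convergence_gain_high` (ahc_like) | 0.15 | reward-gated convergence (low = 0) |

A structural property worth knowing: any generative model in which
remembered retrieval trials carry the encoding prototype `P[s]` (which
is what same-scene ERS *is*) also hands two same-scene remembered
retrieval trials a shared component of squared magnitude
`g_reinst²`. A reinstatement region therefore leaks a second-order
same-scene RRS covariance. With the default `g_reinst = 0.02` that
leak sits at the detection floor (measured off-target RRS rejection
≈ 5% over 100 cohorts) while ERS power stays at 100%; raising the
reinstatement gain substantially will make the phc-like profile's RRS
tests light up, which is physics, not a bug.

`simulate_bold` turns pattern rows into 4D time series by convolving
each trial's boxcar with the canonical HRF and scaling by the trial's
amplitude, plus optional white noise and random-walk drift, and emits a
7-column confound table (six motion-like series plus framewise
displacement). The same convolution routine drives the GLM design
matrices, so noiseless recovery is exact by construction rather than
approximate.

What the generator does **not** emulate: spatial autocorrelation of
noise (beyond optional Gaussian smoothing), physiological noise
spectra, scanner drift structure beyond a random walk, hemodynamic
variability across regions or subjects, and between-subject
heterogeneity of effect sizes (gains are cohort-constant; subject
variance arises from finite trials, pairs, and voxels). Passing tests
demonstrate the *pipeline's* correctness and calibration under these
idealized conditions, not robustness to every property of real fMRI
data.

## Single-trial GLM

One GLM per trial ("beta series"): a convolved regressor for the trial
of interest; convolved regressors for all other onsets split by
condition (HR/HF/LR/LF — an encoding trial inherits its object's
next-day memory outcome); one convolved regressor for all button
presses; seven non-convolved confounds consumed as supplied; and one
constant per concatenated run. Empty condition groups are omitted (with
a logged notice), never carried as all-zero columns.

Numerical choices: the HRF is the canonical double-gamma (delays 6/16 s,
dispersions 1/1, peak:undershoot ratio 6, 32 s support), normalized to
unit sum; regressors are built on a 16× oversampled grid so onsets
between scans are represented exactly; events convolve as boxcars of
their stated duration (3.75 s / 3 s defaults, parameterized). Estimation
is ordinary least squares with t = β/SE on `scans − rank(X)` degrees of
freedom; no temporal autocorrelation model is applied (the t values are
OLS t's), and rank-deficient designs fail loudly with the collinear
columns named. Gaussian smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in
voxel units with zero padding ('constant' mode), so an interior
impulse's mass is conserved; defaults are 2 mm FWHM for single-trial t
maps and 6 mm for searchlight contrast maps (2 mm isotropic voxels,
TR = 2 s assumed throughout).

## Similarity and pair rules

Similarity is the Fisher-z Pearson correlation between single-trial
patterns. Degenerate inputs (constant pattern rows, |r| ≥ 1 − 1e−7)
raise rather than clip: with noisy data they always indicate a bug.

Pair inclusion, applied identically at ROI and searchlight level:

- both members must share the reward × memory condition (the stricter
  reading of "same condition", adopted globally for consistency);
- ERS: same-object pairs are excluded (perceptual identity would
  masquerade as reinstatement); any pair touching an object with an
  incorrect encoding repetition is excluded;
- RRS: same-run pairs are excluded (scanner-session autocorrelation),
  incorrect-encoding objects likewise; pairs are unordered and counted
  once.

Cell means are unweighted means of pair z values in the 8 cells
(HR/HF/LR/LF × same/diff). For bilateral regions, cell means are
computed per hemisphere and then averaged (means of means, not pooled
pairs). Empty cells propagate as missing; subjects with any missing
cell are dropped from the ANOVA for that region, with a count reported.

## Group inference

The 2×2×2 within-subject ANOVA is implemented via per-subject contrast
scores: for each of the seven effects, the score is the difference of
means of the +1 and −1 cells; F is the squared one-sample t of the
scores on (1, n−1) degrees of freedom. For two-level within factors
this is algebraically identical to the classical sums-of-squares
decomposition (the test suite verifies agreement with an independent
classical implementation to 1e−8), sphericity is vacuous at two levels,
and the per-subject scores remain available for follow-up paired
contrasts, across-subject correlations, and the RRS-vs-ERS comparison.
All p values are two-sided except the permutation group test.

Label permutation: within each subject, the cell-label vector is
shuffled as a whole across all included pair values (per-cell counts
are thereby preserved exactly), the contrast is recomputed on permuted
cell means, and the true effect is z-scored against the null,
z = (true − null mean)/null sd. The sd-normalized z was chosen over a
rank-based variant; with ≥500 permutations the two agree closely in
calibration, and the z form supports the group-level one-sample t test
("greater than 0", one-sided) directly. Defaults: 10,000 permutations
for ROI analyses, 1,000 for searchlights, reducible for speed. A null
with zero spread raises a degenerate-null error. Because pairs sharing
a trial are mildly dependent, the label-permutation null understates
between-subject variability slightly (per-subject z dispersion ≈ 1.05
under the null profile); the group t test on z's remains calibrated
(type-I ≈ 5%, verified over cohorts).

## Searchlight and family-wise error

The searchlight repeats the ROI analysis inside a sphere of integer
lattice offsets with ‖δ‖² ≤ r² (radius 3 → 123 voxels) centered on
every in-mask voxel, reusing the same pair lists (inclusion rules do
not depend on voxels). Centers with fewer than `min_voxels` in-mask
sphere voxels (default: half the full sphere) are missing. A radius-0
sphere holds one voxel; one-voxel patterns are constant rows, so both
the searchlight and the ROI path raise the same degenerate-pair error —
the exact ROI equivalence is instead exercised with spheres covering
the ROI's full voxel set.

Group maps are voxelwise one-sample t over subject contrast maps.
Family-wise error control is sign-flipping max-statistic permutation:
under the null of sign-symmetric subject effects, each voxel's
corrected p is (1 + #{permutation max |t| ≥ observed |t|})/(n_perm+1),
monotone in |t|, with floor 1/(n_perm+1); a small-volume mask can only
shrink corrected p values. This permutation scheme replaces parametric
random-field-theory peak correction deliberately: it is
assumption-light, exact under exchangeability, and testable, at the
cost of runtime and of requiring the subject maps on a common grid
(maps are assumed pre-normalized; spatial normalization itself is out
of scope).

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; cohort seeds are spawned
from a root seed via `numpy.random.SeedSequence`, and identical
configurations reproduce byte-identical outputs (audited in the test
suite and the run log). The packaged calibration checks use Monte-Carlo
sizes chosen as the package's own operating points: 100 cohorts per
profile for power, 500 cohorts for ANOVA type-I error, 200 subjects /
500 permutations for z calibration, and 200 cohorts × 200 sign-flips
for FWE calibration; `scripts/acceptance.py` reports the same
quantities at similar sizes from a single root seed.

## Known limitations

- OLS t values without autocorrelation correction are slightly
  optimistic as within-subject statistics; this cancels in the
  similarity analyses (which only compare patterns) but matters if the
  t maps are reused univariately.
- The generator's cohort-constant gains make between-subject variance
  purely sampling-driven; real cohorts add heterogeneity that widens
  group-level confidence intervals.
- Searchlight computation is pure Python/NumPy per center; it is sized
  for ROI-scale grids and calibration studies, not whole-brain 2 mm
  grids.
- The second-order reinstatement→RRS leakage described above bounds how
  strongly a pure-reinstatement region can be simulated before its RRS
  control tests light up.
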