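# Methods

## Model

For one electrode shank with N contacts, labels z ∈ {−1, +1}ᴺ (−1 gray,
+1 white) and per-contact features xᵢ = (sᵢ, dᵢ), the joint model is

    P(z, x) ∝ exp(β Σᵢ zᵢ zᵢ₊₁) · Πᵢ L(xᵢ | zᵢ)

with no external-field term in the prior: any information about overall
class balance enters only through the likelihood. Shanks are independent
given the parameters; contacts are conditionally independent given their
labels.

**Likelihood.** L(x | c) is a Gaussian product-kernel density estimate over
the pooled training contacts of class c, with widths α_c = (α_c,1, α_c,2)
in the power-shift and depth dimensions. Because depth is effectively an
interval (a contact "owns" the stretch of shank halfway to each
neighbour), the depth factor of each kernel is integrated in closed form
over [midpoint to previous contact, midpoint to next contact]; at shank
ends the open side extends half the local spacing outward (the midpoint
rule is undefined there, so the interval is made symmetric). This makes
the likelihood an honest probability per unit shank and lets irregular
contact spacings rescale the densities automatically. Kernels are
normalised over the full plane; truncating their depth support to the
in-brain range was considered and rejected as it complicates the
closed form for a second-order effect at the shank ends.

**Inference.** All per-shank quantities are exact. The partition function
and the per-contact marginals P(zᵢ = +1 | x) come from transfer-matrix /
forward–backward recursions in log space (O(N), stable up to β ≈ 50 and
beyond); a brute-force enumeration over all 2ᴺ labelings serves as an
independent oracle in the tests and agrees to 1e−10 relative tolerance.
At β = 0 the marginals reduce exactly to independent two-class Bayes
posteriors; as β → ∞ the shank is forced to a single consensus label.

**Hyperparameters.** α₂ (depth widths) is user-set, default one
inter-contact spacing (5 mm electrodes; for wider spacing choose a smaller
width relative to spacing). The free parameters (α_wm,1, α_gm,1, β) get
diffuse exponential hyperpriors (rate 0.01, exposed in config) and a grid
posterior:

* kernel widths — leave-one-point-out KDE log-likelihood of each class's
  pooled training features (each point's density evaluated from the other
  M−1 points). Plain in-sample likelihood is degenerate (optimum at width
  0); leave-one-out removes that without extra machinery.
* β — product over training shanks of the normalised chain-prior
  probability of the observed labeling, using the closed-form partition
  function log Z = log 2 + (N−1) log(2 cosh β).

The three likelihood terms touch disjoint data, so the posterior
factorises exactly and is fit as three 1-D grid posteriors (log-spaced, 40
points by default, α over [0.01, 2], β over [0.01, 30]) moment-matched by
a Gaussian truncated to the positive orthant with diagonal covariance.
When the truth is expected to lie within a few grid steps of interest
(e.g. parameter-recovery studies), pass a denser grid; moment matching
over a coarse grid otherwise inflates the reported SD by the bin width.

**Posterior predictive.** Class probabilities are averaged over draws from
the truncated Gaussian (rejection sampling on positivity, coordinate-wise
truncated sampling as a logged fallback below 1% acceptance); 100 draws by
default. Every stochastic operation takes an explicit NumPy generator; no
global random state. Hard calls use threshold 0.5 with ties going to gray
(conservative: a 50/50 contact should not be discarded as white matter),
and confidence is reported as 2|p − 0.5|.

## Features

* Bipolar referencing: each usable contact minus the adjacent usable
  contact toward the shank tip; the deepest usable contact has its
  peripheral neighbour subtracted so the output count equals the usable
  count. When the neighbour toward the tip is excluded (clinician-flagged
  noisy), the nearest usable contact toward the tip is used instead — the
  montage skips bad channels rather than fabricating data. Shanks with a
  single usable contact are dropped with a warning.
* Welch PSD: 10 equally spaced 10 s windows (overlapping with a warning if
  the recording is shorter than 100 s), Hann segments of 1 s with 50%
  overlap inside each window, periodograms averaged in the power domain
  across windows, then natural log. Natural log is the package-wide
  convention (the shift feature is base-invariant up to scale, but kernel
  widths are only meaningful under one fixed convention).
* Relative power shift: mean over unmasked bins in 1–150 Hz of the
  contact's log-PSD minus the patient-reference spectrum; the reference is
  the across-contact mean of log-PSDs (geometric-mean spectrum) by
  default, with an arithmetic power-domain mean behind a switch. Shifts
  are re-centered so each patient's mean is exactly zero, which removes
  common gain/impedance offsets across patients. The 4 Hz line-noise
  exclusions are read as ±2 Hz around 60 and 120 Hz.
* Depth: zero at the most peripheral in-brain contact, increasing toward
  the tip in spacing units, or in mm via per-gap distances for irregular
  electrodes. Contact order is fixed package-wide as index 0 = tip.

## Synthetic study

The generator produces what the model assumes, plus the known structure of
real implants that the inference prior deliberately ignores:

* labelings from the exact Ising chain at `beta_true` with a
  depth-dependent external field used *only during generation*: a
  parabolic profile pulls both shank ends toward gray (electrodes enter
  through cortex and often end in deep gray structures) and a uniform
  offset, calibrated by bisection on the exact chain marginals, fixes the
  expected white fraction at 30%. Defaults (8 patients × 6 shanks × 12
  contacts, `beta_true = 1`, field amplitude 2) give ~1.4 gray/white
  transitions per shank — blocky but not frozen, matching typical
  implants.
* feature-1 draws from class Gaussians separated by 1.2 natural-log units
  (SD 0.6), white below gray, then patient-centered. This emulates the
  observed class clouds with moderate overlap.
* raw time series: per shank, a shared 1/f pink-noise source (100 µV)
  whose amplitude decays slowly (rate 0.05 per contact of distance from
  the nearest gray contact) plus independent local pink noise (25 µV on
  gray, attenuated into white). The shared component dominates the common
  reference and nearly cancels under bipolar referencing, so the bipolar
  power feature separates the classes more strongly — the mechanism that
  motivates bipolar referencing. Recordings are written to plain 16-bit
  EDF (a minimal writer lives in `signal_io`; reading goes through
  MNE-Python) and round-trip within quantization error.

What passing on this cohort does **not** show: robustness to artifacts,
non-stationary spectra, mislabeled training contacts, region-dependent
depth distributions, or electrode geometries where white-matter contacts
pick up large bipolar signals from flanking gray patches — all present in
clinical data. The synthetic class clouds are cleaner than real ones, so
cross-validated AUCs here (~0.95–0.98) sit above what mixed clinical
cohorts can achieve; the quantities to read are the *contrasts* (full
model vs. β = 0 ablation, bipolar vs. common reference, transition vs.
deep contacts), not the absolute level.

## Evaluation

AUC is computed per patient from a full threshold sweep (trapezoid rule;
verified against the normalised Mann–Whitney U statistic) and averaged
across patients; pooled-contact AUC is available behind a flag.
Cross-validation refits the hyperparameter posterior and class densities
per fold; k-fold assignment is seeded and re-drawn until every training
fold contains both classes. The fixed-β variant picks the training-set
AUC-maximising β on a grid (ties to the smallest value) with kernel widths
at their posterior means. The transition-distance analysis places each
labeled transition at x = 0 with the first white-side contact at +0.5 and
summarises p_white quartiles per signed half-integer distance; a contact
equidistant from two transitions is assigned the one toward the tip.

## Numerical notes

* Chain messages, KDE sums and Gaussian-CDF differences all run in log
  space; log(Φ(b) − Φ(a)) is computed from `log_ndtr` with reflection, so
  depth intervals far into either tail stay finite.
* Contact log-likelihoods are floored at −1e6: a contact far from all
  training points in both classes then contributes an uninformative
  (0.5/0.5) factor instead of NaNs.
* The acceptance script scales the study to 8 patients (576 contacts) and
  200-shank recovery runs; these sizes give stable estimates in a few
  minutes on one CPU and were chosen as the package's desk-scale defaults.

## Known limitations

* The β scale is specific to this prior parameterisation; couplings fitted
  elsewhere with a differently scaled exponent are not directly
  comparable, so β is always re-estimated from training data.
* Only two tissue classes are modeled; ventricle/out-of-brain contacts
  must be excluded upstream (the metadata `in_brain`/`excluded` flags).
* The depth distribution pools all shanks; region- or angle-specific depth
  profiles are out of scope.
* The hyperparameter posterior is a truncated-Gaussian approximation to a
  grid posterior; strongly skewed posteriors (tiny training sets) are
  represented only through their first two moments.
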