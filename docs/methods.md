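# Methods

## Problem and model

The package infers recurrent spectral-connectivity states from region-level
multichannel electrophysiology.  The observation model is a hidden Markov
model on time-delay embedded data: each sample is the stack of all N
channels at L consecutive lags in a symmetric window (L = 15 at 250 Hz,
i.e. 60 ms), reduced by PCA to P components (default 2N).  Every state is a
zero-mean Gaussian with full covariance in that space, so a state encodes a
pattern of frequency-resolved power and cross-channel phase coupling; the
state means are pinned at zero so amplitude offsets cannot drive the
segmentation.

Inference is variational Bayes with conjugate priors:

- precision of each state: Wishart (equivalently inverse-Wishart on the
  covariance) with scale equal to the empirical covariance of the embedded
  data and P + 2 degrees of freedom — the weakest proper prior centred on
  the data scale;
- transition rows: Dirichlet with diagonal count 10 and off-diagonal 1,
  a mild persistence prior;
- initial distribution: symmetric Dirichlet(1).

The E-step is an exact scaled forward–backward pass using exponentiated
expected log-parameters, run per subject so chains never cross recording
boundaries; the M-step is conjugate.  The negative evidence lower bound
("free energy") decomposes exactly into the forward-pass log-evidence minus
Dirichlet and Wishart KL terms and is non-increasing across batch sweeps; it
is reported per iteration for diagnostics and model comparison.

Initialisation: k-means on log second-moment features of short windows,
hard-label transition counts, a few VB sweeps, best of R = 5 seeded restarts
by free energy.  Initialising the transition counts from the *hard* init
labels matters: a uniform (or smoothed outer-product) count matrix starts
the optimiser in a fast-switching basin from which it does not escape, and
the resulting decoder never integrates evidence across a dwell.

A stochastic variational option updates the global posteriors from
subject-level minibatches with step size (t + 5)^(−0.6) (Robbins–Monro);
batch VB is the default and the reference path for all tests.  Numerical
floors: covariance eigenvalues are floored at 1e-8 of the mean trace before
Cholesky factorisation; Viterbi ties break toward the lower state index.

## Preprocessing

Fixed order: per-region first-PC reduction → symmetric orthogonalisation of
the cortical block → per-subject per-channel z-scoring → stacking with the
STN contacts → temporal concatenation → cross-subject sign-flip correction.
STN channels bypass the orthogonalisation: intracranial contacts have no
source-leakage mixing, and orthogonalising them against cortex would remove
genuine zero-lag STN–cortex coupling.  Symmetric orthogonalisation finds the
Frobenius-closest matrix with exactly orthogonal (zero-correlation) rows by
alternating a polar (Procrustes) step with row-magnitude updates.  The
sign-flip correction maximises cross-subject agreement of 15-lag
autocovariance structure by greedy per-channel flips; the objective is
invariant to flipping all channels of one subject, so signs are unique only
up to a global flip per subject.  Constant channels are rejected, never
imputed.  Z-scoring is per subject, before concatenation.

## State spectra

State visits are maximal argmax-probability runs (hard assignment; this
matches the "state visit" definition used for temporal metrics —
gamma-weighted estimation is not implemented).  The posterior is aligned to
raw samples by the embedding offset ⌊L/2⌋.  Visit data are band-passed
1–45 Hz (zero-phase Butterworth applied to the full series before slicing,
so all segments see the same filter) and spectra estimated with 7 DPSS
tapers, time–bandwidth 4.  The 0.5 Hz grid comes from zero-padding each
taper window to fs/0.5 points (500 at 250 Hz); segments longer than one
window are tiled into non-overlapping full windows (a trailing remainder of
at least a quarter window is kept), shorter visits form a single window of
their own length.  Cross-spectra are averaged over tapers and windows with
duration weighting; coherence is the normalised cross-spectral magnitude,
in [0, 1] with unit diagonal.  Useful identities: integrated PSD matches
the signal variance (Parseval, within windowing effects), and the expected
coherence magnitude between independent channels is ≈ √(π/(4 n)) for n
averaged taper-windows — the "bias floor" referenced below.

## Frequency modes and networks

The group-level STN–cortex cross-coherence (bins × [6·42 edges · K states])
is factorised into 4 non-negative modes by multiplicative-update NNMF with
seeded restarts; the kept solution is the lowest-error restart among those
whose modes agree with the best restart above 0.9 matched correlation, and
a stability score (mean matched correlation across restarts) is reported.
Modes are normalised to unit 1-norm and auto-labelled by mass-in-band
(delta/theta 1–8, alpha 8–12, beta 13–30 Hz; unmatched modes are
"residual") — an automated stand-in for the visual specificity check used
in practice.

Edge significance within a condition: group-level mode-projected coherence
is normalised by subtracting each edge's mean across states; a
two-component 1-D Gaussian mixture with both variances fixed at the
(standardised) unit scale is fitted by EM to the absolute normalised values
of each state × mode; an edge's p-value is its upper-tail probability under
the lower-mean (noise) component, corrected across edges by
Benjamini–Hochberg (per state × mode family; Bonferroni available).  The
fixed-variance EM is deterministic (percentile initialisation).

Between conditions: matched states are compared per anatomical cluster pair
and mode by two-sided independent-sample t-tests on subject-level mean
coherence, Bonferroni-corrected over the total number of comparisons
(cluster pairs × modes × matched state pairs) by default.  Independent
(not paired) tests mirror the emulated design; a paired test would be
statistically preferable for within-subject designs and can be added by the
caller on the returned subject-level values.

## State matching

Two HMMs fitted on different datasets live in different PCA subspaces, so
state covariances are first mapped back through each model's own projection
and the lag-0 channel-space block (N × N, full rank) is compared; the whole
channel × lag space is available behind a flag but is rank-deficient and
leans on the SPD repair floor (eigenvalues floored at 1e-10 of trace, with
a warning).  The metric is the affine-invariant Riemannian distance
√Σ log² λ_i over generalised eigenvalues; the K × K distance matrix is
solved by linear assignment, which for K ≤ 8 provably equals the
brute-force minimum over permutations.

## Temporal statistics

Fractional occupancy, lifetimes and intervals are computed from the hard
(Viterbi or argmax) path by run-length encoding.  Lifetimes ≤ 100 ms are
excluded from lifetime *comparisons* only (not from FO or intervals — the
filter's scope for intervals is a documented choice).  FO is analysed with
a two-way repeated-measures ANOVA at the subject level (state × condition,
both within subject); lifetimes and intervals are pooled at the visit level
and analysed with a two-way fixed-effects ANOVA (type II), matching the
much larger degrees of freedom such comparisons carry.  Post hoc: Tukey HSD
(Bonferroni-corrected t-tests optional).

## The synthetic cohort generator

Each state is a band-limited coherence graph: every edge shares a
narrow-band Gaussian latent between its two channels on top of independent
white channel noise.  The mixing gain has a closed form — coherence
magnitude at the centre frequency is a²S_z/(a²S_z + S_n), so a target c
fixes a² = c/(1−c) · S_n/S_z — which makes every spectral assertion in the
test suite checkable without simulation.  When several edges meet at a
channel the realised coherence drops below the nominal target; the ground
truth records the exact generalised closed form.  The latent chain is
first-order Markov, optionally semi-Markov via a minimum dwell (dwell =
min_dwell + geometric), preserving the geometric tail.

The default demonstration cohort mirrors the study geometry: 48 channels of
which 6 are STN contacts, 250 Hz, three states living in delta/theta
(4.5 Hz), alpha (10 Hz) and beta (21 Hz), each coupling the STN contacts to
10 distinct cortical regions plus one cortico-cortical edge, nominal edge
coherence 0.8, mean dwell ≈ 2 s (minimum 1 s) so that most visits span at
least one full multitaper window.  Latent bandwidths (3, 2 and 6 Hz) are
sized so each edge's spectral footprint stays inside its canonical band
after the ±2 Hz taper smearing.  A second condition reuses the same
blueprint with an independent chain realisation, a nominal state-label
permutation and optional per-edge amplitude scaling.

What the generator does **not** emulate: 1/f background spectra, volume
conduction/leakage (so the orthogonalisation step is exercised but not
needed), non-Gaussian or non-stationary noise, inter-subject variability in
spectral peaks, and realistic coherence magnitudes (empirical MEG coherence
is far weaker; recovery at realistic SNR would require more data than a
desk-scale experiment).  Passing recovery tests therefore demonstrate the
correctness of the estimation machinery, not expected performance on real
recordings.

## Validation summary and known limitations

The recovery benchmark (4 subjects × 5 min × two conditions, seeded)
decodes the latent state sequence at ≈ 0.97 frame accuracy, recovers
fractional occupancy within 0.01, flags all 30 planted STN–cortex edges in
the matching state and mode, and recovers the cross-condition state
correspondence exactly.  Null-calibration suites hold the GMM edge rate and
the cluster-test family-wise rate at or below the nominal 0.05.

Known limitation — alpha-mode mass: of the three band modes recovered by
the 4-mode NNMF, delta/theta holds ≈ 75% and beta ≈ 92% of their 1-norm
mass inside their canonical bands, but the alpha mode holds only ≈ 47%
despite peaking squarely at 9–11.5 Hz.  Two structural effects cap it: the
alpha band is only 4 Hz wide while the prescribed multitaper smears ±2 Hz,
bounding even an ideal narrow-band alpha mode near 87%; and the coherence
bias floor of short state visits (≈ 0.05 at this cohort size) forms a
broadband pedestal that a rank-4 factorisation distributes across modes —
the effect persists on an idealised noise-free group matrix, so it is a
non-identifiability of the factorisation, not estimation noise.  Band
*identity* (peak location, labelling) is recovered reliably; the mass
fraction for narrow bands is not a robust statistic of this method at
desk-scale data volumes.

Other limitations: stochastic VI is validated only on small problems (its
final bound is checked against batch VB within 0.5%); no model-order
selection beyond reporting free energy; no MAR observation model or
parametric spectra; hard state assignment only for spectral estimation.

## Problem sizes used by the test suite

Unit tests run on toy dimensions (≤ 10 channels, ≤ 40 k samples).  The
recovery benchmark uses the full study geometry (48 channels, 96 PCA
components, 300 k embedded samples per condition) and runs in ~2 minutes;
calibration suites use 200 seeded replicates at the statistical-input level
(edge values, subject-level means, visit tables) rather than 200 full
cohort simulations, because the calibration property concerns the
inference procedures and full cohorts would add hours of simulation without
changing what is being tested.
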