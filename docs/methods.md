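# Methods notes

This note records the model assumptions, parameter choices and numerical
conventions behind `leida`, in the spirit of a statistical methods
appendix. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and temporal preprocessing

The package starts from parcellated ROI time series; all image-space
preprocessing (registration, smoothing, ICA denoising, nuisance
regression) is assumed done. The retained temporal steps are, in order:
initial-volume discard (default 0 for the bundled generator, which emits
analyzed frames directly; use 4 for raw scanner exports that include T2*
equilibration volumes), linear detrend, band-pass 0.01–0.1 Hz, demean.

The band-pass is a 2nd-order Butterworth applied forward-backward
(`sosfiltfilt`). The filter design is deliberately zero-phase: every
downstream quantity is a function of instantaneous phase, and a causal
filter's group delay would bias phase differences. Detrending before
filtering removes the linear drift a short-record band-pass only
attenuates; for linear trends the combined operation is order-insensitive.
A separate high-pass (e.g. 100 s cut-off) is not applied because the
0.01 Hz edge of the band-pass subsumes it.

## Phases, phase-locking and the leading eigenvector

Phases come from the analytic signal (`scipy.signal.hilbert`), wrapped to
(−π, π]; all phase arithmetic is done on unit phasors to avoid wrap
errors. The phase-locking matrix `PL = cos(θ_n − θ_p)` is algebraically
rank 2 (`ccᵀ + ssᵀ`), so `eigenvector_series` computes each frame's
leading eigenvector exactly from the 2×2 Gram matrix of `(cos θ, sin θ)` —
a closed form, not an approximation; `leading_eigenvector` accepts any
symmetric matrix through a LAPACK path and both routes are cross-checked
in tests.

Sign convention: eigenvectors are defined up to sign, so each `V1` is
flipped to make the majority of elements negative; the positive residual
marks the phase-shifted community. An exact tie on sign counts is broken
by making the largest-magnitude element negative. A degenerate top
eigenvalue (multiplicity > 1 within tolerance) keeps the deterministic
solver ordering and logs the event; for the rank-2 path the degenerate
Gram matrix falls back to the cosine direction.

Edge handling: the Hilbert transform distorts boundaries, and an
`trim_edges` option drops frames from each end of the eigenvector
sequence. The default is 0 so that a 204-frame scan contributes exactly
204 eigenvectors and the pooled counts of the emulated design (4488 =
11 × 2 × 204; 6936 = 17 × 2 × 204) hold by construction; trimming is a
config option for users who prefer it.

## State detection

Pooled eigenvectors are unit-norm directional objects, so the default
clustering distance is cosine and the fitting loop is a spherical k-means
(k-means++ seeding, Lloyd iterations, centroid = mean direction). The
distance and the restart count are exposed in config because neither is
canonical; defaults are cosine and 50 seeded restarts per k with
best-by-inertia selection, so k-means local minima do not leak into group
statistics. An empty cluster during fitting re-seeds that replicate; during
fixed-centroid assignment of a validation pool, empty states are allowed
(occupancy 0). No optimal-k criterion is applied: the sweep k = 2…20 is
reported in full, and states are named `kXcY`.

## State metrics

Occupancy is a frame count over total frames. Lifetime is mean run length
× TR; runs truncated by the scan boundary count as complete runs, because
discarding them would bias short scans (204 frames) downward and no
principled alternative exists at this record length. A state never visited
has lifetime 0.

Decoupling: per frame, the circular mean phase (angle of the summed unit
phasors — arithmetic means of wrapped angles are wrong near ±π) is taken
over the centroid-positive and centroid-negative regions; the absolute
wrapped difference, averaged over **all** frames of the scan (not only
frames where the state is dominant), is reported in [0°, 180°]. The
absolute value is used because a signed mean could cancel. The metric is
invariant to global phase rotations. It is undefined for single-sign
centroids (typically the global in-phase mode): the low-level function
raises, and table builders record NaN and exclude such states from the
decoupling test family. Both cohorts use the discovery-fit centroid signs,
so the comparison is on identical state definitions.

## Statistics

The paired test is the ordinary paired t on follow-up − baseline
differences with a sign-flip permutation null (random independent flips;
valid under exchangeability of sessions). p-values are two-sided with
add-one smoothing, `p = (1 + #{|t*| ≥ |t_obs|}) / (n_perm + 1)`, so p > 0
always. Zero-variance differences return p = 1 with a warning. BH-FDR is
applied within each (k, metric) family — i.e. separately per partition
model — matching the sweep-wise adjustment convention. Frequentist tests
are two-sided; the Bayes factor defaults to the one-sided alternative
"baseline < follow-up" (the direction of interest in a recurrence design)
with the conventional medium Cauchy prior scale r = 1/√2; both are config
options, since neither sidedness nor prior is canonical.

The JZS Bayes factor is computed as the ratio of the marginal likelihood
of the observed t under a Cauchy(0, r) prior on the standardized effect
(noncentral-t density integrated by adaptive quadrature; one-sided
alternatives truncate and renormalize the prior) to the central-t density.
This is equivalent to the usual g-prior integral form. Integration
failures (negative mass or relative error above 1e−4) raise with
diagnostics rather than returning a silent number.

Per-test permutation seeds are derived from the master seed and the
(k, state, metric) triple, so results are reproducible and independent of
iteration order.

## The synthetic cohort generator

There is no generative model in the LEiDA literature to copy, so the
generator is built to reproduce exactly the statistical objects the
analysis measures. A discrete-time Markov chain over `n_states_true`
latent PL-states (default 3; baseline self-transition 0.85, uniform
switching, i.e. expected dwell ≈ 13 s at TR = 2 s) drives all regions'
band-limited carriers at 0.04 Hz — the mid-band of the 0.01–0.1 Hz filter.
While a state is active, its community (disjoint consecutive blocks of
`n_regions // (n_states + 1)` regions; one block of regions belongs to no
community) is phase-advanced by π/2 plus a per-state jitter drawn once
from U(0.3, 0.8) rad, so communities are shifted by more than 90° — the
conventional rendering threshold for a PL-state's subsystem — while
remaining mutually distinguishable. Gaussian observation noise
(sd 0.5 against unit-amplitude carriers; after band-passing, an in-band
amplitude SNR of roughly 3:1, plausible for parcel-averaged BOLD) is added.

The default paired design is 11 recurrent + 17 non-recurrent subjects, 2
sessions, 204 frames, 80 regions. Effects apply only to follow-up scans of
the recurrent arm, mirroring the asymmetry of a recurrence design; with
all factors at 1 the sessions are exchangeable (the null mode used for
error-control tests). Default planted effects, one per metric: entry
probability ×2.0 on state 1 (stationary occupancy 1/3 → 1/2), self
transition ×1.10 on state 2 (dwell ≈ 13 s → 31 s), offset +0.6 rad on
state 3 (decoupling ≈ +11°). These magnitudes are sized for unambiguous
parameter recovery at n = 11 pairs — a recovery test should fail only when
the method is broken, not when sampling noise is unkind — and the offset
increment is capped so every community offset stays below π, where the
wrapped angular difference is monotone in the offset. Note that effects
are mechanically coupled: because transition rows are renormalized and
occupancies sum to one, raising one state's entry probability necessarily
depresses the occupancy (and, through row rescaling, the dwell) of the
others; recovery tests therefore plant one effect at a time.

What the generator does *not* emulate: hemodynamic response convolution,
voxel-level structure, motion and physiological artifacts,
subject-specific connectomes, amplitude dynamics (carriers have unit
amplitude) and spatially correlated noise. Passing tests therefore show
that the pipeline recovers the dynamical objects it defines — not that
those objects are identifiable in any particular real dataset.

## Problem sizes used by the test suite

Unit tests run on reduced cohorts (24 regions, 120 frames, 5 + 5
subjects). The acceptance suite uses the full emulated dimensions where
the claim is about counts or recovery (80 regions, 204 frames, 11 and 17
subject arms), 100 repeats per planted-effect recovery scenario with
n_perm = 1000 and 5 clustering restarts, 1000 repeats for per-test type-I
calibration, and 20 full null-cohort repeats (19-model sweep, 3 restarts)
for the global null property; clustering restarts and permutation counts
in repeated-simulation loops are reduced relative to the analysis defaults
(50 restarts, 5000 permutations) because they enter those loops only
through best-of-restart stability, not through the tested quantities.

## Known limitations

* Whether the original sweep-wise k-means used cosine or Euclidean
  distance, and its restart count, is not canonical; both are config
  options and results can shift at fixed seed when they change.
* A global-null cohort analyzed across 19 partition models × 2–3 metrics
  carries ~38 BH families; each family has ≈ 5% probability of at least
  one rejection under the global null, so *some* FDR-significant state
  somewhere is common even when nothing is real. Sweep-wide findings
  should be judged by their consistency across adjacent k (as in the
  emulated study), not by any single family.
* The decoupling metric is occupancy-weighted by construction (it averages
  over all frames); an offset change and an occupancy change on the same
  state are not separable from the metric alone.
* At 204 frames, lifetime estimates for partitions with large k rest on
  few runs per state and are noisy; interpret high-k lifetimes cautiously.
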