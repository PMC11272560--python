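# Methods

This note documents the models, estimators and numerical choices behind
`tdabreak`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable convention exists.

## Windowed embedding

A multivariate series X(t) ∈ R^P over T samples is sliced into windows of
width w covering samples [i·s, i·s + w) in 0-based half-open indexing
(stride s = w by default, i.e. non-overlapping; a trailing partial window
is dropped). The w samples of a window are treated as w points in R^P with
no centering, detrending or rescaling — the raw coordinates are embedded,
so total persistence is expressed in signal units. Each window's summary is
time-stamped at the window *end*. Non-overlapping windows are the default
because overlap induces strong serial correlation in the TP curves, which
the permutation null (exchangeability) would then violate.

## Rips persistence and total persistence

Per window the Vietoris-Rips filtration on the Euclidean distance matrix is
computed up to homology dimension 2. Total persistence TP_k sums
(death − birth) over the finite bars of dimension k. The essential
connected component is excluded (otherwise TP_0 would be infinite for every
window); an optional `cap_infinite` mode instead caps infinite deaths at
the filtration cutoff. With the default cutoff `eps_max="auto"` — the
cloud's maximum pairwise distance — the complex is complete at the end of
the filtration, so every loop and cavity dies and the essential component
is the only infinite bar. A useful identity, exercised by the tests: TP_0
equals the total edge weight of the cloud's Euclidean minimum spanning
tree.

The engine is an in-package implementation (no TDA dependency): persistent
cohomology with clearing, columns processed in decreasing filtration order,
simplices identified by colex index with the global order (diameter, colex
index) — a filtration refinement that puts faces before cofaces, so ties
(equal distances, duplicate points) are resolved deterministically. H0 uses
Kruskal union-find. Three exact optimizations keep 50-point windows at
~10 ms and 150-point windows at ~1-2 s per cloud on one CPU:

* columns that claim their pivot without any addition (the vast majority)
  are never sorted and are stored only as their vertex tuple, with the raw
  coboundary re-enumerated on demand;
* explicit reduced columns are stored only after an actual collision;
* the filtration is truncated at the *enclosing radius* (min over points of
  the max distance to any other point). At that scale the complex is a
  cone, hence contractible: every class born below it has died, and any
  class born at or above it has zero persistence, so the
  positive-persistence diagram is unchanged while far fewer simplices enter
  the reduction. Zero-persistence pairs are dropped from diagrams.

Correctness is established in the tests against an independent brute-force
oracle (full boundary-matrix reduction over GF(2) on ≤ 12-point clouds,
including tied and duplicated points) and the MST identity for TP_0.

## Higuchi fractal dimension

For a series X(1..T), the normalized curve length at lag k and offset m is

    L_m(k) = (T−1) / (⌊(T−m)/k⌋ · k²) · Σ_i |X(m+ik) − X(m+(i−1)k)|,

L(k) is the mean over m = 1..k, and the HFD is the OLS slope of log L(k)
on log(1/k) for k = 1..kmax (all integer lags, unweighted, natural logs).
Anchors: x(t) = t gives HFD = 1 exactly (L(k) = (T−1)/k is a closed form);
Brownian motion ≈ 1.5; white noise ≈ 2; fractional Brownian motion with
Hurst index H gives 2 − H. The estimator is affine-invariant. Degenerate
inputs (constant series, series shorter than 2·kmax + 1) raise errors
rather than returning NaN.

`kmax = 10` is the default. The TP curves this estimator is applied to
have 100-300 samples; with kmax = 10 every lag retains at least ~15
increments on a length-300 curve, and the calibration anchors above are
reproduced to within a few hundredths. Larger kmax starves the long lags
on curves this short; smaller kmax leaves too few points for a stable
log-log fit.

The box-counting dimension of a planar set is estimated on an axis-aligned
grid anchored at the bounding-box minimum (points on the far edge are
clamped into the last box; no grid-offset averaging), with D the OLS slope
of log N_r on log(1/r).

## The structural-break test

Given a TP curve of length n, deviations are taken from the *global*
sample mean (no windowing or trend removal): D(t) = TP(t) − mean(TP). The
CUSUM S(0) = 0, S(t) = S(t−1) + D(t) — the leading zero is included, so
the HFD estimator sees n + 1 points — starts and ends at zero by
construction. Under exchangeability of the deviations the CUSUM is a
random-walk bridge with HFD ≈ 1.5; a sustained mean shift produces a
smooth excursion with HFD near 1. The reference distribution is built from
B uniformly random permutations of the deviation values (B = 999 by
default; the p-value uses the add-one formula and ties count as extreme,
so p ∈ [1/(B+1), 1] and is never 0). The default alternative is the lower
tail; a two-sided option measures extremeness by |HFD − 1.5| for users who
also care about anti-persistent alternatives. When the full pipeline tests
k = 0, 1, 2 jointly, each dimension draws its permutations from an
independent stream spawned from the master seed, and no multiplicity
correction is applied by default (an optional Bonferroni flag multiplies
p by the number of tested dimensions).

Calibration, measured by the test suite: the null rejection rate at
α = 0.05 over 200 replicate length-300 curves stays inside the 99%
binomial band, the permuted-CUSUM HFD averages 1.5 within ±0.15, and a
3-standard-deviation mean shift over the middle third of a length-300
curve is detected (p ≤ 0.05) in ≥ 90% of replicates.

## Synthetic generators

The scenario generators produce 3-dimensional signals whose samples are
independent draws from a per-epoch pattern:

* `example1` — five 3,000-sample epochs at 100 Hz (window 50): Gaussian
  sd 1, circle radius 4, Gaussian, sphere radius 2.5, Gaussian.
* `example2` — three 5,000-sample epochs at 100 Hz (window 150):
  lemniscate, torus, spiral.

Manifold epochs carry additive isotropic Gaussian observation noise,
default sd 0.1, so the clouds are full-dimensional and H0 persistence is
non-degenerate; unit tests of algebraic invariants use noise 0. Sampling
densities are uniform in angle (circle, torus angles) or exactly uniform
(sphere via normalized Gaussian triples); the torus is therefore not
area-uniform — a documented simplification. The `example2` pattern
parameters are package defaults chosen so the torus epoch dominates both
TP_1 and TP_2: Gerono lemniscate scale 4 in the xy-plane, torus radii
R = 3, r = 1, conical spiral radius 0.5 → 4 over three turns with vertical
drift 2.

Univariate calibration processes: Brownian motion (cumulative N(0, dt)
increments from 0), white noise, the chirp x(t) = t·cos(t²/10), and
fractional Brownian motion by Davies-Harte circulant embedding — an
exact-covariance construction, verified in tests by the increment-variance
scaling Var[B_H(t+s) − B_H(t)] ∝ s^{2H}.

What these generators do *not* emulate: serial correlation within an
epoch (samples are i.i.d. given the pattern), cross-channel noise
correlation, smooth transitions between regimes, or 1/f-type spectra of
real electrophysiological recordings. Passing tests therefore demonstrate
that the pipeline detects changes in cloud geometry under clean regime
switches, not that it is calibrated for autocorrelated TP curves — with
strongly dependent windows the exchangeability assumption of the
permutation null weakens, which is one reason non-overlapping windows are
the default.

## A finding about the five-epoch scenario

With the printed pattern scales (Gaussian sd 1, circle radius 4, sphere
radius 2.5), the 0-dimensional curve breaks as strongly as the others:
TP_0 — the MST length of a 50-point cloud — has epoch means of roughly 35
(Gaussian), 26 (circle) and 40 (sphere) against a within-epoch sd of ~1.9.
All three observed CUSUM HFDs land near 1.07 or below, outside the entire
permutation reference, so all three p-values saturate at the floor
1/(B+1) and the dimensions cannot be ranked by p-value at B = 999. The
loop and cavity changes are detected exactly as intended; the scenario
simply also moves connectivity scale.

## Problem sizes

Default suite and script sizes were picked as desk-scale settings that
leave the estimates' sampling error well inside the assertion tolerances:
50 replicates of length 10,000 for the HFD anchors, 50 fBm paths of length
8,192, 200 null replicates at B = 199 for the type-I check, B = 999 for
single test runs, and the full 15,000-sample `example1` at homology
dimension 2. `example2` at dimension 2 (100 windows of 150 points) runs in
a few minutes end to end; the tests exercise it on one window per epoch.

## Known limitations

* Rips complexes only (no alpha or cubical complexes), Euclidean metric
  only, homology dimensions 0-2.
* The test detects the *presence* of a break, not its location; it is not
  sequential/online.
* Diagram values are exact for the given cloud, but reproducing another
  implementation's TP curves requires matching its cutoff convention for
  essential classes.
* The permutation null assumes exchangeable deviations; strong
  autocorrelation in TP curves (e.g. from overlapping windows) inflates
  the type-I error.
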