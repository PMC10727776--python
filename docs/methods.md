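# Methods

This note documents the models, the numerical choices, and what the
synthetic generators do and do not emulate. Everything quantitative stated
here is computed by the test suite or the analysis scripts.

## State-based dFC (point-based method)

Frames are standardized per subject and per region to mean 0, variance 1
(population convention), then concatenated across subjects. Standardizing
raw BOLD rather than applying a correlation-type variance-stabilizing
transform is deliberate: such transforms are defined for correlations, not
raw signals, so plain z-scoring is the well-defined reading of
"standardize before clustering".

K-means uses squared-Euclidean distortion, best of `n_init = 100`
repetitions with `max_iter = 100`. The elbow criterion returns the interior
`k` maximizing the discrete second difference `d(k−1) − 2d(k) + d(k+1)` of
the distortion curve, ties broken to the smallest `k`. This detector
responds to a *localized* curvature; a caveat documented by the simplex
design below.

**Canonical state ordering.** Cluster labels are arbitrary, so states are
relabeled by descending mean centroid activation over Zone II, then over
Zone I. The primary key is quantized to 0.5 z-units before sorting:
empirical Zone-II means of states with equal planted activation differ by
estimation noise, and without quantization the secondary key would never
engage, making labels unstable across seeds.

**State FC.** `FC^(λ)` is the Pearson correlation over frames assigned to
state `λ`. A region constant within a state (detected with a relative
tolerance of 1e−12, since floating-point "constant" series rarely have
exactly zero variance) has its correlations set to 0 with a warning —
degenerate inputs stay finite instead of propagating NaNs. States with
fewer than `n + 1` frames are flagged unreliable. Note that with imperfect
frame labels, `FC^(λ)` acquires a contamination bias of order
`ε·Δμ Δμᵀ` from mislabeled frames at distance `Δμ`; convergence to the
true state correlation therefore requires label accuracy, not just more
frames. Recovery tests evaluate `compute_state_fc` against ground-truth
labels for this reason.

**Dwell statistics.** Epochs are maximal constant-label runs; runs
truncated by session boundaries are included (an `--exclude-censored`
style exclusion would bias short sessions toward short dwells; with
per-subject sessions of ~208 frames and mean dwells of ~3 frames the
censoring effect is negligible).

## Temporal-network metrics

Binarization is strict (`weight > θ`), matching the "going above
threshold" reading; ties have measure zero on continuous weights. The
threshold grid spans the open interval (1 %, 10 %) of the maximum
off-diagonal FC entry, sampling the midpoints of `n` equal sub-intervals.

**Intercontact times.** The ICT sequence defaults to activation-epoch
durations (activation→offset distances); the classical gap convention is
available via `ict="gaps"`. Burstiness uses the population standard
deviation — `β` is a shape statistic of the duration distribution, and the
population convention makes `β = −1` exact for constant durations at any
sample size. `β` needs ≥ 2 epochs, memory ≥ 3 epochs with non-constant
durations; undefined values are reported missing, never as 0.

**Relative excess** is `100·(m_φ − m_ref)/|m_φ + m_ref|` per threshold,
with `m` a group median (mean available) of subject-level link-averaged
values. Per-threshold excess values are kept as replicates rather than
averaged, preserving dispersion for downstream tests.

## Graph efficiency

FC matrices are prepared by zeroing the diagonal and clipping negative
weights to 0 (shortest-path lengths require non-negative weights; an
absolute-value variant is exposed for sensitivity checks). Lengths are
`1/weight`; global efficiency is the mean inverse shortest-path distance
over ordered pairs (disconnected pairs contribute 0, Dijkstra via
`scipy.sparse.csgraph`). Local efficiency of a node is the global
efficiency of the subgraph induced on its positively-weighted neighbors,
keeping original weights — the neighborhood-subgraph variant standard in
brain-connectivity work; nodes with fewer than two neighbors contribute 0.

## Meta-connectivity

Windows of `ω = 5` frames (10 s at TR = 2 s) are stepped without overlap;
trailing remainder frames are dropped. `ω = 5` matches the fast intrinsic
timescale suggested by the state analysis (about 80 % of state epochs are
shorter than 5 frames on the default cohort). A window in which a region
is constant yields imputed-zero entries with a warning. MC is the Pearson
correlation between link series across windows; a zero-variance link
series zeroes its row/column (diagonal kept at 1). Group-level MC is the
entrywise mean of subject MCs; Fisher-z averaging is available.

**Signed Louvain.** `bctpy`-style community detection for signed networks
is implemented in-package: the modularity matrix is
`B = (W⁺ − γ k⁺k⁺ᵀ/v⁺)/v⁺ − (W⁻ − γ k⁻k⁻ᵀ/v⁻)/(v⁺ + v⁻)`, i.e. the
negative layer is down-weighted by the combined strength (the asymmetric
scaling: negative weights should discourage merging but not dominate).
`Q*` is the within-community sum of `B`. Optimization is greedy local
moving in seeded-random order plus aggregation, repeated to a fixed point,
best of 10 restarts. The MC diagonal is zeroed before community detection
(self-coupling is not a meta-link). At the default `Γ = 1.4` a uniform
all-positive matrix splits into singletons because the configuration null
exceeds the uniform weight; the single-module regime requires `Γ ≤ ~1`,
which is where the corresponding test operates.

**Participation** uses positive weights only (the coefficient is defined
for non-negative strengths; a signed variant uses absolute weights).
Isolated nodes are excluded from the mean with a warning.

**Meta-strengths.** The trimer sum is kept ordered — each unordered leaf
pair counts twice, the degenerate self-pair (the MC diagonal) is excluded;
this affects scale only, not orderings or signs. Tetramer sums are
restricted to vertex-disjoint partners: link pairs sharing a region are
trimers and would double-count. Trimer classes: within-zone (root and both
leaves in one zone), leaves-same-zone (leaves share a zone, root
elsewhere), leaves-two-zones. Tetramer classes keep only both-bases-within
and both-bases-between; mixed cases enter the unrestricted total only.
Genuinity is strict (`MC > FC`); the tetramer condition compares against
the base dimer `FC_ij` by default, with a `max(FC_ij, FC_mn)` variant.

## Synthetic generators

All generators are pure functions of (config, seed); every stage's
randomness derives from one master seed through named SHA-256 substreams.

**Two-zone state model** (`make_default_two_zone_model`). Sixteen regions,
10 ventral Zone I + 6 dorsal Zone II, TR 2 s, 208 frames/subject, four
Markov states with geometric dwell (self-transition `1 − 1/dwell_mean`,
default mean 3 frames, so ~80 % of epochs are shorter than 5 frames). The
four centroids sit at regular-simplex vertices spanned by the Zone-II
mean, Zone-I mean, and a within-Zone-I hemispheric contrast (amplitude 3.5
z-units per coordinate). The simplex is the geometry under which the
second-difference elbow detector is informative: equally separated
clusters drain distortion linearly until `k = K`, so the only curvature
spike sits at the planted count; centrosymmetric geometries (e.g. a ±cross)
put equal curvature at `k = 2` and are not identifiable by this detector.
Correlation structure per state: Zone-I internal synchrony 0.5 (high) or
0.3 (low) times a pair-proximity factor; Zone-II internal correlation 0.45,
raised in the Zone-II-active state and mildly negative (−0.15) in the
Zone-II-suppressed state; transient interzone coupling (0.24) in one
low-synchrony state only. Transitions follow a preferred cycle
(bias 0.95): multi-state activation epochs then have Erlang-like (low-CV)
durations, giving intrazone links a tonic profile (`β ≈ −0.35`) clearly
separated from the single-state interzone epochs (`β ≈ −0.10`) — the
zone contrast the temporal metrics are designed to detect. Amplitudes and
correlation levels were fixed at design time so that, at the default
cohort size (20 × 208), the elbow selects K = 4 and frame labels are
recovered with ARI > 0.95.

**Entangled model** (`make_default_entangled_model`). Star-shaped
modulators: modulator `m` switches the covariance between a Zone-II root
and three Zone-I leaves between −0.55 and +0.55 (sign of a slow sinusoid
plus AR(1) noise, period 80 frames). The square-wave sign profile
maximizes slow signal variance relative to the short-window correlation
noise (whose variance at ω = 5 is ≈ 0.25 at r = 0 — the binding constraint
on recoverable MC), keeps static root-leaf FC near zero, and leaves
leaf-leaf covariance exactly zero, so every root-sharing dimer pair is a
planted genuine trimer. Depth is PSD-bounded by `√k·depth < 1` for `k`
leaves; the generator Cholesky-checks every frame and raises on violation.

**Graded cohorts** (`generate_graded_cohorts`). Two interzone bundles
(Zone-II root + five Zone-I leaves) gated by binary renewal processes with
Gamma-distributed epoch durations, mean 10 frames. Across the four groups
the Gamma shape falls (20, 6, 2, 0.7 — duration CV 0.22 → 1.2), making
interzone activation epochs progressively more bursty, and the second gate
copies the first only during a deterministic agreement mask covering
(0.9, 0.65, 0.4, 0.15) of the session, decoupling the two bundles'
fluctuations. Group participation is scored against a *common* partition
of the pooled-cohort MC, so all groups are measured on the same module
scheme, and is strength-weighted to emphasize the meta-connected part of
the graph. Both knobs were fixed at design time.

**What the generators do not emulate**: hemodynamic convolution and its
regional variability, scanner and physiological noise spectra, motion
artifacts, spatial maps, inter-subject anatomical variability, and the
heavy-tailed, non-Gaussian features of real BOLD. Passing recovery tests
therefore shows that the estimators recover the quantities they define
under their own generative assumptions — not that those assumptions hold
in clinical data, where the original group effects cannot be reproduced
without the cohort.

## Group comparison

Two-sided Mann-Whitney U on subject-level aggregates, Bonferroni over an
explicitly declared comparison family (family sizes are an analysis
choice; forcing the caller to declare them keeps multiplicity control
reproducible). Group summaries are median ± MAD. At n = 15/group the exact
U test is conservative (achieved level ≈ 0.03 at nominal 0.05); the test
suite checks control, not exact attainment, of α, and detects a planted
bursty-vs-Poisson difference with power > 0.9 at that sample size.

## Problem sizes

Default analysis sizes — 20 × 208 frames (state arm), 10 × 2000 frames
(MC arm), 4 × 10 × 1000 (graded arm), 10⁵ draws for duration-law anchors,
and a 73-subject end-to-end run — were chosen so the full pipeline and
test suite complete in minutes on a single CPU while keeping Monte-Carlo
error well inside the asserted margins.

## Known limitations

- The elbow detector is geometry-dependent (see above); hierarchical or
  unequal-census state structures may defeat it even when k-means itself
  separates the states.
- MC magnitude at ω = 5 is bounded by window-estimation noise; absolute MC
  values are not comparable across window lengths.
- Trimer strengths use the ordered double-sum convention (×2 scale) —
  comparisons across packages must account for it.
- The exact down-weighting constant of the negative modularity layer
  varies across implementations; ours follows the asymmetric form above
  and is configurable in code.
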