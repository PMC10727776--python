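# metadfc

Dynamic functional connectivity (dFC) of resting-state BOLD signals on a
small two-zone limbic parcellation, analyzed with two complementary arms
and validated end-to-end on synthetic cohorts with known ground truth.

**Who it is for.** Researchers studying how the *temporal organization* of
interregional BOLD correlations — not just their time-averaged strength —
changes across clinical or cognitive groups (e.g., along a healthy-aging /
MCI / dementia spectrum), and who need a fully reproducible pipeline they
can exercise without access to clinical data.

## The two analysis arms

**State-based (point-based method).** All subjects' frames are z-scored
per region and concatenated, then clustered with k-means into `K`
activation states (elbow criterion on the distortion curve; best of 100
initializations). Each state `λ` gets an FC matrix `FC^(λ)` (Pearson
correlation over its frames), and each session becomes a temporal network
whose frame at time `t` carries the link weights of `FC^(λ(t))`. After
binarizing at a global threshold `θ` (swept over 1–10 % of the maximum FC
weight), each link's activation raster yields intercontact-time metrics:

- burstiness `β = (σ_τ − μ_τ)/(σ_τ + μ_τ)` over the activation-epoch
  durations (−1 periodic/tonic, 0 Poisson-like, → +1 bursty),
- mean activation `μ`, total active fraction `τ`, and the memory
  coefficient (lag-1 correlation of consecutive epoch durations).

Group contrasts are expressed as percent excess vs a reference group,
`%x_φ = 100·(x_φ − x_ref)/|x_φ + x_ref|`, pooled across thresholds.
Weighted global/local efficiency of each `FC^(λ)` summarizes state
topology.

**State-free (meta-connectivity).** A 5-frame window stepped without
overlap turns every region pair ("dimer") into a time series of windowed
correlations; the `l × l` correlation matrix between link series is the
meta-connectivity `MC`. Dimer pairs sharing a region are **trimers**
(shared region = root), vertex-disjoint pairs **tetramers**. The package
provides signed-network Louvain modularity (`Q*` with asymmetric negative
weighting, resolution `Γ = 1.4`), participation coefficients, root-pinned
trimer strengths `MC_j^(3) = Σ_{i,n} MC_(ij),(jn)`, base-pinned tetramer
strengths `MC_ij^(4)`, zone-class decompositions, and **genuinity** tests
(`MC_(ir),(jr) > FC_ij`: a higher-order coupling not explained by the
direct leaf-leaf dimer).

**Synthetic cohorts.** Because each analysis needs a recoverable answer,
the package generates: (i) Markov-switching multivariate-normal sessions
with four planted activation states crossing Zone-II activation with
Zone-I synchrony; (ii) sessions with slow covariance "modulators" that
plant MC modules and genuine trimers; (iii) four graded groups whose
interzone coupling becomes progressively more intermittent and decoupled.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_state_dfc.py
python analysis/03_temporal_metrics.py
python analysis/04_meta_connectivity.py
python analysis/05_group_gradient.py
```

Output of `02`–`05` on the default seeds:

```
elbow criterion selected K = 4 (planted K = 4)
frame-label recovery: adjusted Rand index = 0.990
mean dwell per state (frames): [3.0, 2.91, 2.87, 2.87]
epochs shorter than 5 frames: 81.0%

zone-class medians:
             beta       mu    tau
interzone  -0.233    5.211  0.495
intrazone  -0.354  208.000  1.000

Louvain (Gamma=1.4): planted-module ARI = 1.000
planted genuine trimers flagged: 6/6

group  beta_excess_interzone_pct  weighted_mean_participation
  SNC                    -16.031                        0.564
   NC                      0.000                        0.541
 aMCI                     19.380                        0.519
   AD                     39.349                        0.416
```

Reading this: the elbow criterion recovers the planted four states and
frame labels almost perfectly; dwell times match the generator's 3-frame
expectation. Interzone links are more intermittent than intrazone links
(higher `β`, lower `τ` and `μ`) — the direction the method is designed to
detect. The signed Louvain recovers the planted MC modules exactly and
every planted genuine trimer passes the genuinity test. On the graded
cohorts, interzone burstiness excess rises and MC participation falls
monotonically from the SNC-like to the AD-like group.

The same stages are available as a CLI (`metadfc simulate | states |
temporal-metrics | mc | report | run`); `metadfc run` executes everything
end-to-end, deterministically for a given seed, and writes a run manifest
with config hash and per-stage timings.

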