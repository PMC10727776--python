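"""Synthetic BOLD cohorts with known ground truth.

The clinical resting-state data this pipeline was designed around is not
redistributable, so every downstream stage is validated against synthetic
cohorts with a recoverable answer:

* ``make_default_two_zone_model`` / ``generate_bold_cohort`` — a Markov chain
  over K discrete activation states, each with its own mean-activation
  centroid and covariance, emulating the high/low activation x high/low
  Zone-I synchronization factorial of the state-based analyses (16 regions,
  TR = 2 s, ~208 frames per subject, short dwell times).
* ``generate_binary_train`` — toy link-activation rasters (periodic, Poisson,
  bursty) anchoring the burstiness coefficient.
* ``generate_entangled_bold`` — slow gain "modulators" applied to covariance
  blocks, planting correlated link fluctuations (meta-connectivity modules
  and genuine trimers).
* ``generate_graded_cohorts`` — four groups whose interzone coupling gate is
  made progressively more irregular and mutually decorrelated, yielding a
  known direction for burstiness excess and mean participation.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ZoneAtlas, default_limbic_atlas, link_index

__all__ = [
    "BoldSession",
    "StateGenConfig",
    "Modulator",
    "CouplingGenConfig",
    "make_default_two_zone_model",
    "make_default_entangled_model",
    "generate_state_sequence",
    "generate_bold_cohort",
    "generate_binary_train",
    "generate_entangled_bold",
    "generate_graded_cohorts",
    "write_cohort",
    "read_cohort",
]

GROUPS = ("SNC", "NC", "aMCI", "AD", "SYN")


@dataclass
class BoldSession:
    """One subject's parcellated BOLD acquisition (regions x frames)."""

    subject_id: str
    group: str
    tr_seconds: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("data must be a (n_regions, T>=2) matrix")
        if not np.isfinite(self.data).all():
            raise ValueError(f"session {self.subject_id}: non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class StateGenConfig:
    """Markov-switching multivariate-normal generator configuration.

    ``centroids`` are K x n mean activations (z-units), ``covariances``
    K x n x n symmetric PSD matrices, ``transition_matrix`` K x K
    row-stochastic. ``dwell_mean`` is the expected number of consecutive
    frames per state visit implied by the self-transition probabilities.
    """

    centroids: np.ndarray
    covariances: np.ndarray
    transition_matrix: np.ndarray
    dwell_mean: float
    atlas: ZoneAtlas = field(default_factory=default_limbic_atlas)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        K, n = self.centroids.shape
        if self.covariances.shape != (K, n, n):
            raise ValueError("covariances must be (K, n, n)")
        if self.transition_matrix.shape != (K, K):
            raise ValueError("transition_matrix must be (K, K)")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1")
        if (self.transition_matrix < -1e-12).any():
            raise ValueError("transition_matrix entries must be non-negative")
        if self.dwell_mean < 1:
            raise ValueError("dwell_mean must be >= 1")
        for k in range(K):
            cov = self.covariances[k]
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance of state {k + 1} is not symmetric")
            lo = np.linalg.eigvalsh(cov)[0]
            if lo < -1e-10:
                raise ValueError(
                    f"covariance of state {k + 1} is not PSD (min eigenvalue {lo:.3g})"
                )

    @property
    def n_states(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_regions(self) -> int:
        return self.centroids.shape[1]


def make_default_two_zone_model(
    n_zone1: int = 10,
    n_zone2: int = 6,
    sync_high: float = 0.5,
    sync_low: float = 0.3,
    act_amp: float = 3.5,
    dwell_mean: float = 3.0,
    zone2_corr: float = 0.45,
    cycle_bias: float = 0.95,
) -> StateGenConfig:
    """Four-state two-zone generator.

    The states cross {Zone-II above vs below average activation} with
    {Zone-I internal correlation = ``sync_high`` vs ``sync_low``}; the four
    centroids sit at the vertices of a regular simplex spanned by the
    Zone-II mean, the Zone-I mean and a within-Zone-I hemispheric contrast
    (coordinate signs per state: (+,-,-), (+,+,+), (-,+,-), (-,-,+)), so no
    coarser grouping of states is geometrically preferred. ``act_amp`` is
    the simplex radius per coordinate (z-units).

    Correlation structure (d = sync_high - sync_low):

    * Zone I internal: ``sync`` level times a pair-proximity factor (1 for
      homotopic same-structure pairs, 0.6 otherwise);
    * Zone II internal: ``zone2_corr`` everywhere, raised by d/2 in state 1
      (Zone II active, synchronized) and lowered by 3 d (floored at 0) in
      state 3 (Zone II suppressed and desynchronized) — the dips of
      cingulate links below threshold come from this state;
    * interzone: 1.2 d in state 1 only (zones transiently co-fluctuate when
      Zone II is active), 0 elsewhere.

    When ``sync_high == sync_low`` all four covariances coincide and the
    states differ only in activation.

    Transitions: self-transition 1 - 1/``dwell_mean``; of the remaining
    mass a fraction ``cycle_bias`` goes to the next state in the cycle
    1 -> 2 -> 3 -> 4 -> 1 (a preferred switching order), the rest spread
    uniformly. Stationary census stays uniform.
    """
    if not (0 <= sync_low <= sync_high < 1):
        raise ValueError("require 0 <= sync_low <= sync_high < 1")
    if n_zone1 < 2 or n_zone2 < 2:
        raise ValueError("each zone needs at least 2 regions")

    if n_zone1 == 10 and n_zone2 == 6:
        atlas = default_limbic_atlas()
    else:
        names = tuple(
            [f"Z1.{i}" for i in range(n_zone1)] + [f"Z2.{i}" for i in range(n_zone2)]
        )
        atlas = ZoneAtlas(names, tuple(["I"] * n_zone1 + ["II"] * n_zone2))
    n = n_zone1 + n_zone2
    z1 = atlas.zone_indices("I")
    z2 = atlas.zone_indices("II")

    K = 4
    # orthonormal centroid basis: Zone-II mean, Zone-I mean, Zone-I contrast
    e1 = np.zeros(n)
    e1[z2] = 1.0 / math.sqrt(len(z2))
    e2 = np.zeros(n)
    e2[z1] = 1.0 / math.sqrt(len(z1))
    e3 = np.zeros(n)
    half = len(z1) // 2
    e3[z1[:half]] = 1.0 / math.sqrt(len(z1))
    e3[z1[half:]] = -1.0 / math.sqrt(len(z1))
    # vertex signs listed in canonical order (Zone-II mean desc, then
    # Zone-I mean desc), matching the relabeling used after clustering
    signs = [(+1, +1, +1), (+1, -1, -1), (-1, +1, -1), (-1, -1, +1)]
    centroids = np.array(
        [act_amp * (x * e1 + y * e2 + h * e3) for x, y, h in signs]
    )

    # Zone-I pair-proximity factor: homotopic pairs tighter than the rest
    prox = np.full((n, n), 0.6)
    for a_i, a in enumerate(z1):
        for b_i, b in enumerate(z1):
            if abs(a_i - b_i) == 1 and min(a_i, b_i) % 2 == 0:
                prox[a, b] = 1.0

    d = sync_high - sync_low
    # state 2: Zone II active + synchronized + transient interzone coupling;
    # state 3: Zone II suppressed and mildly anti-synchronized (its links
    # dip decisively below any positive threshold)
    z2_floor = -0.8 / max(1, len(z2) - 1)
    z2_level = [
        zone2_corr,
        zone2_corr + 0.5 * d,
        max(z2_floor, zone2_corr - 3 * d),
        zone2_corr,
    ]
    inter_level = [0.0, 1.2 * d, 0.0, 0.0]
    sync_level = [sync_high, sync_low, sync_low, sync_high]

    covariances = np.empty((K, n, n))
    for k in range(K):
        inter_k = inter_level[k]
        for _attempt in range(30):
            corr = np.eye(n)
            for a in z1:
                for b in z1:
                    if a != b:
                        corr[a, b] = sync_level[k] * prox[a, b]
            for a in z2:
                for b in z2:
                    if a != b:
                        corr[a, b] = z2_level[k]
            for a in z1:
                corr[a, z2] = inter_k
                corr[z2, a] = inter_k
            lo = np.linalg.eigvalsh(corr)[0]
            if lo > 1e-10:
                break
            if inter_k == 0.0:
                break
            inter_k *= 0.8  # renormalize the interzone block to keep PSD
        if lo < 1e-10:
            raise ValueError(
                f"state {k + 1}: constructed covariance is not PSD "
                f"(min eigenvalue {lo:.3g})"
            )
        covariances[k] = corr

    p_stay = 1.0 - 1.0 / dwell_mean
    leave = 1.0 - p_stay
    succ = [2, 0, 3, 1]  # preferred switching cycle 2 -> 1 -> 3 -> 4 -> 2
    tm = np.zeros((K, K))
    for k in range(K):
        tm[k, k] = p_stay
        for j in range(K):
            if j != k:
                tm[k, j] = leave * (1.0 - cycle_bias) / (K - 1)
        tm[k, succ[k]] += leave * cycle_bias
    return StateGenConfig(centroids, covariances, tm, dwell_mean, atlas)


def generate_state_sequence(
    cfg: StateGenConfig, T: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample a length-T Markov state-label sequence (labels 1..K)."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    K = cfg.n_states
    tm = cfg.transition_matrix
    cum = np.cumsum(tm, axis=1)
    labels = np.empty(T, dtype=int)
    state = int(rng.integers(K))
    labels[0] = state + 1
    u = rng.random(T)
    for t in range(1, T):
        state = int(np.searchsorted(cum[state], u[t]))
        labels[t] = state + 1
    return labels


def generate_bold_cohort(
    cfg: StateGenConfig,
    n_subjects: int,
    T: int = 208,
    seed: int = 0,
    tr_seconds: float = 2.0,
    group: str = "SYN",
) -> tuple[list[BoldSession], list[np.ndarray]]:
    """Sample a cohort of Markov-switching MVN sessions.

    Frame ``t`` is drawn from N(centroid[s_t], covariance[s_t]). Returns the
    sessions and the per-subject ground-truth label sequences (1..K).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n = cfg.n_regions
    if n != cfg.atlas.n_regions:
        raise ValueError("config region count does not match its atlas")
    chols = np.array([np.linalg.cholesky(_jitter(cfg.covariances[k])) for k in range(cfg.n_states)])
    sessions, truths = [], []
    for s in range(n_subjects):
        labels = generate_state_sequence(cfg, T, rng)
        z = rng.standard_normal((T, n))
        data = np.empty((T, n))
        for k in range(cfg.n_states):
            m = labels == k + 1
            data[m] = z[m] @ chols[k].T + cfg.centroids[k]
        sessions.append(
            BoldSession(f"{group.lower()}{s:03d}", group, tr_seconds, data.T)
        )
        truths.append(labels)
    return sessions, truths


def _jitter(cov: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Tiny ridge so exactly-singular PSD matrices factorize."""
    return cov + eps * np.eye(cov.shape[0])


# ---------------------------------------------------------------------------
# Binary activation trains


def _draw_durations(kind: str, mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if kind == "periodic":
        return np.full(n, max(1, round(mean)), dtype=int)
    if kind == "poisson":
        # round-to-nearest keeps the mean/std ratio of the exponential law;
        # ceiling would bias the burstiness of mean-10 trains to ~ -0.025
        return np.maximum(1, np.rint(rng.exponential(mean, n))).astype(int)
    if kind == "bursty":
        # Pareto alpha=1.5: infinite variance, duration spread >> mean
        alpha = 1.5
        xm = mean * (alpha - 1) / alpha
        draws = xm / rng.random(n) ** (1 / alpha)
        return np.maximum(1, np.rint(draws)).astype(int)
    raise ValueError(f"unknown train kind {kind!r}")


def generate_binary_train(
    kind: str,
    length: int,
    params: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binary activation raster with controlled epoch-duration statistics.

    ``kind`` is one of ``periodic`` (constant epoch and gap durations),
    ``poisson`` (exponential epoch durations) or ``bursty`` (heavy-tailed
    epoch durations). ``params`` may set ``mean_duration`` and ``mean_gap``
    (frames; defaults 4 and 4).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    params = dict(params or {})
    mean_dur = float(params.pop("mean_duration", 4))
    mean_gap = float(params.pop("mean_gap", 4))
    if params:
        raise ValueError(f"unknown params {sorted(params)}")
    if mean_dur < 1 or mean_gap < 0.5 or mean_dur + mean_gap >= length:
        raise ValueError("parameters imply zero complete epochs in the train")
    rng = np.random.default_rng(seed)
    out = np.zeros(length, dtype=bool)
    # over-draw durations then lay epochs/gaps alternately until the end
    n_guess = max(8, int(2 * length / (mean_dur + mean_gap)) + 8)
    t = 0
    while t < length:
        durs = _draw_durations(kind, mean_dur, n_guess, rng)
        gaps = np.maximum(1, np.rint(rng.exponential(mean_gap, n_guess))).astype(int) \
            if kind != "periodic" else np.full(n_guess, max(1, round(mean_gap)), dtype=int)
        for d, g in zip(durs, gaps):
            out[t : t + int(d)] = True
            t += int(d) + int(g)
            if t >= length:
                break
    return out


# ---------------------------------------------------------------------------
# Entangled (meta-connectivity) generator


@dataclass
class Modulator:
    """Slow on/off gain process switching a set of covariance entries.

    The latent is a sinusoid of ``period_frames`` plus AR(1) noise of
    standard deviation ``noise_sd``; the gain is its sign, so the affected
    region-pair covariances alternate between -``depth`` and +``depth``.
    The square-wave sign profile maximizes the slow variance of the
    windowed correlations relative to their short-window estimation noise,
    and leaves the time-averaged (static) FC of the modulated dimers near
    zero.
    """

    links: tuple[tuple[int, int], ...]
    depth: float = 0.55
    period_frames: float = 80.0
    phase: float = 0.0
    noise_sd: float = 0.2

    def gain(self, T: int, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(T)
        lat = np.sin(2 * np.pi * t / self.period_frames + self.phase)
        lat = lat + self.noise_sd * _ar1(T, 0.8, rng)
        return np.where(lat > 0, 1.0, -1.0)


@dataclass
class CouplingGenConfig:
    """Entangled-dimer generator configuration."""

    modulators: tuple[Modulator, ...]
    baseline_cov: np.ndarray
    atlas: ZoneAtlas = field(default_factory=default_limbic_atlas)

    def __post_init__(self) -> None:
        if len(self.modulators) < 1:
            raise ValueError("at least one modulator required")
        self.baseline_cov = np.asarray(self.baseline_cov, dtype=float)
        n = self.atlas.n_regions
        if self.baseline_cov.shape != (n, n):
            raise ValueError("baseline_cov must match the atlas size")
        for m in self.modulators:
            for (i, j) in m.links:
                if not (0 <= i < n and 0 <= j < n and i != j):
                    raise ValueError(f"modulator link ({i},{j}) invalid")


def make_default_entangled_model(
    atlas: ZoneAtlas | None = None,
    n_modulators: int = 2,
    leaves_per_root: int = 3,
    depth: float = 0.55,
    period_frames: float = 80.0,
) -> CouplingGenConfig:
    """Star-shaped modulators on an independent-noise baseline.

    Modulator ``m`` drives the dimers from root region ``m`` (Zone II if
    available) to ``leaves_per_root`` distinct Zone-I leaves, with disjoint
    leaf sets across modulators. Because only root-leaf covariances are
    modulated, the leaf-leaf static correlation stays near zero and every
    root-sharing dimer pair is a planted *genuine* trimer.
    """
    atlas = atlas or default_limbic_atlas()
    z1 = list(atlas.zone_indices("I"))
    z2 = list(atlas.zone_indices("II"))
    if n_modulators * leaves_per_root > len(z1) or n_modulators > len(z2):
        raise ValueError("not enough regions for the requested modulators")
    mods = []
    for m in range(n_modulators):
        root = z2[m]
        leaves = z1[m * leaves_per_root : (m + 1) * leaves_per_root]
        links = tuple((min(root, lf), max(root, lf)) for lf in leaves)
        mods.append(
            Modulator(
                links=links,
                depth=depth,
                period_frames=period_frames,
                phase=2 * np.pi * m / max(1, n_modulators) + 0.7,
            )
        )
    return CouplingGenConfig(tuple(mods), np.eye(atlas.n_regions), atlas)


def generate_entangled_bold(
    cfg: CouplingGenConfig,
    n_subjects: int,
    T: int = 2000,
    seed: int = 0,
    tr_seconds: float = 2.0,
    group: str = "SYN",
) -> tuple[list[BoldSession], dict]:
    """Sample sessions whose link fluctuations carry planted meta-connectivity.

    Frame ``t`` is drawn from N(0, Sigma(t)) with Sigma(t) = baseline plus,
    for each modulator, ``depth * gain(t)`` added to its affected
    off-diagonal entries. Returns the sessions plus a ground-truth dict with
    the planted module membership (link id -> module index) and the planted
    genuine trimers (root, leaf_a, leaf_b).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n = cfg.atlas.n_regions
    lidx = link_index(n)

    modules: dict[int, int] = {}
    trimers: list[tuple[int, int, int]] = []
    for m_id, mod in enumerate(cfg.modulators):
        for (i, j) in mod.links:
            modules[lidx[(i, j)]] = m_id
        # root = region common to the modulator's links (if any)
        regs = [set(l) for l in mod.links]
        common = set.intersection(*regs) if regs else set()
        if len(common) == 1:
            root = common.pop()
            leaves = sorted(set(r for l in mod.links for r in l) - {root})
            for a_i in range(len(leaves)):
                for b_i in range(a_i + 1, len(leaves)):
                    trimers.append((root, leaves[a_i], leaves[b_i]))

    sessions = []
    for s in range(n_subjects):
        gains = np.stack([mod.gain(T, rng) for mod in cfg.modulators])
        data = np.empty((T, n))
        zs = rng.standard_normal((T, n))
        for t in range(T):
            sigma = cfg.baseline_cov.copy()
            for m_id, mod in enumerate(cfg.modulators):
                g = mod.depth * gains[m_id, t]
                for (i, j) in mod.links:
                    sigma[i, j] += g
                    sigma[j, i] += g
            try:
                chol = np.linalg.cholesky(_jitter(sigma, 1e-9))
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"instantaneous covariance not PSD at frame {t}"
                ) from exc
            data[t] = chol @ zs[t]
        sessions.append(
            BoldSession(f"{group.lower()}{s:03d}", group, tr_seconds, data.T)
        )
    truth = {
        "modules": {int(k): int(v) for k, v in modules.items()},
        "genuine_trimers": [tuple(int(x) for x in tr) for tr in trimers],
    }
    return sessions, truth


# ---------------------------------------------------------------------------
# Graded-intermittency cohorts (four groups, two monotone knobs)

GRADED_GROUPS = ("SNC", "NC", "aMCI", "AD")
GRADED_SHAPES = (20.0, 6.0, 2.0, 0.7)  # Gamma shape of gate epoch durations
GRADED_AGREEMENT = (0.9, 0.65, 0.4, 0.15)  # fraction of time gates agree
_GATE_MEAN_EPOCH = 10.0
_AGREE_BLOCK = 100
_BUNDLE_CORR = 0.6
_BUNDLE_ACT = 1.5


def _ar1(T: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    x = np.empty(T)
    x[0] = rng.standard_normal()
    eps = rng.standard_normal(T) * math.sqrt(1 - phi**2)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def _renewal_gate(
    T: int, shape: float, mean_epoch: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary renewal gate: ON/OFF durations ~ Gamma(shape, mean_epoch).

    The duration coefficient of variation is 1/sqrt(shape), so small
    shapes give bursty, irregular gating and large shapes near-periodic
    gating at the same mean epoch length.
    """
    out = np.empty(T, dtype=bool)
    state = bool(rng.integers(2))
    t = 0
    while t < T:
        d = max(1, int(round(rng.gamma(shape, mean_epoch / shape))))
        out[t : t + d] = state
        state = not state
        t += d
    return out


def generate_graded_cohorts(
    n_subjects_per_group: int = 10,
    T: int = 1000,
    seed: int = 0,
    tr_seconds: float = 2.0,
    atlas: ZoneAtlas | None = None,
) -> tuple[list[BoldSession], dict]:
    """Four groups with increasingly intermittent interzone coupling.

    Two interzone "bundles" (a Zone-II root plus five Zone-I leaves each)
    are switched on and off by binary renewal gates; a gate that is ON
    raises the bundle regions' mean activation and couples them through a
    shared factor. Across the groups SNC -> NC -> aMCI -> AD two things
    degrade together:

    * gate epoch durations go from near-periodic to heavy-tailed (Gamma
      shapes ``GRADED_SHAPES``), so interzone link activation becomes more
      bursty;
    * the two bundle gates decouple (the second gate copies the first
      during a deterministic agreement mask covering ``GRADED_AGREEMENT``
      of the session, and follows an independent renewal gate elsewhere),
      so the meta-connectivity between the two bundles' link fluctuations
      weakens.

    Ground truth records the bundle link sets and per-subject gate traces.
    """
    atlas = atlas or default_limbic_atlas()
    rng = np.random.default_rng(seed)
    n = atlas.n_regions
    z1 = list(atlas.zone_indices("I"))
    z2 = list(atlas.zone_indices("II"))
    bundle_a = [z2[0]] + z1[:5]
    bundle_b = [z2[1]] + z1[5:10]
    lidx = link_index(n)
    links_a = [lidx[tuple(sorted((bundle_a[0], r)))] for r in bundle_a[1:]]
    links_b = [lidx[tuple(sorted((bundle_b[0], r)))] for r in bundle_b[1:]]

    sessions: list[BoldSession] = []
    gate_truth: dict[str, dict] = {}
    for grp, shape, agree in zip(GRADED_GROUPS, GRADED_SHAPES, GRADED_AGREEMENT):
        for s in range(n_subjects_per_group):
            gate_a = _renewal_gate(T, shape, _GATE_MEAN_EPOCH, rng)
            indep = _renewal_gate(T, shape, _GATE_MEAN_EPOCH, rng)
            mask = (np.arange(T) % _AGREE_BLOCK) < agree * _AGREE_BLOCK
            gate_b = np.where(mask, gate_a, indep)
            data = rng.standard_normal((T, n))
            fac_a = rng.standard_normal(T)
            fac_b = rng.standard_normal(T)
            c = math.sqrt(_BUNDLE_CORR)
            for r in bundle_a:
                data[:, r] += gate_a * (c * fac_a + _BUNDLE_ACT)
            for r in bundle_b:
                data[:, r] += gate_b * (c * fac_b + _BUNDLE_ACT)
            sid = f"{grp.lower()}{s:03d}"
            sessions.append(BoldSession(sid, grp, tr_seconds, data.T))
            gate_truth[sid] = {
                "gate_a": gate_a.astype(int).tolist(),
                "gate_b": gate_b.astype(int).tolist(),
            }
    truth = {
        "groups": list(GRADED_GROUPS),
        "shapes": list(GRADED_SHAPES),
        "agreement": list(GRADED_AGREEMENT),
        "links_a": [int(l) for l in links_a],
        "links_b": [int(l) for l in links_b],
        "gates": gate_truth,
    }
    return sessions, truth


# ---------------------------------------------------------------------------
# Cohort I/O (one TSV per subject + manifest + atlas + ground truth)


def write_cohort(
    sessions: list[BoldSession],
    atlas: ZoneAtlas,
    out_dir: str | Path,
    ground_truth: dict | None = None,
) -> Path:
    """Write subject TSVs, a cohort manifest CSV, the atlas TSV and an
    optional ground-truth JSON. Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sessions:
        path = out_dir / f"{s.subject_id}.tsv"
        df = pd.DataFrame(s.data, index=list(atlas.region_names))
        df.to_csv(path, sep="\t", header=False, float_format="%.6f")
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "tr_seconds": s.tr_seconds,
                "path": path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    atlas.write_tsv(out_dir / "atlas.tsv")
    if ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(_jsonable(ground_truth), fh)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_cohort(manifest_path: str | Path) -> tuple[list[BoldSession], ZoneAtlas]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    man = pd.read_csv(manifest_path)
    atlas = ZoneAtlas.read_tsv(base / "atlas.tsv")
    sessions = []
    for _, row in man.iterrows():
        path = base / row["path"]
        if not path.exists():
            raise FileNotFoundError(f"subject file missing: {path}")
        data = pd.read_csv(path, sep="\t", header=None, index_col=0).to_numpy(float)
        sessions.append(
            BoldSession(str(row["subject_id"]), str(row["group"]), float(row["tr_seconds"]), data)
        )
    return sessions, atlas
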