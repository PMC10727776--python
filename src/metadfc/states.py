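"""State-based dynamic functional connectivity (point-based method).

BOLD frames from all subjects are standardized per subject/region,
concatenated, and clustered with k-means into K activation states. Each
state gets a state-specific FC matrix (Pearson correlation over the frames
assigned to it), and each session becomes a temporal network whose frame at
time t carries the link weights of the FC matrix of the state visited at t.
Dwell-time and census statistics summarize state switching per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .atlas import ZoneAtlas, link_pairs
from .synth import BoldSession

__all__ = [
    "FrameMatrix",
    "StateModel",
    "StateStats",
    "TemporalNetwork",
    "standardize_and_concatenate",
    "select_k_elbow",
    "fit_states",
    "compute_state_fc",
    "state_statistics",
    "build_temporal_network",
    "run_lengths",
]


@dataclass
class FrameMatrix:
    """T_total x n standardized activation frames with subject boundaries."""

    frames: np.ndarray
    subject_ids: list[str]
    boundaries: list[tuple[int, int]]  # half-open [start, stop) per subject
    groups: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.frames.shape[1]

    def per_subject(self, values: np.ndarray) -> list[np.ndarray]:
        """Split a length-T_total vector back into per-subject pieces."""
        return [values[a:b] for a, b in self.boundaries]


def standardize_and_concatenate(sessions: list[BoldSession]) -> FrameMatrix:
    """Per-subject, per-region z-scoring (population variance), then
    temporal concatenation into a T_total x n frame matrix."""
    if not sessions:
        raise ValueError("no sessions given")
    n = sessions[0].n_regions
    blocks, bounds, ids, groups = [], [], [], []
    t0 = 0
    for s in sessions:
        if s.n_regions != n:
            raise ValueError(f"session {s.subject_id}: region count mismatch")
        x = s.data.T.astype(float)  # T x n
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population convention (ddof=0)
        zero = np.flatnonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0)))
        if zero.size:
            raise ValueError(
                f"session {s.subject_id}: region index {int(zero[0])} has zero variance"
            )
        blocks.append((x - mu) / sd)
        bounds.append((t0, t0 + x.shape[0]))
        t0 += x.shape[0]
        ids.append(s.subject_id)
        groups.append(s.group)
    return FrameMatrix(np.vstack(blocks), ids, bounds, groups)


@dataclass
class StateModel:
    """K-means state model: centroids, per-state FC, per-subject labels."""

    K: int
    centroids: np.ndarray  # K x n, canonical order
    state_fc: np.ndarray  # K x n x n correlation matrices
    labels: list[np.ndarray]  # per subject, values 1..K
    subject_ids: list[str]
    groups: list[str]
    distortion: float
    distortion_by_k: dict[int, float] = field(default_factory=dict)
    unreliable_states: tuple[int, ...] = ()  # states with < n+1 frames


def _distortion_curve(
    frames: np.ndarray, k_values: list[int], seed: int, n_init: int, max_iter: int
) -> dict[int, float]:
    out = {}
    for k in k_values:
        km = KMeans(
            n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed
        ).fit(frames)
        out[k] = float(km.inertia_)
    return out


def select_k_elbow(
    frames: FrameMatrix,
    k_range: tuple[int, int] = (1, 8),
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
) -> tuple[int, dict[int, float]]:
    """Elbow criterion on the k-means distortion curve.

    Returns the interior k maximizing the discrete second difference
    d(k-1) - 2 d(k) + d(k+1) (ties broken to the smallest k), together with
    the full distortion curve.
    """
    lo, hi = int(k_range[0]), int(k_range[1])
    ks = list(range(lo, hi + 1))
    if len(ks) < 3:
        raise ValueError("k_range must span at least 3 values")
    if hi > frames.frames.shape[0]:
        raise ValueError("k_range exceeds the number of frames")
    curve = _distortion_curve(frames.frames, ks, seed, n_init, max_iter)
    return elbow_from_curve(curve), curve


def elbow_from_curve(curve: dict[int, float]) -> int:
    """Max-second-difference elbow of a distortion curve; smallest-k ties."""
    ks = sorted(curve)
    d = np.array([curve[k] for k in ks])
    if (np.diff(d) > 1e-9 * max(1.0, abs(d[0]))).any():
        warnings.warn("distortion curve is not monotonically decreasing")
    second = d[:-2] - 2 * d[1:-1] + d[2:]
    best = int(np.argmax(np.round(second, 12)))  # first (smallest k) argmax
    return ks[1 + best]


def fit_states(
    frames: FrameMatrix,
    K: int,
    n_init: int = 100,
    max_iter: int = 100,
    seed: int = 0,
    atlas: ZoneAtlas | None = None,
) -> StateModel:
    """Best-of-``n_init`` k-means on the concatenated frames.

    States are relabeled canonically — descending mean centroid activation
    over Zone II, then over Zone I (overall mean when no atlas is given) —
    so labels are stable across runs and seeds.
    """
    X = frames.frames
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > np.unique(X, axis=0).shape[0]:
        raise ValueError("K exceeds the number of distinct frames")
    km = KMeans(n_clusters=K, n_init=n_init, max_iter=max_iter, random_state=seed).fit(X)
    order = _canonical_order(km.cluster_centers_, atlas)
    rank = np.empty(K, dtype=int)
    rank[order] = np.arange(K)
    centroids = km.cluster_centers_[order]
    flat = rank[km.labels_] + 1  # 1..K
    state_fc, unreliable = compute_state_fc(frames, frames.per_subject(flat))
    return StateModel(
        K=K,
        centroids=centroids,
        state_fc=state_fc,
        labels=frames.per_subject(flat),
        subject_ids=list(frames.subject_ids),
        groups=list(frames.groups),
        distortion=float(km.inertia_),
        unreliable_states=unreliable,
    )


def _canonical_order(centroids: np.ndarray, atlas: ZoneAtlas | None) -> np.ndarray:
    if atlas is not None and atlas.n_regions == centroids.shape[1]:
        z2 = atlas.zone_indices("II")
        z1 = atlas.zone_indices("I")
        key2 = centroids[:, z2].mean(axis=1)
        key1 = centroids[:, z1].mean(axis=1)
    else:
        key2 = centroids.mean(axis=1)
        key1 = np.zeros(centroids.shape[0])
    # sort by descending Zone-II mean, then descending Zone-I mean; the
    # primary key is quantized to 0.5 z-units so that states with equal
    # planted Zone-II activation tie robustly and fall through to Zone I
    key2_coarse = np.round(2 * key2) / 2
    return np.lexsort((-key1, -key2_coarse))


def compute_state_fc(
    frames: FrameMatrix, labels: list[np.ndarray]
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Pearson FC per state over the frames assigned to it.

    A region constant within a state gets zero correlations (warning).
    Returns (K x n x n array, tuple of unreliable state labels — states with
    fewer than n + 1 frames).
    """
    flat = np.concatenate(labels)
    if flat.shape[0] != frames.frames.shape[0]:
        raise ValueError("labels do not tile the frame matrix")
    K = int(flat.max())
    n = frames.n_regions
    fcs = np.empty((K, n, n))
    unreliable = []
    for k in range(1, K + 1):
        X = frames.frames[flat == k]
        if X.shape[0] < 3:
            raise ValueError(f"state {k} has fewer than 3 frames")
        if X.shape[0] < n + 1:
            unreliable.append(k)
        sd = X.std(axis=0)
        const = sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
        if const.any():
            warnings.warn(
                f"state {k}: {int(const.sum())} constant region(s); correlations set to 0"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = np.corrcoef(X.T)
        fc[np.isnan(fc)] = 0.0
        np.fill_diagonal(fc, 1.0)
        fcs[k - 1] = np.clip((fc + fc.T) / 2, -1.0, 1.0)
    return fcs, tuple(unreliable)


def run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, lengths) of the maximal constant runs of a sequence."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return np.array([]), np.array([], dtype=int)
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [seq.size]))
    return seq[starts], stops - starts


@dataclass
class StateStats:
    """Tidy per-subject-per-state dwell/census table + pooled epochs."""

    table: pd.DataFrame  # subject, group, state, mean_dwell, census, n_epochs
    epoch_durations: np.ndarray  # pooled over subjects and states

    def epoch_fraction_below(self, frames: int) -> float:
        """Fraction of pooled epochs strictly shorter than ``frames``."""
        return float((self.epoch_durations < frames).mean())


def state_statistics(
    labels: list[np.ndarray],
    subject_ids: list[str] | None = None,
    groups: list[str] | None = None,
    K: int | None = None,
) -> StateStats:
    """Dwell-time and census statistics from per-subject label sequences.

    Epochs are maximal runs of a constant label (runs truncated by session
    boundaries included). ``census`` is the fraction of frames in each
    state; unvisited states get census 0 and missing mean_dwell.
    """
    subject_ids = subject_ids or [f"sub{i:03d}" for i in range(len(labels))]
    groups = groups or ["SYN"] * len(labels)
    K = K or int(max(l.max() for l in labels))
    rows = []
    pooled = []
    for sid, grp, seq in zip(subject_ids, groups, labels):
        if len(seq) == 0:
            raise ValueError(f"subject {sid}: empty label sequence")
        vals, lens = run_lengths(seq)
        pooled.append(lens)
        T = len(seq)
        for k in range(1, K + 1):
            m = vals == k
            durs = lens[m]
            rows.append(
                {
                    "subject": sid,
                    "group": grp,
                    "state": k,
                    "mean_dwell": float(durs.mean()) if durs.size else np.nan,
                    "census": float(durs.sum() / T),
                    "n_epochs": int(durs.size),
                }
            )
    return StateStats(pd.DataFrame(rows), np.concatenate(pooled))


@dataclass
class TemporalNetwork:
    """Per-subject l x T link-weight arrays driven by state switching."""

    link_pairs: np.ndarray  # l x 2 region indices (i < j)
    weights: list[np.ndarray]  # per subject, l x T
    subject_ids: list[str]
    groups: list[str]
    state_link_weights: np.ndarray  # K x l upper-triangular FC values

    @property
    def n_links(self) -> int:
        return self.link_pairs.shape[0]


def build_temporal_network(model: StateModel, labels: list[np.ndarray] | None = None) -> TemporalNetwork:
    """Assign to every frame the link weights of its state's FC matrix."""
    labels = labels if labels is not None else model.labels
    n = model.state_fc.shape[1]
    iu = np.triu_indices(n, k=1)
    state_w = np.stack([fc[iu] for fc in model.state_fc])  # K x l
    weights = []
    for seq in labels:
        if seq.min() < 1 or seq.max() > model.K:
            raise ValueError("labels outside 1..K")
        weights.append(state_w[seq - 1].T.copy())  # l x T
    return TemporalNetwork(
        link_pairs=link_pairs(n),
        weights=weights,
        subject_ids=list(model.subject_ids),
        groups=list(model.groups),
        state_link_weights=state_w,
    )
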