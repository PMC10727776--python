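"""State-free dynamic functional connectivity: meta-connectivity.

A short non-overlapping window (default 5 frames) is slid over each
session; within every window a Pearson FC matrix is computed, giving each
of the l = n(n-1)/2 links a time series of windowed strengths (the dFC
stream). The meta-connectivity (MC) matrix is the l x l Pearson
correlation between link time series: entry (ij),(mn) quantifies the
entanglement of the two dimers. Dimer pairs sharing a region are trimers
(shared region = root, others = leaves); vertex-disjoint pairs are
tetramers.

The module also provides the signed-Louvain partition of MC with the
asymmetric modularity Q*, participation coefficients, dimer / root-pinned
trimer / base-pinned tetramer strengths split by zone class, genuinity
tests (higher-order coupling exceeding the corresponding static dimer),
and FC-MC coupling correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import (
    ZoneAtlas,
    classify_link,
    classify_tetramer,
    classify_trimer,
    link_index,
    link_pairs,
    zone_class_per_link,
)
from .louvain import signed_louvain
from .synth import BoldSession

__all__ = [
    "DfcStream",
    "MetaConnectivity",
    "McPartition",
    "compute_dfc_stream",
    "compute_mc",
    "partition_mc",
    "participation_coefficients",
    "dimer_strengths",
    "trimer_strengths",
    "tetramer_strengths",
    "genuinity",
    "fc_mc_coupling",
    "static_fc",
]


@dataclass
class DfcStream:
    """l x W windowed link-correlation series for one subject."""

    omega: int
    step: int
    series: np.ndarray  # l x W
    subject_id: str = ""
    group: str = ""

    @property
    def n_windows(self) -> int:
        return self.series.shape[1]


def compute_dfc_stream(
    session: BoldSession, omega: int = 5, step: int | None = None
) -> DfcStream:
    """Windowed Pearson correlations of every region pair.

    Windows of ``omega`` frames are stepped by ``step`` (default: no
    overlap); trailing remainder frames are dropped. A window in which a
    region is constant yields zero entries for that region's links
    (imputed, with a warning).
    """
    if omega < 3:
        raise ValueError("omega must be >= 3 (correlation ill-posed below)")
    step = omega if step is None else int(step)
    if step < 1:
        raise ValueError("step must be >= 1")
    x = session.data  # n x T
    n, T = x.shape
    if T < omega:
        raise ValueError("session shorter than one window")
    starts = range(0, T - omega + 1, step)
    iu = np.triu_indices(n, k=1)
    cols = []
    n_imputed = 0
    for s0 in starts:
        win = x[:, s0 : s0 + omega]
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(win)
        bad = ~np.isfinite(c)
        const = _constant_rows(win)
        if const.size:
            bad[const, :] = True
            bad[:, const] = True
        if bad[iu].any():
            n_imputed += int(bad[iu].sum())
            c[bad] = 0.0
        cols.append(c[iu])
    if n_imputed:
        warnings.warn(
            f"{session.subject_id}: {n_imputed} undefined window correlations imputed as 0"
        )
    return DfcStream(
        omega=omega,
        step=step,
        series=np.column_stack(cols),
        subject_id=session.subject_id,
        group=session.group,
    )


@dataclass
class MetaConnectivity:
    """l x l link-link correlation matrix with zone bookkeeping."""

    mc: np.ndarray
    atlas: ZoneAtlas
    link_pairs: np.ndarray = field(init=False)
    zone_class: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc, dtype=float)
        l = self.atlas.n_links
        if self.mc.shape != (l, l):
            raise ValueError(f"mc must be {l} x {l} for this atlas")
        self.link_pairs = link_pairs(self.atlas.n_regions)
        self.zone_class = zone_class_per_link(self.atlas)


def _constant_rows(X: np.ndarray) -> np.ndarray:
    """Indices of rows that are constant up to floating-point noise."""
    sd = X.std(axis=1)
    scale = np.maximum(1.0, np.abs(X).max(axis=1))
    return np.flatnonzero(sd <= 1e-12 * scale)


def _corr_with_zero_variance(X: np.ndarray) -> np.ndarray:
    """Row-wise correlation; zero-variance rows get zero rows/cols, unit diag."""
    flat = _constant_rows(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(X)
    if flat.size:
        warnings.warn(
            f"{flat.size} link series with zero variance; MC rows set to 0"
        )
        c[flat, :] = 0.0
        c[:, flat] = 0.0
    c[np.isnan(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip((c + c.T) / 2, -1.0, 1.0)


def compute_mc(
    streams: DfcStream | list[DfcStream],
    atlas: ZoneAtlas,
    pooling: str = "group-average",
    fisher_z: bool = False,
) -> MetaConnectivity | list[MetaConnectivity]:
    """Meta-connectivity from one or more dFC streams.

    For a list of streams, ``pooling='per-subject'`` returns one MC per
    stream while ``'group-average'`` averages the subject MCs entrywise
    (optionally through Fisher's z transform).
    """
    if isinstance(streams, DfcStream):
        if streams.n_windows < 3:
            raise ValueError("need at least 3 windows")
        return MetaConnectivity(_corr_with_zero_variance(streams.series), atlas)
    mcs = [compute_mc(s, atlas) for s in streams]
    if pooling == "per-subject":
        return mcs
    if pooling != "group-average":
        raise ValueError("pooling must be 'per-subject' or 'group-average'")
    stack = np.stack([m.mc for m in mcs])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -0.999999, 0.999999)).mean(axis=0)
        avg = np.tanh(z)
    else:
        avg = stack.mean(axis=0)
    np.fill_diagonal(avg, 1.0)
    return MetaConnectivity(avg, atlas)


@dataclass
class McPartition:
    """Signed-Louvain partition of the MC graph."""

    labels: np.ndarray  # per link-node, 1..M
    gamma: float
    q_star: float

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())


def partition_mc(
    mc: MetaConnectivity,
    gamma: float = 1.4,
    seed: int = 0,
    restarts: int = 10,
) -> McPartition:
    """Signed-network Louvain partition of MC (diagonal excluded)."""
    W = mc.mc.copy()
    if not np.isfinite(W).all():
        raise ValueError("MC contains non-finite entries")
    np.fill_diagonal(W, 0.0)
    labels, q = signed_louvain(W, gamma=gamma, seed=seed, restarts=restarts)
    return McPartition(labels=labels, gamma=gamma, q_star=q)


def participation_coefficients(
    mc: MetaConnectivity,
    partition: McPartition,
    signed: bool = False,
) -> tuple[np.ndarray, float]:
    """Participation coefficient P_i = 1 - sum_m (kappa_im / kappa_i)^2.

    Computed on positive MC weights by default (``signed=True`` uses
    absolute weights). Isolated nodes (zero strength) get NaN and are
    excluded from the mean (with a warning).
    """
    W = mc.mc.copy()
    np.fill_diagonal(W, 0.0)
    W = np.abs(W) if signed else np.where(W > 0, W, 0.0)
    labels = partition.labels
    if labels.shape[0] != W.shape[0]:
        raise ValueError("partition does not cover all link-nodes")
    kappa = W.sum(axis=1)
    P = np.full(W.shape[0], np.nan)
    mods = np.unique(labels)
    km = np.stack([W[:, labels == m].sum(axis=1) for m in mods], axis=1)
    ok = kappa > 0
    P[ok] = 1.0 - ((km[ok] / kappa[ok, None]) ** 2).sum(axis=1)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} isolated link-node(s) excluded from mean")
    return P, float(np.nanmean(P))


def static_fc(session: BoldSession) -> np.ndarray:
    """Whole-session Pearson FC matrix of one subject."""
    return np.corrcoef(session.data)


def dimer_strengths(fc: np.ndarray, atlas: ZoneAtlas) -> pd.DataFrame:
    """Per-region FC strength split into intrazone and interzone sums
    (self term excluded)."""
    fc = np.asarray(fc, dtype=float)
    n = atlas.n_regions
    if fc.shape != (n, n):
        raise ValueError("fc does not match the atlas")
    rows = []
    for r in range(n):
        intra = inter = 0.0
        for i in range(n):
            if i == r:
                continue
            if classify_link(atlas, r, i) == "intrazone":
                intra += fc[r, i]
            else:
                inter += fc[r, i]
        rows.append(
            {
                "region": atlas.region_names[r],
                "region_idx": r,
                "intrazone": intra,
                "interzone": inter,
                "total": intra + inter,
            }
        )
    return pd.DataFrame(rows)


TRIMER_CLASSES = ("within-zone", "leaves-same-zone", "leaves-two-zones")
TETRAMER_CLASSES = ("base-within-zone", "base-between-zones")


def trimer_strengths(mc: MetaConnectivity, atlas: ZoneAtlas | None = None) -> pd.DataFrame:
    """Root-pinned trimer strength per region, by leaf-zone class.

    MC_j = sum over ordered leaf pairs (i, n), i != n, both different from
    the root j, of MC_(ij),(jn); each unordered leaf pair therefore counts
    twice, and the degenerate self-pair (i = n, the MC diagonal) is
    excluded.
    """
    atlas = atlas or mc.atlas
    n = atlas.n_regions
    lidx = link_index(n)
    M = mc.mc
    rows = []
    for j in range(n):
        sums = {c: 0.0 for c in TRIMER_CLASSES}
        total = 0.0
        for i in range(n):
            if i == j:
                continue
            li = lidx[(min(i, j), max(i, j))]
            for m in range(n):
                if m == j or m == i:
                    continue
                lm = lidx[(min(m, j), max(m, j))]
                v = M[li, lm]
                total += v
                sums[classify_trimer(atlas, j, i, m)] += v
        row = {"region": atlas.region_names[j], "region_idx": j, "total": total}
        row.update(sums)
        rows.append(row)
    return pd.DataFrame(rows)


def tetramer_strengths(mc: MetaConnectivity, atlas: ZoneAtlas | None = None) -> pd.DataFrame:
    """Base-pinned tetramer strength per link, summed over vertex-disjoint
    partner links, with the two base classes of interest.

    Only true tetramers enter (partner shares no region with the base);
    class columns cover base-within-zone (both links intrazone) and
    base-between-zones (both interzone); mixed pairs count only in
    ``total``.
    """
    atlas = atlas or mc.atlas
    pairs = link_pairs(atlas.n_regions)
    M = mc.mc
    l = pairs.shape[0]
    rows = []
    for a in range(l):
        i, j = pairs[a]
        sums = {c: 0.0 for c in TETRAMER_CLASSES}
        total = 0.0
        for b in range(l):
            m, nn = pairs[b]
            if len({int(i), int(j), int(m), int(nn)}) < 4:
                continue
            v = M[a, b]
            total += v
            c = classify_tetramer(atlas, (int(i), int(j)), (int(m), int(nn)))
            if c is not None:
                sums[c] += v
        row = {
            "link": a,
            "region_i": atlas.region_names[int(i)],
            "region_j": atlas.region_names[int(j)],
            "zone_class": classify_link(atlas, int(i), int(j)),
            "total": total,
        }
        row.update(sums)
        rows.append(row)
    return pd.DataFrame(rows)


def genuinity(
    mc: MetaConnectivity,
    fc: np.ndarray,
    atlas: ZoneAtlas | None = None,
    tetramer_rule: str = "base",
) -> dict[str, pd.DataFrame]:
    """Fractions of genuine trimers and tetramers per zone class.

    A trimer (root r, leaves i, j) is genuine iff MC_(ir),(jr) > FC_ij
    (strict): the coupling through the root exceeds the direct leaf-leaf
    dimer. A tetramer with base (ij) and partner (mn) is genuine iff
    MC_(ij),(mn) > FC_ij (``tetramer_rule='base'``, evaluated per ordered
    base) or > max(FC_ij, FC_mn) (``'max'``).
    """
    atlas = atlas or mc.atlas
    if tetramer_rule not in ("base", "max"):
        raise ValueError("tetramer_rule must be 'base' or 'max'")
    n = atlas.n_regions
    lidx = link_index(n)
    M = mc.mc
    tri_counts = {c: [0, 0] for c in TRIMER_CLASSES}  # [genuine, total]
    for r in range(n):
        for i in range(n):
            if i == r:
                continue
            for j in range(i + 1, n):
                if j == r:
                    continue
                li = lidx[(min(i, r), max(i, r))]
                lj = lidx[(min(j, r), max(j, r))]
                c = classify_trimer(atlas, r, i, j)
                tri_counts[c][1] += 1
                if M[li, lj] > fc[i, j]:
                    tri_counts[c][0] += 1
    tri = pd.DataFrame(
        [
            {"class": c, "genuine": g, "total": t, "fraction": g / t if t else np.nan}
            for c, (g, t) in tri_counts.items()
        ]
    )

    pairs = link_pairs(n)
    l = pairs.shape[0]
    tet_counts = {c: [0, 0] for c in TETRAMER_CLASSES}
    for a in range(l):
        i, j = (int(v) for v in pairs[a])
        for b in range(l):
            if b == a:
                continue
            m, nn = (int(v) for v in pairs[b])
            if len({i, j, m, nn}) < 4:
                continue
            c = classify_tetramer(atlas, (i, j), (m, nn))
            if c is None:
                continue
            tet_counts[c][1] += 1
            ref = fc[i, j] if tetramer_rule == "base" else max(fc[i, j], fc[m, nn])
            if M[a, b] > ref:
                tet_counts[c][0] += 1
    tet = pd.DataFrame(
        [
            {"class": c, "genuine": g, "total": t, "fraction": g / t if t else np.nan}
            for c, (g, t) in tet_counts.items()
        ]
    )
    return {"trimers": tri, "tetramers": tet}


def fc_mc_coupling(fc_strengths: np.ndarray, mc_strengths: np.ndarray) -> float:
    """Pearson correlation between paired FC and MC strength vectors
    (node-level Delta over regions, or edge-level Delta over links).

    NaN when either vector is constant; requires >= 3 paired observations.
    """
    x = np.asarray(fc_strengths, dtype=float)
    y = np.asarray(mc_strengths, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations of equal length")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
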