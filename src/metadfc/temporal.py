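"""Temporal-network link metrics over a threshold sweep.

The state-driven temporal network is binarized with a global threshold
theta (link active when its instantaneous weight is strictly above theta).
Each link's activation raster is decomposed into activation epochs and
gaps; from the intercontact-time (ICT) sequence we compute, per link:

* beta — burstiness coefficient (sigma - mu)/(sigma + mu) of the ICTs
  (population standard deviation); -1 periodic/tonic, 0 Poisson-like,
  -> +1 bursty;
* mu — mean activation-epoch duration (frames);
* tau — total active time fraction;
* memory — lag-1 Pearson correlation of consecutive epoch durations.

Group differences are expressed as percent excess relative to a reference
group, pooled across thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ZoneAtlas, classify_link
from .states import TemporalNetwork, run_lengths

__all__ = [
    "BinaryLinkRaster",
    "binarize",
    "threshold_grid",
    "interval_decomposition",
    "burstiness",
    "memory_coefficient",
    "link_metrics",
    "metrics_table",
    "relative_excess",
]


@dataclass
class BinaryLinkRaster:
    """Thresholded link x time activity for one subject."""

    theta: float
    active: np.ndarray  # l x T boolean
    subject_id: str = ""
    group: str = ""


def binarize(tnet: TemporalNetwork, theta: float) -> list[BinaryLinkRaster]:
    """Strict-greater global thresholding of every subject's link weights."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return [
        BinaryLinkRaster(float(theta), w > theta, sid, grp)
        for w, sid, grp in zip(tnet.weights, tnet.subject_ids, tnet.groups)
    ]


def threshold_grid(
    weights: np.ndarray,
    low_frac: float = 0.01,
    high_frac: float = 0.10,
    n_points: int = 10,
) -> np.ndarray:
    """Evenly spaced thresholds inside (low_frac*MAX, high_frac*MAX).

    MAX is the global maximum off-diagonal FC entry. The grid samples the
    open interval at the midpoints of ``n_points`` equal sub-intervals
    (endpoints nudged inward by half a step).
    """
    w = np.asarray(weights, dtype=float)
    mx = float(np.max(w))
    if mx <= 0:
        raise ValueError("maximum FC entry must be positive")
    lo, hi = low_frac * mx, high_frac * mx
    step = (hi - lo) / n_points
    return np.linspace(lo + step / 2, hi - step / 2, n_points)


def interval_decomposition(active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Epoch durations (maximal runs of 1s) and gap durations (runs of 0s),
    each in temporal order; boundary-touching runs included."""
    active = np.asarray(active, dtype=bool)
    vals, lens = run_lengths(active)
    return lens[vals.astype(bool)], lens[~vals.astype(bool)]


def burstiness(durations: np.ndarray) -> float:
    """(sigma - mu)/(sigma + mu) of a duration sequence (population sigma).

    NaN when fewer than 2 durations are available.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 2:
        return float("nan")
    mu = d.mean()
    sigma = d.std()  # ddof=0
    if sigma + mu == 0:
        return float("nan")
    return float((sigma - mu) / (sigma + mu))


def memory_coefficient(durations: np.ndarray) -> float:
    """Lag-1 Pearson correlation of consecutive epoch durations.

    NaN when fewer than 3 epochs or when either lagged subsequence is
    constant.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 3:
        return float("nan")
    x, y = d[:-1], d[1:]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def link_metrics(raster: BinaryLinkRaster, ict: str = "epochs") -> pd.DataFrame:
    """Per-link temporal metrics for one binarized raster.

    ``ict`` selects the intercontact-time sequence entering beta: activation
    epoch durations (``"epochs"``, the default) or inter-activation gap
    durations (``"gaps"``, the classical convention). Undefined metrics are
    NaN, never 0.
    """
    if ict not in ("epochs", "gaps"):
        raise ValueError("ict must be 'epochs' or 'gaps'")
    l, T = raster.active.shape
    rows = []
    for li in range(l):
        epochs, gaps = interval_decomposition(raster.active[li])
        icts = epochs if ict == "epochs" else gaps
        n_active = int(raster.active[li].sum())
        rows.append(
            {
                "link": li,
                "beta": burstiness(icts),
                "mu": float(epochs.mean()) if epochs.size else np.nan,
                "tau": n_active / T,
                "memory": memory_coefficient(epochs),
                "n_epochs": int(epochs.size),
                "mu_tau": float(icts.mean()) if icts.size else np.nan,
                "sigma_tau": float(icts.std()) if icts.size else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    df["theta"] = raster.theta
    df["subject"] = raster.subject_id
    df["group"] = raster.group
    return df


def metrics_table(
    tnet: TemporalNetwork,
    thetas: np.ndarray,
    atlas: ZoneAtlas,
    ict: str = "epochs",
) -> pd.DataFrame:
    """Tidy link-metric table over subjects and thresholds, with region-pair
    names and intrazone/interzone class."""
    zclass = np.array(
        [classify_link(atlas, int(i), int(j)) for i, j in tnet.link_pairs]
    )
    names = np.array(
        [
            f"{atlas.region_names[int(i)]}--{atlas.region_names[int(j)]}"
            for i, j in tnet.link_pairs
        ]
    )
    parts = []
    for theta in np.atleast_1d(thetas):
        for raster in binarize(tnet, float(theta)):
            df = link_metrics(raster, ict=ict)
            df["zone_class"] = zclass[df["link"].to_numpy()]
            df["region_pair"] = names[df["link"].to_numpy()]
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


def relative_excess(
    table: pd.DataFrame,
    metric: str = "beta",
    reference_group: str = "NC",
    center: str = "median",
) -> pd.DataFrame:
    """Percent excess of a metric vs the reference group, per threshold.

    For each (theta, zone class): subject-level metric values (mean over a
    subject's defined links) are aggregated to a group center (median by
    default); excess = 100 * (m_phi - m_ref) / |m_phi + m_ref|. Per-theta
    excess values are kept as replicates (one row per group x class x
    theta) so pooling across thresholds preserves dispersion.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    agg = getattr(np, center)
    per_subject = (
        table.dropna(subset=[metric])
        .groupby(["theta", "zone_class", "group", "subject"], sort=True)[metric]
        .mean()
        .reset_index()
    )
    rows = []
    for (theta, zc), sub in per_subject.groupby(["theta", "zone_class"], sort=True):
        ref = sub.loc[sub["group"] == reference_group, metric].to_numpy()
        if ref.size == 0:
            raise ValueError(
                f"reference group {reference_group!r} absent at theta={theta}"
            )
        m_ref = float(agg(ref))
        for grp, vals in sub.groupby("group", sort=True):
            m_phi = float(agg(vals[metric].to_numpy()))
            denom = abs(m_phi + m_ref)
            if denom == 0:
                warnings.warn(
                    f"theta={theta}: degenerate denominator for group {grp}; excluded"
                )
                continue
            rows.append(
                {
                    "group": grp,
                    "zone_class": zc,
                    "theta": theta,
                    "metric": metric,
                    "excess_pct": 100.0 * (m_phi - m_ref) / denom,
                }
            )
    return pd.DataFrame(rows)
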