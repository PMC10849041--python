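"""Distributional and clustering summaries over assigned inputs.

Two families of statistics:

* along-dendrite distributions — per-channel counts, proportions, 10 µm
  path-distance bins, proximal/medial/distal region fractions, and the
  M1/S1 count ratio;
* spatial clustering — directional nearest-neighbour (NN) distances within
  and across channels, the fraction of inputs with a cross-channel
  neighbour within a threshold (the 5 µm "cluster" criterion), and the
  colocalized fraction as a function of threshold.

NN and colocalization distances are centre-to-centre Euclidean in 3D.
Per-cell summaries are averaged across cells with equal weight, matching a
mean ± SEM over N cells rather than a pooled-spot statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import AnalysisConfig, DEFAULT_CONFIG
from .puncta import AssignedInput, Channel


@dataclass
class ChannelSummary:
    count: int
    proportion_pct: float | None  # of M1+S1 total
    bin_fractions: np.ndarray  # 10 µm bins of soma path distance, sums to 1
    region_fractions: tuple[float, float, float] | None  # proximal, medial, distal
    mean_soma_path_distance: float | None


@dataclass
class DistributionSummary:
    per_channel: dict[Channel, ChannelSummary]
    ratio_m1_s1: float | None  # None flags an undefined ratio (no S1 inputs)


@dataclass
class ClusterSummary:
    nn_same: dict[Channel, float | None]  # mean NN distance M1→M1, S1→S1
    nn_cross: dict[tuple[Channel, Channel], float | None]  # (from, to) → mean
    coloc_curve: dict[Channel, np.ndarray]  # fraction coloc vs threshold 1..10 µm
    coloc_fraction_at_threshold: dict[Channel, float | None]
    clustered_path_bins: dict[Channel, np.ndarray]  # members of ≤thr cross pairs
    clustered_mean_path: dict[Channel, float | None]


def _bin_fractions(path_distances: np.ndarray, bin_width: float, n_bins: int | None = None) -> np.ndarray:
    if len(path_distances) == 0:
        return np.zeros(0 if n_bins is None else n_bins)
    idx = np.floor(path_distances / bin_width).astype(int)  # half-open [k·w, (k+1)·w)
    if n_bins is None:
        n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    return counts / len(path_distances)


def _region_fractions(path_distances: np.ndarray, bounds: tuple[float, float]) -> tuple[float, float, float]:
    prox_max, med_max = bounds
    n = len(path_distances)
    prox = float((path_distances < prox_max).sum()) / n
    med = float(((path_distances >= prox_max) & (path_distances < med_max)).sum()) / n
    dist = float((path_distances >= med_max).sum()) / n
    return prox, med, dist


def distribution_summary(
    inputs: Sequence[AssignedInput],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
    n_bins: int | None = None,
) -> DistributionSummary:
    """Per-channel distribution record for one cell.

    Proportions are percentages of the M1+S1 total; ratio is M1 count over
    S1 count (None when the cell has no S1 inputs).  Bins are half-open
    ``[k·w, (k+1)·w)``; the region split follows the proximal < 30 µm,
    medial [30, 100) µm, distal ≥ 100 µm convention.
    """
    per: dict[Channel, ChannelSummary] = {}
    m1s1_total = sum(1 for i in inputs if i.channel in (Channel.M1, Channel.S1))
    for ch in Channel:
        spd = np.array([i.soma_path_distance for i in inputs if i.channel is ch])
        count = len(spd)
        prop = None
        if ch in (Channel.M1, Channel.S1) and m1s1_total > 0:
            prop = 100.0 * count / m1s1_total
        per[ch] = ChannelSummary(
            count=count,
            proportion_pct=prop,
            bin_fractions=_bin_fractions(spd, cfg.bin_width, n_bins),
            region_fractions=_region_fractions(spd, cfg.region_bounds) if count else None,
            mean_soma_path_distance=float(spd.mean()) if count else None,
        )
    n_s1 = per[Channel.S1].count
    ratio = per[Channel.M1].count / n_s1 if n_s1 > 0 else None
    return DistributionSummary(per_channel=per, ratio_m1_s1=ratio)


def nn_distances(
    a: np.ndarray,
    b: np.ndarray,
    exclude_self: bool = False,
) -> tuple[np.ndarray, float]:
    """Directional nearest-neighbour distances from each point of *a* to *b*.

    3D Euclidean, centre-to-centre.  With ``exclude_self`` the two sets are
    taken to be identical and each point's own zero-distance match is
    skipped.  Returns (per-point distances, their mean).  Note the statistic
    is directional: nn(a→b) need not equal nn(b→a).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if len(b) == 0:
        raise ValueError("target point set is empty")
    if exclude_self and len(b) < 2:
        raise ValueError("self-excluded NN needs at least two points")
    tree = cKDTree(b)
    d, _ = tree.query(a, k=2 if exclude_self else 1)
    d = np.asarray(d, dtype=float)
    out = d[:, 1] if exclude_self else d.reshape(-1)
    return out, float(out.mean())


def coloc_vs_chance(
    per_cell_nn: Sequence[np.ndarray],
    thr: float,
    null_pct: float = 50.0,
):
    """Per-cell colocalized fractions at *thr* and a one-sample test vs chance.

    ``per_cell_nn`` holds, for each cell, the directional NN distances of the
    query channel's inputs to the reference channel.  Returns
    ``(fractions_pct, test_result_or_None)``; the test (selected by the
    normality-gated decision tree) compares the per-cell percentages with the
    chance level and is skipped (None) below 3 cells.
    """
    from .inference import ComparisonSpec, Design, select_and_run

    fracs = np.array([100.0 * float((np.asarray(d) <= thr).mean()) for d in per_cell_nn])
    test = None
    if len(fracs) >= 3:
        spec = ComparisonSpec(design=Design.ONE_SAMPLE, null_value=null_pct)
        test = select_and_run(fracs, None, spec)
    return fracs, test


def cluster_summary(
    inputs: Sequence[AssignedInput],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
    curve_thresholds: Sequence[float] = tuple(range(1, 11)),
    n_bins: int | None = None,
) -> ClusterSummary:
    """Same- and cross-channel NN statistics for one cell."""
    pts = {
        ch: np.array([i.center for i in inputs if i.channel is ch]).reshape(-1, 3)
        for ch in (Channel.M1, Channel.S1)
    }
    spd = {
        ch: np.array([i.soma_path_distance for i in inputs if i.channel is ch])
        for ch in (Channel.M1, Channel.S1)
    }

    nn_same: dict[Channel, float | None] = {}
    for ch in (Channel.M1, Channel.S1):
        if len(pts[ch]) >= 2:
            _, mean = nn_distances(pts[ch], pts[ch], exclude_self=True)
            nn_same[ch] = mean
        else:
            nn_same[ch] = None

    nn_cross: dict[tuple[Channel, Channel], float | None] = {}
    cross_d: dict[Channel, np.ndarray | None] = {}
    for src, dst in ((Channel.M1, Channel.S1), (Channel.S1, Channel.M1)):
        if len(pts[src]) >= 1 and len(pts[dst]) >= 1:
            d, mean = nn_distances(pts[src], pts[dst])
            nn_cross[(src, dst)] = mean
            cross_d[src] = d
        else:
            nn_cross[(src, dst)] = None
            cross_d[src] = None

    coloc_curve: dict[Channel, np.ndarray] = {}
    coloc_at: dict[Channel, float | None] = {}
    clustered_bins: dict[Channel, np.ndarray] = {}
    clustered_mean: dict[Channel, float | None] = {}
    thresholds = np.asarray(curve_thresholds, dtype=float)
    for ch in (Channel.M1, Channel.S1):
        d = cross_d[ch]
        if d is None or len(d) == 0:
            coloc_curve[ch] = np.full(len(thresholds), np.nan)
            coloc_at[ch] = None
            clustered_bins[ch] = np.zeros(0 if n_bins is None else n_bins)
            clustered_mean[ch] = None
            continue
        coloc_curve[ch] = np.array([float((d <= t).mean()) for t in thresholds])
        coloc_at[ch] = float((d <= cfg.cluster_threshold).mean())
        member = d <= cfg.cluster_threshold
        member_spd = spd[ch][member]
        clustered_bins[ch] = _bin_fractions(member_spd, cfg.bin_width, n_bins)
        clustered_mean[ch] = float(member_spd.mean()) if member.any() else None

    return ClusterSummary(
        nn_same=nn_same,
        nn_cross=nn_cross,
        coloc_curve=coloc_curve,
        coloc_fraction_at_threshold=coloc_at,
        clustered_path_bins=clustered_bins,
        clustered_mean_path=clustered_mean,
    )
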