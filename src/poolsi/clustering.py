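"""Functional clustering: pairwise tuning similarity versus cortical distance.

All unordered cell pairs are binned by Euclidean cortical distance into
75-um-wide half-open bins. For non-circular parameters the per-bin statistic
is the Pearson correlation of the paired values (each pair entered in both
orders so the statistic is symmetric); for preferred orientation it is the
circular statistic r = <cos 2(ori_i - ori_j)>, which is 1 for identical
orientations and ~0 for independent ones. Significance comes either from
the parametric Pearson p or from a position-shuffle permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "ClusteringProfile",
    "pairwise_profile",
    "circular_ori_profile",
    "shuffle_significance",
]

BIN_UM = 75.0
MIN_PAIRS = 3


@dataclass
class ClusteringProfile:
    bin_edges: np.ndarray          # um, width 75
    pair_count: np.ndarray
    statistic: np.ndarray          # Pearson r or circular r per bin
    p_value: np.ndarray
    kind: str = "pearson"
    parameter: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def significance_tier(self) -> list[str]:
        tiers = []
        for p, n in zip(self.p_value, self.pair_count):
            if n < MIN_PAIRS or not np.isfinite(p):
                tiers.append("untested")
            elif p < 0.001:
                tiers.append("p<0.001")
            elif p < 0.01:
                tiers.append("p<0.01")
            else:
                tiers.append("ns")
        return tiers

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_um": self.bin_edges[:-1],
            "bin_hi_um": self.bin_edges[1:],
            "n_pairs": self.pair_count,
            "statistic": self.statistic,
            "p": self.p_value,
            "tier": self.significance_tier(),
        })


def _pair_arrays(values, positions):
    values = np.asarray(values, float)
    positions = np.asarray(positions, float)
    ok = np.isfinite(values) & np.all(np.isfinite(positions), axis=1)
    values, positions = values[ok], positions[ok]
    if len(values) < 2:
        raise ValueError("need >= 2 cells with finite values and positions")
    dist = pdist(positions)
    iu, ju = np.triu_indices(len(values), k=1)
    return values, dist, iu, ju


def _bin_edges(dist, max_distance=None):
    dmax = max_distance if max_distance is not None else dist.max()
    n_bins = max(1, int(np.ceil(dmax / BIN_UM)))
    return np.arange(n_bins + 1) * BIN_UM


def _binned_pearson(values, dist, iu, ju, edges):
    which = np.digitize(dist, edges) - 1
    nb = len(edges) - 1
    counts = np.zeros(nb, dtype=int)
    r = np.full(nb, np.nan)
    p = np.full(nb, np.nan)
    for b in range(nb):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b] < MIN_PAIRS:
            continue
        a = np.concatenate([values[iu[sel]], values[ju[sel]]])
        c = np.concatenate([values[ju[sel]], values[iu[sel]]])
        if a.std() == 0 or c.std() == 0:
            continue
        res = stats.pearsonr(a, c)
        r[b], p[b] = res.statistic, res.pvalue
    return counts, r, p


def pairwise_profile(values, positions, parameter: str = "",
                     max_distance: float | None = None,
                     significance: str = "parametric",
                     n_shuffles: int = 1000, seed=None) -> ClusteringProfile:
    """Distance-binned Pearson correlation profile of a tuning parameter.

    ``positions`` is (n, 2) in um. ``significance`` is 'parametric'
    (Pearson p) or 'shuffle' (position permutation).
    """
    values, dist, iu, ju = _pair_arrays(values, positions)
    edges = _bin_edges(dist, max_distance)
    counts, r, p = _binned_pearson(values, dist, iu, ju, edges)
    prof = ClusteringProfile(edges, counts, r, p, kind="pearson",
                             parameter=parameter)
    if significance == "shuffle":
        prof.p_value = shuffle_significance(
            values, dist, iu, ju, edges, statistic="pearson",
            observed=r, n_shuffles=n_shuffles, seed=seed)
    return prof


def _binned_circular(values_deg, dist, iu, ju, edges):
    which = np.digitize(dist, edges) - 1
    nb = len(edges) - 1
    counts = np.zeros(nb, dtype=int)
    r = np.full(nb, np.nan)
    d2 = np.radians(2.0 * (values_deg[iu] - values_deg[ju]))
    for b in range(nb):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b] >= MIN_PAIRS:
            r[b] = np.cos(d2[sel]).mean()
    return counts, r


def circular_ori_profile(ori_deg, positions, n_shuffles: int = 1000,
                         seed=None) -> ClusteringProfile:
    """Circular orientation-clustering profile with shuffle significance.

    Per bin: r = <cos 2(ori_i - ori_j)> over pairs; p from shuffling neuron
    positions (values fixed) and counting stronger clustering.
    """
    ori_deg = np.asarray(ori_deg, float)
    if np.any((ori_deg < 0) | (ori_deg >= 180.0)):
        raise ValueError("orientations must lie in [0, 180)")
    values, dist, iu, ju = _pair_arrays(ori_deg, positions)
    edges = _bin_edges(dist)
    counts, r = _binned_circular(values, dist, iu, ju, edges)
    p = shuffle_significance(values, dist, iu, ju, edges, statistic="circular",
                             observed=r, n_shuffles=n_shuffles, seed=seed)
    prof = ClusteringProfile(edges, counts, r, p, kind="circular",
                             parameter="ori")
    return prof


def shuffle_significance(values, dist, iu, ju, edges, statistic: str,
                         observed: np.ndarray, n_shuffles: int = 1000,
                         seed=None, smoothing: bool = True) -> np.ndarray:
    """One-sided permutation p per distance bin.

    Neuron positions are shuffled (equivalently, values permuted across
    positions), the binned statistic recomputed, and p is the proportion of
    shuffles with clustering at least as strong as observed. With
    ``smoothing`` (add-one), p is (1 + k)/(1 + n_shuffles), so the smallest
    attainable p is 1/(n_shuffles + 1).
    """
    rng = np.random.default_rng(seed)
    nb = len(edges) - 1
    exceed = np.zeros(nb)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(values))
        v = values[perm]
        if statistic == "circular":
            _, rs = _binned_circular(v, dist, iu, ju, edges)
        else:
            _, rs, _ = _binned_pearson(v, dist, iu, ju, edges)
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isfinite(rs) & np.isfinite(observed),
                               rs >= observed, 0)
    if smoothing:
        return (1.0 + exceed) / (1.0 + n_shuffles)
    return exceed / n_shuffles
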