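"""Geographic distances and distance-decay regression.

The distance-decay relationship regresses pairwise community dissimilarity
on great-circle distance; a positive slope means nearby communities are
more alike.  The ordinary-least-squares fit mirrors common practice even
though pairwise distances are not independent observations; a Mantel
permutation test is available as a statistically honest alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import PairwiseMatrix, SampleMetadata

__all__ = ["DecayFit", "haversine_m", "haversine_matrix", "distance_decay"]

EARTH_RADIUS_M = 6_371_000.0


@dataclass
class DecayFit:
    slope: float           # dissimilarity per metre
    intercept: float
    r: float               # Pearson correlation of the pair scatter
    p_value: float
    n_pairs: int
    mantel_p: float | None = None


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in metres (Earth radius 6,371,000 m)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a)))


def haversine_matrix(meta: Sequence[SampleMetadata]) -> PairwiseMatrix:
    """Pairwise great-circle distances (metres) between samples."""
    labels = [m.sample_id for m in meta]
    lat = np.array([m.latitude for m in meta])
    lon = np.array([m.longitude for m in meta])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_m(lat[i], lon[i], lat[j], lon[j])
    return PairwiseMatrix(d, labels, "haversine_m")


def distance_decay(comm_dist: PairwiseMatrix, geo_dist: PairwiseMatrix,
                   mantel_perms: int = 0, seed: int = 0) -> DecayFit:
    """OLS of pairwise community dissimilarity on geographic distance.

    Upper-triangle pairs are unravelled and fitted by ordinary least
    squares.  When ``mantel_perms`` > 0 a Mantel test (permuting the sample
    labels of the geographic matrix) supplements the OLS p-value.
    """
    if comm_dist.labels != geo_dist.labels:
        geo_dist = geo_dist.subset(comm_dist.labels)
    n = len(comm_dist.labels)
    if n < 3:
        raise ValueError("distance-decay needs at least 3 samples")
    y = comm_dist.condensed()
    x = geo_dist.condensed()
    if np.ptp(x) == 0:
        raise ValueError("geographic distances have zero variance")
    if np.ptp(y) == 0:
        # flat response: slope and correlation are exactly zero
        return DecayFit(0.0, float(y[0]), 0.0, 1.0, y.size)
    fit = stats.linregress(x, y)
    mantel_p = None
    if mantel_perms > 0:
        rng = np.random.default_rng(seed)
        obs = np.corrcoef(x, y)[0, 1]
        count = 0
        g = geo_dist.values
        iu = np.triu_indices(n, k=1)
        for _ in range(mantel_perms):
            perm = rng.permutation(n)
            xp = g[np.ix_(perm, perm)][iu]
            if abs(np.corrcoef(xp, y)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        mantel_p = (count + 1) / (mantel_perms + 1)
    return DecayFit(float(fit.slope), float(fit.intercept), float(fit.rvalue),
                    float(fit.pvalue), y.size, mantel_p)
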