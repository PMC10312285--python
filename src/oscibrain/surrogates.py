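"""Spatial-autocorrelation-preserving surrogate heterogeneity maps.

The null-model comparison needs heterogeneity maps whose regional
identity is destroyed but whose spatial autocorrelation structure is
preserved, so any fitting advantage of the real map cannot be explained
by its smoothness alone.

Surrogates are built by rigid rotation: the node cloud is randomly
rotated about its centroid and each original node takes the map value
of the rotated node assigned to it by an optimal (minimum total
distance) matching.  A rigid motion of a smooth field preserves its
spatial autocorrelation by construction, and the induced reassignment
is a permutation, so the surrogate's value multiset — hence mean and
variance — equals the original's exactly.  Candidate rotations are
screened: those still correlated with the original (|r| above a
tolerance) are rejected, and among the rest the one whose empirical
variogram (quantile-binned squared differences vs distance) best
matches the original's is kept.  A plain permutation is available as a
degraded control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .data import HeterogeneityMap

__all__ = ["SurrogateSet", "generate_surrogates", "variogram", "variogram_deviation"]

logger = logging.getLogger(__name__)


@dataclass
class SurrogateSet:
    maps: list[HeterogeneityMap]
    method: str
    seed: int

    def __len__(self) -> int:
        return len(self.maps)

    def __getitem__(self, i: int) -> HeterogeneityMap:
        return self.maps[i]


def variogram(values: np.ndarray, coords: np.ndarray,
              n_bins: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Binned empirical variogram: gamma(h) = mean of (x_i - x_j)^2 / 2.

    Bins are distance quantiles, so each holds the same number of node
    pairs.  Returns (bin centers, gamma).
    """
    values = np.asarray(values, float).ravel()
    d = pdist(np.asarray(coords, float))
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    gamma = np.array([sq[idx == b].mean() if np.any(idx == b) else np.nan
                      for b in range(n_bins)])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma


def variogram_deviation(original: np.ndarray, candidate: np.ndarray,
                        coords: np.ndarray, n_bins: int = 5) -> float:
    """Mean relative deviation |gamma_s - gamma_o| / gamma_o over usable bins."""
    _, go = variogram(original, coords, n_bins)
    _, gc = variogram(candidate, coords, n_bins)
    ok = np.isfinite(go) & np.isfinite(gc) & (go > 0)
    if not np.any(ok):
        return np.nan
    return float(np.mean(np.abs(gc[ok] - go[ok]) / go[ok]))


def _spin_permutation(coords: np.ndarray, centered: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Permutation induced by a random rigid rotation of the node cloud."""
    R = Rotation.random(random_state=rng).as_matrix()
    rotated = centered @ R.T + coords.mean(axis=0)
    _, col = linear_sum_assignment(cdist(coords, rotated))
    return col


def generate_surrogates(
    hmap: HeterogeneityMap,
    coords: np.ndarray,
    n: int,
    method: str = "variogram_match",
    seed: int = 0,
    n_bins: int = 5,
    n_search: int = 40,
    corr_tol: float = 0.3,
) -> SurrogateSet:
    """Surrogate maps preserving (variogram_match) spatial autocorrelation.

    Per surrogate, ``n_search`` random rotations are proposed; rotations
    whose induced map still correlates with the original above
    ``corr_tol`` are discarded (identity destruction), and the best
    variogram match among the rest is kept.  ``plain_permutation``
    shuffles without any spatial constraint.
    """
    if n < 1:
        raise ValueError("need n >= 1 surrogates")
    if method not in ("variogram_match", "plain_permutation"):
        raise ValueError(f"unknown method {method!r}")
    beta = hmap.beta
    coords = np.asarray(coords, float)
    if coords.shape[0] != beta.size:
        raise ValueError("coords and map length mismatch")
    if beta.std() <= 1e-12 * max(1.0, abs(beta.mean())):
        logger.warning("constant map: surrogates equal the original")
        maps = [HeterogeneityMap(beta.copy(), source_tag="surrogate")
                for _ in range(n)]
        return SurrogateSet(maps=maps, method=method, seed=seed)

    rng = np.random.default_rng(seed)
    centered = coords - coords.mean(axis=0)

    maps = []
    for _ in range(n):
        if method == "plain_permutation":
            maps.append(HeterogeneityMap(rng.permutation(beta),
                                         source_tag="surrogate"))
            continue
        kept, fallback = [], []
        for _ in range(n_search):
            cand = beta[_spin_permutation(coords, centered, rng)]
            dev = variogram_deviation(beta, cand, coords, n_bins)
            if not np.isfinite(dev):
                continue
            r = abs(np.corrcoef(beta, cand)[0, 1])
            (kept if r <= corr_tol else fallback).append((dev, cand))
        pool = kept or fallback
        if not pool:
            raise RuntimeError("no usable surrogate candidate found")
        if not kept:
            logger.warning("no rotation met the correlation tolerance; "
                           "keeping the best variogram match regardless")
        maps.append(HeterogeneityMap(min(pool, key=lambda c: c[0])[1],
                                     source_tag="surrogate"))
    return SurrogateSet(maps=maps, method=method, seed=seed)
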