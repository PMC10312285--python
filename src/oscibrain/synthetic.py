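"""Synthetic connectomes, heterogeneity maps, and ground-truth BOLD.

Stands in for the empirical inputs of a whole-brain modeling study:

* a spatially embedded connectome — nodes on a sphere (70 mm radius, the
  scale of a human hemisphere), weights following an exponential distance
  rule modulated by lognormal noise, symmetrized and normalized to a
  maximum of 0.2;
* a spatially autocorrelated, positive heterogeneity map — white noise
  smoothed with a Gaussian kernel over inter-node distances and affinely
  mapped to [0.5, 2.0];
* "empirical" BOLD with known ground truth — the Stuart-Landau network
  run at a chosen (G, bias, scale), one independent noise realization per
  synthetic subject.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import BOLDDataset, ConnectomeBundle, HeterogeneityMap
from .hopf import HopfParams, simulate_hopf

__all__ = [
    "SyntheticSpec",
    "make_connectome",
    "make_heterogeneity_map",
    "make_ground_truth_bold",
    "sphere_points",
]

#: Sphere radius for node placement (mm).
SPHERE_RADIUS = 70.0


@dataclass
class SyntheticSpec:
    """Study-design parameters of the synthetic dataset.

    ``edr_lambda`` is the exponential-distance-rule decay (1/mm);
    ``map_smoothness`` the Gaussian kernel width of the heterogeneity map
    (mm); ``duration``/``tr`` size each subject's recording.
    """

    n_regions: int = 30
    seed: int = 0
    edr_lambda: float = 0.02
    map_smoothness: float = 30.0
    subjects: int = 10
    duration: float = 600.0
    tr: float = 2.0
    band: tuple[float, float] = (0.008, 0.08)

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.duration / self.tr < 200:
            raise ValueError(
                "duration/tr must give at least 200 samples for causal-ignition "
                f"estimation, got {self.duration / self.tr:.0f}"
            )


def sphere_points(n: int, rng: np.random.Generator,
                  radius: float = SPHERE_RADIUS) -> np.ndarray:
    """Uniform random points on a sphere surface."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


def make_connectome(spec: SyntheticSpec) -> ConnectomeBundle:
    """Exponential-distance-rule connectome on a sphere.

    Weights w_ij ∝ exp(-lambda * d_ij) * lognormal noise, symmetrized,
    zero diagonal, max-normalized to 0.2.
    """
    rng = np.random.default_rng(spec.seed)
    coords = sphere_points(spec.n_regions, rng)
    d = squareform(pdist(coords))
    noise = rng.lognormal(mean=0.0, sigma=0.5, size=d.shape)
    w = np.exp(-spec.edr_lambda * d) * noise
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    w *= 0.2 / w.max()
    w[w == w.max()] = 0.2
    labels = [f"region_{i:03d}" for i in range(spec.n_regions)]
    return ConnectomeBundle(C=w, labels=labels, coords=coords)


def _distance_kernel(coords: np.ndarray, smoothness: float) -> np.ndarray:
    """Row-normalized Gaussian kernel over inter-node distances."""
    d = squareform(pdist(coords))
    k = np.exp(-0.5 * (d / smoothness) ** 2)
    return k / k.sum(axis=1, keepdims=True)


def make_heterogeneity_map(
    coords: np.ndarray,
    smoothness: float,
    seed: int,
    value_range: tuple[float, float] = (0.5, 2.0),
) -> HeterogeneityMap:
    """Spatially autocorrelated positive map from smoothed white noise.

    ``smoothness`` = 0 returns rescaled white noise; larger values give a
    smoother, eventually near-constant map.  The result is affinely mapped
    to ``value_range``.
    """
    if smoothness < 0:
        raise ValueError("smoothness must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(coords.shape[0])
    if smoothness > 0:
        noise = _distance_kernel(np.asarray(coords, float), smoothness) @ noise
    lo, hi = value_range
    span = noise.max() - noise.min()
    if span == 0:  # pathological constant field
        beta = np.full_like(noise, 0.5 * (lo + hi))
    else:
        beta = lo + (hi - lo) * (noise - noise.min()) / span
    return HeterogeneityMap(beta=beta, source_tag="synthetic")


def make_ground_truth_bold(
    params: HopfParams,
    bundle: ConnectomeBundle,
    spec: SyntheticSpec,
    a_vector: np.ndarray | None = None,
) -> BOLDDataset:
    """Ground-truth BOLD: independent noise realizations of one model.

    ``a_vector`` overrides ``params.a`` with a heterogeneity-modulated
    bifurcation-parameter vector (the known ground truth).  Each synthetic
    subject is a fresh noise realization with a seed derived from
    ``spec.seed``.
    """
    if spec.duration <= 0:
        raise ValueError("duration must be positive")
    p = HopfParams(
        a=a_vector if a_vector is not None else params.a,
        omega=params.omega,
        G=params.G,
        nu=params.nu,
        dt=params.dt,
        duration=spec.duration,
        transient=params.transient,
        tr=spec.tr,
    )
    from .hopf import simulate_hopf_dataset

    return simulate_hopf_dataset(p, bundle, spec.subjects, seed=spec.seed,
                                 band=spec.band)
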