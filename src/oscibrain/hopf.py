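"""Stuart-Landau (Hopf normal form) whole-brain model.

Each region n is a noisy Stuart-Landau oscillator

    dz_n/dt = (a_n + i w_n) z_n - |z_n|^2 z_n + coupling + noise,

the simplest dynamical system that can sit on either side of a Hopf
bifurcation: for a_n < 0 a stable focus driven by noise, for a_n > 0 a
limit cycle of radius sqrt(a_n).  Regions interact diffusively through the
structural connectome, G * sum_j C_nj (x_j - x_n), and the real part x_n
stands in for the regional fMRI signal.

Regional heterogeneity enters by modulating the bifurcation parameter:
a_n = a0 * (1 + bias + scale * beta_n), so (bias, scale) = (0, 0) is the
homogeneous model with a_n = a0 for every region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import welch

from .data import BOLDDataset, ConnectomeBundle, HeterogeneityMap

__all__ = [
    "HopfParams",
    "heterogeneous_a",
    "simulate_hopf",
    "estimate_intrinsic_frequencies",
    "locate_critical_a",
]

logger = logging.getLogger(__name__)

#: Homogeneous baseline bifurcation parameter.
A0_DEFAULT = -0.02

#: |z| beyond which the integration is declared divergent.
BLOWUP = 1e3


@dataclass
class HopfParams:
    """Parameters of the coupled Stuart-Landau network.

    ``a`` and ``omega`` are per-region vectors (scalar broadcasts); ``G``
    scales the diffusive coupling, ``nu`` is the additive Gaussian noise
    standard deviation applied independently to the x and y equations.
    Times are in seconds of model time; the output is subsampled to ``tr``.
    """

    a: np.ndarray | float = A0_DEFAULT
    omega: np.ndarray | float = 2 * np.pi * 0.05
    G: float = 0.0
    nu: float = 0.02
    dt: float = 0.1
    duration: float = 600.0
    transient: float = 20.0
    tr: float = 2.0

    def vectors(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        a = np.broadcast_to(np.asarray(self.a, float), (n,)).copy()
        w = np.broadcast_to(np.asarray(self.omega, float), (n,)).copy()
        if self.dt >= 2 * np.pi / max(w.max(), 1e-12) / 20:
            logger.warning("dt=%g coarse for max omega=%g", self.dt, w.max())
        return a, w


def heterogeneous_a(
    a0: float,
    bias: float,
    scale: float,
    hmap: HeterogeneityMap,
    mode: str = "multiplicative",
) -> np.ndarray:
    """Heterogeneity-modulated bifurcation parameters.

    multiplicative (default): a_n = a0 * (1 + bias + scale * beta_n), so
    (0, 0) recovers the homogeneous a0 exactly.  additive: a_n = a0 + bias
    + scale * beta_n.
    """
    beta = hmap.beta
    if not np.all(np.isfinite(beta)):
        raise ValueError("heterogeneity map has non-finite entries")
    if mode == "multiplicative":
        return a0 * (1.0 + bias + scale * beta)
    if mode == "additive":
        return a0 + bias + scale * beta
    raise ValueError(f"unknown mode {mode!r}")


def simulate_hopf_batch(
    params: HopfParams,
    bundle: ConnectomeBundle,
    n_trials: int,
    seed: int,
    subsample: bool = True,
) -> np.ndarray:
    """Euler-Maruyama integration of the coupled Stuart-Landau network.

    Integrates ``n_trials`` independent noise realizations in one
    vectorized pass.  Starts from small random initial conditions,
    discards the transient, and returns the x variable with shape
    (n_trials, N, T), subsampled to ``params.tr`` unless ``subsample``
    is False.  Bit-reproducible for a fixed seed.
    """
    n = bundle.n_regions
    a, w = params.vectors(n)
    a, w = a[None, :], w[None, :]
    C = bundle.C
    deg = C.sum(axis=1)[None, :]
    rng = np.random.default_rng(seed)
    dt = params.dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    if subsample:
        # snap dt to an exact divisor of tr so the output sampling is exact
        stride = max(1, int(round(params.tr / dt)))
        dt = params.tr / stride
    else:
        stride = 1
    n_steps = int(round((params.duration + params.transient) / dt))
    n_trans = int(round(params.transient / dt))
    sq = np.sqrt(dt) * params.nu
    shape = (n_trials, n)

    x = 0.001 * rng.standard_normal(shape)
    y = 0.001 * rng.standard_normal(shape)
    n_keep = (n_steps - n_trans + stride - 1) // stride
    out = np.empty((n_trials, n, n_keep))
    k = 0
    G = params.G
    for step in range(n_steps):
        rho2 = x * x + y * y
        cx = x @ C.T - deg * x
        cy = y @ C.T - deg * y
        dx = (a - rho2) * x - w * y + G * cx
        dy = (a - rho2) * y + w * x + G * cy
        if params.nu > 0:
            x = x + dt * dx + sq * rng.standard_normal(shape)
            y = y + dt * dy + sq * rng.standard_normal(shape)
        else:
            x = x + dt * dx
            y = y + dt * dy
        if step == n_trans - 1 or (step + 1) % 200 == 0:
            m = np.max(rho2)
            if not np.isfinite(m) or m > BLOWUP**2:
                raise FloatingPointError(
                    f"Stuart-Landau integration diverged (|z| > {BLOWUP}); "
                    f"reduce dt (currently {dt} s)"
                )
        if step >= n_trans and (step - n_trans) % stride == 0:
            out[:, :, k] = x
            k += 1
    out = out[:, :, :k]
    m = np.max(np.abs(out)) if out.size else 0.0
    if not np.isfinite(m) or m > BLOWUP:
        raise FloatingPointError(
            f"Stuart-Landau integration diverged; reduce dt (currently {dt} s)"
        )
    return out


def simulate_hopf(
    params: HopfParams,
    bundle: ConnectomeBundle,
    seed: int,
    return_full: bool = False,
) -> np.ndarray:
    """One realization of the coupled Stuart-Landau network, as (N, T_s).

    ``return_full`` returns every integration step instead of
    subsampling to ``params.tr``.
    """
    return simulate_hopf_batch(params, bundle, 1, seed,
                               subsample=not return_full)[0]


def simulate_hopf_dataset(
    params: HopfParams,
    bundle: ConnectomeBundle,
    n_trials: int,
    seed: int,
    band: tuple[float, float] = (0.008, 0.08),
) -> BOLDDataset:
    """Simulate ``n_trials`` independent noise realizations as one dataset."""
    xs = simulate_hopf_batch(params, bundle, n_trials, seed)
    return BOLDDataset(subjects=list(xs), tr=params.tr, band=band)


def estimate_intrinsic_frequencies(
    bold: BOLDDataset,
    peak_floor: float = 5.0,
) -> np.ndarray:
    """Per-region intrinsic angular frequency from the group power spectrum.

    omega_i = 2*pi * argmax of the group-averaged Welch spectrum of region i
    within the dataset's band.  A spectrum whose in-band peak is less than
    ``peak_floor`` times the in-band median is treated as flat and falls
    back to the band midpoint (logged).
    """
    low, high = bold.band
    n = bold.n_regions
    nper = min(256, min(s.shape[1] for s in bold.subjects))
    acc = None
    for s in bold.subjects:
        f, p = welch(s, fs=1.0 / bold.tr, nperseg=nper, axis=1)
        acc = p if acc is None else acc + p
    acc /= bold.n_subjects
    sel = (f >= low) & (f <= high)
    if not np.any(sel):
        raise ValueError("no spectral bins inside the band; series too short")
    fband, pband = f[sel], acc[:, sel]
    omega = np.empty(n)
    midpoint = 0.5 * (low + high)
    for i in range(n):
        med = np.median(pband[i])
        if med <= 0 or pband[i].max() < peak_floor * med:
            logger.info("region %d: flat spectrum, falling back to band midpoint", i)
            omega[i] = 2 * np.pi * midpoint
        else:
            omega[i] = 2 * np.pi * fband[np.argmax(pband[i])]
    return omega


def _stationary_amplitude(a: float, rho0: float = 1e-4) -> float:
    """Long-time amplitude of a noise-free uncoupled node started at rho0."""
    horizon = 20.0 / max(abs(a), 1e-7)

    def rhs(t, z):
        x, y = z
        rho2 = x * x + y * y
        return [(a - rho2) * x, (a - rho2) * y]

    sol = solve_ivp(rhs, [0.0, horizon], [rho0, 0.0], rtol=1e-10, atol=1e-14)
    return float(np.hypot(*sol.y[:, -1]))


def locate_critical_a(
    lo: float = -0.5,
    hi: float = 0.5,
    tol: float = 1e-6,
    rho0: float = 1e-4,
) -> float:
    """Bisection on the long-time amplitude of an uncoupled noise-free node.

    Classifies a value of the bifurcation parameter as supercritical when
    the stationary amplitude exceeds the small initial amplitude, i.e. the
    trajectory grew toward a limit cycle rather than decaying to the focus.
    Returns the located critical value (analytically 0 for the normal
    form) to within ``tol``.
    """
    def grew(a: float) -> bool:
        return _stationary_amplitude(a, rho0) > rho0

    if grew(lo) or not grew(hi):
        raise ValueError("bracket does not straddle the bifurcation")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if grew(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
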