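"""Exact mean-field (firing-rate-equation) whole-brain model.

Each region holds an excitatory and an inhibitory population of
quadratic integrate-and-fire (QIF) neurons with Lorentzian-distributed
input currents.  In the thermodynamic limit the population dynamics are
*exactly* described by two ODEs per population — the firing rate
equations (FRE) — for the mean rate r and mean membrane potential v.
In nondimensional form (lowercase variables) region n obeys

    re' = d_e/pi + 2 re ve
    ve' = ve^2 + eta - (pi re)^2 + j_ee re + j_ei ri
          + G j_ee sum_p C_np re_p            (+ noise)
    ri' = d_i/pi + 2 ri vi
    vi' = vi^2 + 1 - (pi ri)^2 + j_ii ri + j_ie re   (+ noise)

with inter-regional coupling only at the E-to-E level.  The rescaled
Lorentzian half-widths (d_e, d_i) act as bifurcation parameters: a Hopf
curve in the (d_e, d_i) plane separates damped from self-sustained E-I
oscillations.  Regional heterogeneity modulates d_e and d_i jointly,
exactly as the Stuart-Landau model's bifurcation parameter.

The nondimensionalization maps the dimensional FRE (capital variables,
membrane time constant tau_m, reference drive eta_ref > 0) via

    r = tau_m R / sqrt(eta_ref),  v = V / sqrt(eta_ref),
    t~ = sqrt(eta_ref) t / tau_m, j = J / sqrt(eta_ref),
    d = Delta / eta_ref,          eta = eta_bar / eta_ref,

which reproduces the dimensional trajectories exactly (the square roots
are required for dimensional consistency; verified by dual integration).

A microscopic QIF simulator provides the exactness cross-check, and a
Balloon-Windkessel stage turns excitatory rates into BOLD-like signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, fsolve

from .data import BOLDDataset, ConnectomeBundle, HeterogeneityMap

__all__ = [
    "FREParams",
    "QIFParams",
    "HemodynamicParams",
    "simulate_fre_network",
    "simulate_fre_single",
    "simulate_fre_dimensional",
    "nondimensionalize_params",
    "dimensionalize_params",
    "nondim_state",
    "dim_state",
    "fre_fixed_point",
    "fre_single_fixed_point",
    "locate_hopf_curve",
    "heterogeneous_d",
    "simulate_qif_population",
    "balloon_windkessel",
    "simulate_meanfield_bold",
]

logger = logging.getLogger(__name__)

#: Positive floor for heterogeneity-modulated half-widths.
D_FLOOR = 1e-6

#: Divergence guard on |v|.
BLOWUP = 1e4


@dataclass
class FREParams:
    """Nondimensional FRE network parameters.

    ``d_e``/``d_i`` may be scalars or length-N vectors.  ``eta`` is the
    rescaled excitatory drive (the inhibitory drive is 1 by construction).
    Defaults place the homogeneous uncoupled system just below the Hopf
    curve at (d_e, d_i) = (1, 1.175).  ``dt``/``duration`` are in
    nondimensional time units; ``tau_m`` and ``eta_i_dim`` define the
    mapping to seconds: one unit = tau_m / sqrt(eta_i_dim).
    """

    d_e: np.ndarray | float = 1.0
    d_i: np.ndarray | float = 1.175
    eta: float = 4.03
    j_ee: float = 5.04
    j_ei: float = -3.8
    j_ie: float = 3.8
    j_ii: float = -3.8
    G: float = 0.0
    tau_m: float = 0.010
    eta_i_dim: float = 1.0
    noise_v: float = 0.0
    dt: float = 0.01
    duration: float = 2000.0
    transient: float = 200.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.d_e) <= 0) or np.any(np.asarray(self.d_i) <= 0):
            raise ValueError("d_e and d_i must be positive")
        if self.tau_m <= 0 or self.eta_i_dim <= 0:
            raise ValueError("tau_m and eta_i_dim must be positive")

    @property
    def time_unit(self) -> float:
        """Seconds per nondimensional time unit."""
        return self.tau_m / np.sqrt(self.eta_i_dim)


@dataclass
class QIFParams:
    """Microscopic QIF population (dimensional, time in units of tau_m)."""

    n_neurons: int = 10_000
    v_threshold: float = 100.0
    eta_center: float = 1.0
    delta: float = 1.0
    J: float = 0.0
    tau_m: float = 0.010
    dt: float = 2e-4      # in tau_m units
    duration: float = 40.0  # in tau_m units
    rate_window: float = 1.0  # sliding rate window, tau_m units

    def __post_init__(self) -> None:
        if self.n_neurons < 100:
            raise ValueError("need at least 100 neurons")
        if self.rate_window < self.dt:
            raise ValueError("rate window shorter than dt")

    @property
    def v_reset(self) -> float:
        return -self.v_threshold


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel constants (standard literature values)."""

    kappa: float = 0.65   # signal decay, 1/s
    gamma: float = 0.41   # flow autoregulation, 1/s
    tau: float = 0.98     # venous transit time, s
    alpha: float = 0.32   # Grubb vessel stiffness exponent
    rho: float = 0.34     # resting oxygen extraction fraction
    v0: float = 0.02      # resting venous volume fraction

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Nondimensionalization
# ---------------------------------------------------------------------------

def nondimensionalize_params(delta: float, eta_bar: float, J: float,
                             tau_m: float, eta_ref: float):
    """Map dimensional (Delta, eta_bar, J) to nondimensional (d, eta, j)."""
    if eta_ref <= 0:
        raise ValueError("reference scale must be positive")
    s = np.sqrt(eta_ref)
    return delta / eta_ref, eta_bar / eta_ref, J / s


def dimensionalize_params(d: float, eta: float, j: float,
                          tau_m: float, eta_ref: float):
    """Inverse of :func:`nondimensionalize_params`."""
    if eta_ref <= 0:
        raise ValueError("reference scale must be positive")
    s = np.sqrt(eta_ref)
    return d * eta_ref, eta * eta_ref, j * s


def nondim_state(R, V, tau_m: float, eta_ref: float):
    s = np.sqrt(eta_ref)
    return tau_m * np.asarray(R) / s, np.asarray(V) / s


def dim_state(r, v, tau_m: float, eta_ref: float):
    s = np.sqrt(eta_ref)
    return np.asarray(r) * s / tau_m, np.asarray(v) * s


def nondim_time(t, tau_m: float, eta_ref: float):
    return np.sqrt(eta_ref) * np.asarray(t) / tau_m


# ---------------------------------------------------------------------------
# Fixed points and bifurcation curve
# ---------------------------------------------------------------------------

def fre_single_fixed_point(d: float, eta: float, j: float) -> tuple[float, float]:
    """Quiescent/active fixed point of one nondimensional population.

    Solves 0 = d/pi + 2 r v and 0 = v^2 + eta - (pi r)^2 + j r with r > 0.
    """
    def eqs(y):
        r = np.exp(y[0])
        v = y[1]
        return [d / np.pi + 2 * r * v, v**2 + eta - (np.pi * r) ** 2 + j * r]

    best = None
    for r0 in (0.05, 0.3, 1.0, 3.0):
        sol, info, ier, _ = fsolve(eqs, [np.log(r0), -0.5], full_output=True)
        if ier == 1:
            cand = (float(np.exp(sol[0])), float(sol[1]))
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        raise RuntimeError("no fixed point found")
    return best


def fre_fixed_point(params: FREParams) -> np.ndarray:
    """Fixed point (re, ve, ri, vi) of one uncoupled E-I region."""
    de = float(np.atleast_1d(params.d_e)[0])
    di = float(np.atleast_1d(params.d_i)[0])
    eta, jee, jei, jie, jii = (params.eta, params.j_ee, params.j_ei,
                               params.j_ie, params.j_ii)

    def eqs(y):
        re, ve, ri, vi = np.exp(y[0]), y[1], np.exp(y[2]), y[3]
        return [de / np.pi + 2 * re * ve,
                ve**2 + eta - (np.pi * re) ** 2 + jee * re + jei * ri,
                di / np.pi + 2 * ri * vi,
                vi**2 + 1 - (np.pi * ri) ** 2 + jii * ri + jie * re]

    for re0 in (0.1, 0.5, 1.0, 2.0, 0.02):
        y0 = [np.log(re0), -0.5, np.log(re0), -0.5]
        sol, info, ier, _ = fsolve(eqs, y0, full_output=True)
        if ier == 1:
            return np.array([np.exp(sol[0]), sol[1], np.exp(sol[2]), sol[3]])
    raise RuntimeError("no E-I fixed point found")


def _jacobian(fp: np.ndarray, params: FREParams) -> np.ndarray:
    re, ve, ri, vi = fp
    jee, jei, jie, jii = params.j_ee, params.j_ei, params.j_ie, params.j_ii
    return np.array([
        [2 * ve, 2 * re, 0, 0],
        [-2 * np.pi**2 * re + jee, 2 * ve, jei, 0],
        [0, 0, 2 * vi, 2 * ri],
        [jie, 0, -2 * np.pi**2 * ri + jii, 2 * vi],
    ])


def _max_real_eig(params: FREParams) -> float:
    fp = fre_fixed_point(params)
    return float(np.linalg.eigvals(_jacobian(fp, params)).real.max())


def locate_hopf_curve(
    d_e_values: np.ndarray,
    params: FREParams | None = None,
    d_i_range: tuple[float, float] = (0.05, 4.0),
    tol: float = 1e-9,
) -> list[tuple[float, float | None]]:
    """Hopf bifurcation curve in the (d_e, d_i) plane.

    For each d_e, bisects on d_i for the zero crossing of the largest
    real part of the Jacobian eigenvalues at the uncoupled fixed point.
    A d_e with no sign change in range maps to (d_e, None).
    """
    params = params or FREParams()
    curve: list[tuple[float, float | None]] = []
    for de in np.atleast_1d(d_e_values):
        def f(di):
            return _max_real_eig(replace(params, d_e=float(de), d_i=float(di)))
        lo, hi = d_i_range
        try:
            flo, fhi = f(lo), f(hi)
            if flo * fhi > 0:
                curve.append((float(de), None))
                continue
            curve.append((float(de), float(brentq(f, lo, hi, xtol=tol))))
        except RuntimeError:
            curve.append((float(de), None))
    return curve


def heterogeneous_d(
    d0_e: float,
    d0_i: float,
    bias: float,
    scale: float,
    hmap: HeterogeneityMap,
    mode: str = "multiplicative",
) -> tuple[np.ndarray, np.ndarray]:
    """Heterogeneity-modulated half-widths, applied equally to E and I.

    Same convention as the Stuart-Landau modulation: (0, 0) returns the
    homogeneous values.  Nonpositive results are clipped to a small
    positive floor (logged).
    """
    beta = hmap.beta
    if mode == "multiplicative":
        fac = 1.0 + bias + scale * beta
        de, di = d0_e * fac, d0_i * fac
    elif mode == "additive":
        de, di = d0_e + bias + scale * beta, d0_i + bias + scale * beta
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_clip = int(np.sum(de <= 0) + np.sum(di <= 0))
    if n_clip:
        logger.warning("heterogeneous_d: clipped %d nonpositive half-widths", n_clip)
    return np.maximum(de, D_FLOOR), np.maximum(di, D_FLOOR)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def simulate_fre_network(
    params: FREParams,
    bundle: ConnectomeBundle,
    seed: int = 0,
    n_trials: int = 1,
    subsample: int = 1,
) -> np.ndarray:
    """Euler(-Maruyama) integration of the nondimensional FRE network.

    Returns excitatory rates with shape (n_trials, N, T) (squeezed to
    (N, T) when ``n_trials`` is 1).  Trials are independent noise
    realizations integrated in one vectorized pass.  ``subsample`` keeps
    every k-th post-transient step.
    """
    n = bundle.n_regions
    C = bundle.C
    de = np.broadcast_to(np.asarray(params.d_e, float), (n,))[None, :]
    di = np.broadcast_to(np.asarray(params.d_i, float), (n,))[None, :]
    eta, jee, jei, jie, jii = (params.eta, params.j_ee, params.j_ei,
                               params.j_ie, params.j_ii)
    G, dt = params.G, params.dt
    rng = np.random.default_rng(seed)
    n_steps = int(round((params.duration + params.transient) / dt))
    n_trans = int(round(params.transient / dt))
    sq = params.noise_v * np.sqrt(dt)

    # start near the uncoupled fixed point with a small perturbation
    try:
        fp = fre_fixed_point(params if np.isscalar(params.d_e) else
                             replace(params, d_e=float(np.mean(de)),
                                     d_i=float(np.mean(di))))
    except RuntimeError:
        fp = np.array([0.5, -0.5, 0.5, -0.5])
    shape = (n_trials, n)
    re = np.full(shape, fp[0]) * (1 + 0.01 * rng.standard_normal(shape))
    ve = np.full(shape, fp[1]) + 0.01 * rng.standard_normal(shape)
    ri = np.full(shape, fp[2]) * (1 + 0.01 * rng.standard_normal(shape))
    vi = np.full(shape, fp[3]) + 0.01 * rng.standard_normal(shape)

    out = np.empty((n_trials, n, (n_steps - n_trans + subsample - 1) // subsample))
    k = 0
    for step in range(n_steps):
        coupling = G * jee * (re @ C.T)
        dre = de / np.pi + 2 * re * ve
        dve = ve**2 + eta - (np.pi * re) ** 2 + jee * re + jei * ri + coupling
        dri = di / np.pi + 2 * ri * vi
        dvi = vi**2 + 1 - (np.pi * ri) ** 2 + jii * ri + jie * re
        re = np.maximum(re + dt * dre, 0.0)
        ri = np.maximum(ri + dt * dri, 0.0)
        if params.noise_v > 0:
            ve = ve + dt * dve + sq * rng.standard_normal(shape)
            vi = vi + dt * dvi + sq * rng.standard_normal(shape)
        else:
            ve = ve + dt * dve
            vi = vi + dt * dvi
        if step >= n_trans:
            if (step - n_trans) % subsample == 0:
                out[:, :, k] = re
                k += 1
        if (step + 1) % 2000 == 0 and np.max(np.abs(ve)) > BLOWUP:
            raise FloatingPointError(
                f"FRE integration diverged; reduce dt (currently {dt})"
            )
    out = out[:, :, :k]
    return out[0] if n_trials == 1 else out


def simulate_fre_single(
    d: float,
    eta: float,
    j: float,
    r0: float,
    v0: float,
    duration: float,
    dt: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One nondimensional population (deterministic Euler); returns t, r, v."""
    n_steps = int(round(duration / dt))
    r, v = r0, v0
    rs, vs = np.empty(n_steps + 1), np.empty(n_steps + 1)
    rs[0], vs[0] = r, v
    for i in range(n_steps):
        dr = d / np.pi + 2 * r * v
        dv = v**2 + eta - (np.pi * r) ** 2 + j * r
        r, v = max(r + dt * dr, 0.0), v + dt * dv
        rs[i + 1], vs[i + 1] = r, v
    return np.arange(n_steps + 1) * dt, rs, vs


def simulate_fre_dimensional(
    delta: float,
    eta_bar: float,
    J: float,
    tau_m: float,
    R0: float,
    V0: float,
    duration: float,
    dt: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dimensional single-population FRE (Euler); returns t (s), R, V.

    tau_m dR/dt = Delta/(pi tau_m) + 2 R V
    tau_m dV/dt = V^2 + eta_bar - (pi tau_m R)^2 + J tau_m R
    """
    if dt is None:
        dt = 1e-3 * tau_m
    n_steps = int(round(duration / dt))
    R, V = R0, V0
    Rs, Vs = np.empty(n_steps + 1), np.empty(n_steps + 1)
    Rs[0], Vs[0] = R, V
    for i in range(n_steps):
        dR = (delta / (np.pi * tau_m) + 2 * R * V) / tau_m
        dV = (V**2 + eta_bar - (np.pi * tau_m * R) ** 2 + J * tau_m * R) / tau_m
        R, V = max(R + dt * dR, 0.0), V + dt * dV
        Rs[i + 1], Vs[i + 1] = R, V
    return np.arange(n_steps + 1) * dt, Rs, Vs


# ---------------------------------------------------------------------------
# Microscopic QIF population
# ---------------------------------------------------------------------------

def lorentzian_quantiles(center: float, delta: float, n: int) -> np.ndarray:
    """Deterministic Lorentzian sample: quantile grid of n currents."""
    k = np.arange(1, n + 1)
    return center + delta * np.tan(0.5 * np.pi * (2 * k - n - 1) / (n + 1))


def simulate_qif_population(
    qif: QIFParams,
    drive: np.ndarray | float = 0.0,
    seed: int = 0,
) -> dict:
    """Euler integration of N coupled QIF neurons (time in tau_m units).

    Input currents are drawn deterministically from the Lorentzian
    quantile function; ``drive`` is an extra common input (scalar or a
    per-step array in tau_m-unit sampling).  Neurons that cross the
    (finite) peak voltage spike, are reset to the opposite sign, and held
    refractory for 2/v_threshold time units — the standard finite-threshold
    correction for the infinite-threshold QIF.

    Returns a dict with spike-count based rate estimates:
    ``t`` (tau_m units), ``rate`` (spikes/neuron per tau_m unit, sliding
    window), ``rate_hz`` (same in 1/s), ``v_median`` (robust population
    voltage), and ``spike_counts`` per step.
    """
    n, dt = qif.n_neurons, qif.dt
    n_steps = int(round(qif.duration / dt))
    eta = lorentzian_quantiles(qif.eta_center, qif.delta, n)
    rng = np.random.default_rng(seed)
    v = rng.uniform(-2.0, 2.0, size=n)
    refractory = np.zeros(n)
    ref_time = 2.0 / qif.v_threshold
    drive_arr = np.broadcast_to(np.asarray(drive, float), (n_steps,)) \
        if np.ndim(drive) <= 1 and np.size(drive) in (1, n_steps) \
        else None
    if drive_arr is None:
        raise ValueError("drive must be scalar or one value per step")

    counts = np.zeros(n_steps)
    v_med = np.empty(n_steps)
    r_inst = 0.0  # recurrent rate estimate (spikes/neuron per tau_m)
    for i in range(n_steps):
        active = refractory <= 0
        I = eta + qif.J * r_inst + drive_arr[i]
        dv = v * v + I
        v = np.where(active, v + dt * dv, v)
        crossed = active & (v >= qif.v_threshold)
        nc = int(np.count_nonzero(crossed))
        if nc:
            v[crossed] = -v[crossed]          # reset to mirrored voltage
            refractory[crossed] = ref_time
        refractory[~crossed] -= dt
        counts[i] = nc
        r_inst = nc / (n * dt)
        v_med[i] = np.median(v)

    win = max(1, int(round(qif.rate_window / dt)))
    kernel = np.ones(win) / (win * dt * n)
    rate = np.convolve(counts, kernel, mode="same")
    t = (np.arange(n_steps) + 1) * dt
    return {
        "t": t,
        "rate": rate,
        "rate_hz": rate / qif.tau_m,
        "v_median": v_med,
        "spike_counts": counts,
    }


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def balloon_windkessel(
    rates: np.ndarray,
    dt: float,
    tr: float,
    hemo: HemodynamicParams | None = None,
    zscore_input: bool = True,
) -> np.ndarray:
    """Balloon-Windkessel transform of rate time series to BOLD.

    Integrates, per region, the 4-state hemodynamic ODE (vasodilatory
    signal s, inflow f, venous volume v, deoxyhemoglobin q) driven by the
    (optionally z-scored) rate, with the nonlinear BOLD readout, and
    downsamples from the input step ``dt`` (s) to ``tr`` (s).
    """
    hemo = hemo or HemodynamicParams()
    z = np.atleast_2d(np.asarray(rates, dtype=float))
    if zscore_input:
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - z.mean(axis=1, keepdims=True)) / sd
    n, T = z.shape
    s = np.zeros(n)
    f = np.ones(n)
    vol = np.ones(n)
    q = np.ones(n)
    k1 = 7 * hemo.rho
    k2 = 2.0
    k3 = 2 * hemo.rho - 0.2
    bold = np.empty((n, T))
    ia = 1.0 / hemo.alpha
    for i in range(T):
        E = 1 - (1 - hemo.rho) ** (1.0 / f)
        ds = z[:, i] - hemo.kappa * s - hemo.gamma * (f - 1)
        df = s
        dv = (f - vol**ia) / hemo.tau
        dq = (f * E / hemo.rho - vol ** (ia - 1) * q) / hemo.tau
        s = s + dt * ds
        f = np.maximum(f + dt * df, 1e-6)
        vol = np.maximum(vol + dt * dv, 1e-6)
        q = np.maximum(q + dt * dq, 1e-6)
        if np.max(np.abs(s)) > 1e6:
            raise FloatingPointError(
                f"hemodynamic integration diverged; reduce dt (currently {dt} s)"
            )
        bold[:, i] = hemo.v0 * (k1 * (1 - q) + k2 * (1 - q / vol) + k3 * (1 - vol))
    stride = max(1, int(round(tr / dt)))
    return bold[:, ::stride]


def _pool(x: np.ndarray, k: int) -> np.ndarray:
    """Average-pool the last axis in blocks of k."""
    if k <= 1:
        return x
    T = (x.shape[-1] // k) * k
    return x[..., :T].reshape(*x.shape[:-1], T // k, k).mean(axis=-1)


def simulate_meanfield_bold(
    params: FREParams,
    bundle: ConnectomeBundle,
    seed: int,
    tr: float,
    duration_s: float,
    hemo: HemodynamicParams | None = None,
    hemo_dt: float = 0.01,
    n_trials: int = 1,
    band: tuple[float, float] = (0.008, 0.08),
) -> BOLDDataset:
    """FRE network -> excitatory rates -> Balloon-Windkessel BOLD dataset.

    ``duration_s`` is wall-clock signal length in seconds; the FRE runs in
    nondimensional units internally and its rates are average-pooled to
    ``hemo_dt`` before the hemodynamic stage.
    """
    unit = params.time_unit
    p = replace(params, duration=duration_s / unit)
    pool = max(1, int(round(hemo_dt / (params.dt * unit))))
    rates = simulate_fre_network(p, bundle, seed=seed, n_trials=n_trials)
    if n_trials == 1:
        rates = rates[None]
    subjects = []
    for tr_i in range(n_trials):
        pooled = _pool(rates[tr_i], pool)
        subjects.append(balloon_windkessel(pooled, dt=hemo_dt, tr=tr, hemo=hemo))
    return BOLDDataset(subjects=subjects, tr=tr, band=band)
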