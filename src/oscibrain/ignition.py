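"""Causal ignition: region-to-global-synchronization transfer entropy.

For each region n, causal ignition (CI) quantifies how much the recent
history of that region's oscillation amplitude A_n improves prediction
of the next-step global synchronization level (the Kuramoto order
parameter, KoP), beyond what KoP's own history already predicts:

    I_n = H(KoP_{i+1} | KoP^i) - H(KoP_{i+1} | A_n^i, KoP^i)

with all entropies computed under a Gaussian approximation — i.e. from
(conditional) covariances of lag-embedded windows of length T — so I_n
is a Gaussian transfer entropy / Granger causality from amplitude to
global phase coherence.  CI normalizes I_n by the total predictive
information the joint past (A_n^i, KoP^i) carries about KoP_{i+1},
giving a value in [0, 1].

Significance per region and subject comes from circularly shifted
amplitude surrogates; subject-level p values are aggregated with
Stouffer's method and masked across regions by Benjamini-Hochberg FDR.
CIfit is the Pearson correlation of group-averaged empirical vs modeled
CI restricted to the empirically significant regions.

For coarsely sampled data the proxy CI — the lag-1 correlation between
A_n(t) and KoP(t+1) — replaces the full estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import BOLDDataset, analytic_signal, bandpass_filter
from .observables import EDGE_DISCARD, compute_kop

__all__ = [
    "CIResult",
    "gaussian_entropies",
    "conditional_mi",
    "normalize_ci",
    "transfer_entropy_ci",
    "surrogate_pvalue",
    "aggregate_stouffer",
    "fdr_mask",
    "compute_ci_dataset",
    "ci_fit",
    "proxy_ci",
]

logger = logging.getLogger(__name__)

#: Default embedding window length (samples).
T_DEFAULT = 10

#: Relative ridge added to near-singular covariances.
RIDGE = 1e-8

#: Default correlation-shrinkage intensity for embedding covariances.
SHRINKAGE = 0.1

_LOG2PIE = np.log(2 * np.pi * np.e)


def _shrunk_cov(X: np.ndarray, alpha: float) -> np.ndarray:
    """Sample covariance with correlations shrunk toward the identity.

    The lag-embedded covariances are high-dimensional relative to the
    number of effectively independent windows (band-limited series are
    strongly autocorrelated), so the raw log-determinants are noisy.
    Shrinking the correlation matrix toward the identity by ``alpha``
    stabilizes them; variances are kept untouched.  ``alpha = 0`` is the
    plain sample covariance.
    """
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    if alpha <= 0:
        return S
    sd = np.sqrt(np.diag(S)).copy()
    sd[sd == 0] = 1.0
    R = S / np.outer(sd, sd)
    R = (1 - alpha) * R + alpha * np.eye(R.shape[0])
    return R * np.outer(sd, sd)


def _logdet_psd(m: np.ndarray) -> float:
    """log det of a PSD matrix, adding a ridge when not positive definite."""
    m = np.atleast_2d(m)
    sign, ld = np.linalg.slogdet(m)
    if sign <= 0 or not np.isfinite(ld):
        ridge = RIDGE * np.trace(m) / m.shape[0]
        ridge = ridge if ridge > 0 else RIDGE
        logger.debug("singular covariance: adding ridge %g", ridge)
        sign, ld = np.linalg.slogdet(m + ridge * np.eye(m.shape[0]))
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance not positive definite")
    return float(ld)


def _cond_cov(cov: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
    """Schur complement: covariance of Y given Z (ridge on failure)."""
    syy = cov[np.ix_(iy, iy)]
    if iz.size == 0:
        return syy
    szz = cov[np.ix_(iz, iz)]
    syz = cov[np.ix_(iy, iz)]
    try:
        sol = np.linalg.solve(szz, syz.T)
    except np.linalg.LinAlgError:
        ridge = RIDGE * np.trace(szz) / szz.shape[0]
        logger.debug("conditioning covariance singular: ridge %g", ridge)
        sol = np.linalg.solve(szz + ridge * np.eye(szz.shape[0]), syz.T)
    return syy - syz @ sol


def _gaussian_h(cov: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> float:
    """Differential entropy H(Y|Z) = dy/2 log 2 pi e + 1/2 log det Sigma_Y|Z."""
    cc = _cond_cov(cov, iy, iz)
    return 0.5 * len(iy) * _LOG2PIE + 0.5 * _logdet_psd(cc)


class _Embedding:
    """Lag embedding of a KoP series with pluggable amplitude block.

    Columns of the joint vector: [KoP_{i+1} | KoP past window | A past
    window]; the KoP-only entropy terms are cached since surrogates only
    permute the amplitude stream.
    """

    def __init__(self, kop: np.ndarray, T: int, shrinkage: float = SHRINKAGE):
        kop = np.asarray(kop, float).ravel()
        self.shrinkage = shrinkage
        if T < 1:
            raise ValueError("embedding window T must be >= 1")
        L = kop.size
        self.n_windows = L - T
        if self.n_windows < 5 * (2 * T + 1):
            raise ValueError(
                f"series too short: {self.n_windows} windows for "
                f"dimension {2 * T + 1} (need >= {5 * (2 * T + 1)})"
            )
        self.T, self.L = T, L
        self.fut = kop[T:]                                   # (n_w,)
        self.kp = sliding_window_view(kop, T)[: self.n_windows]  # (n_w, T)
        self._iy = np.array([0])
        self._iz_k = np.arange(1, T + 1)
        self._iz_ka = np.arange(1, 2 * T + 1)
        base = np.column_stack([self.fut, self.kp])
        cov_k = _shrunk_cov(base, shrinkage)
        self.h_fut = _gaussian_h(np.atleast_2d(cov_k), self._iy, np.array([], int))
        self.h_fut_given_k = _gaussian_h(cov_k, self._iy, self._iz_k)

    def amplitude_block(self, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, float).ravel()
        if a.size != self.L:
            raise ValueError("amplitude series length mismatch")
        return sliding_window_view(a, self.T)[: self.n_windows]

    def entropies(self, a: np.ndarray) -> dict[str, float]:
        ap = self.amplitude_block(a)
        X = np.column_stack([self.fut, self.kp, ap])
        cov = _shrunk_cov(X, self.shrinkage)
        ia = np.arange(self.T + 1, 2 * self.T + 1)
        return {
            "h_fut": self.h_fut,
            "h_fut_given_kop": self.h_fut_given_k,
            "h_amp_given_kop": _gaussian_h(cov, ia, self._iz_k),
            "h_fut_given_kop_amp": _gaussian_h(cov, self._iy, self._iz_ka),
        }

    def ci(self, a: np.ndarray) -> tuple[float, float, float]:
        """Returns (CI, I_n, I_total) for one amplitude stream."""
        h = self.entropies(a)
        i_n = self.h_fut_given_k - h["h_fut_given_kop_amp"]
        total = self.h_fut - h["h_fut_given_kop_amp"]
        return normalize_ci(i_n, total), i_n, total


def gaussian_entropies(kop: np.ndarray, amplitude: np.ndarray,
                       T: int = T_DEFAULT,
                       shrinkage: float = 0.0) -> dict[str, float]:
    """The four Gaussian entropy terms of the transfer-entropy decomposition.

    Keys: ``h_fut`` = H(KoP_{i+1}), ``h_fut_given_kop`` =
    H(KoP_{i+1}|KoP^i), ``h_amp_given_kop`` = H(A_n^i|KoP^i),
    ``h_fut_given_kop_amp`` = H(KoP_{i+1}|KoP^i, A_n^i).  Each term is
    dim/2 log 2 pi e + 1/2 log det of the (conditional) covariance over
    all window positions.
    """
    return _Embedding(kop, T, shrinkage=shrinkage).entropies(amplitude)


def conditional_mi(kop: np.ndarray, amplitude: np.ndarray,
                   T: int = T_DEFAULT, shrinkage: float = 0.0) -> float:
    """Transfer entropy I_n = H(KoP_{i+1}|KoP^i) - H(KoP_{i+1}|A_n^i, KoP^i)."""
    _, i_n, _ = _Embedding(kop, T, shrinkage=shrinkage).ci(amplitude)
    return i_n


def normalize_ci(i_n: float, total: float, eps: float = 1e-12) -> float:
    """CI = I_n / I_total clipped to [0, 1]; degenerate totals map to 0."""
    if total <= eps:
        logger.warning("normalize_ci: total MI %g <= eps; CI set to 0", total)
        return 0.0
    ci = i_n / total
    if ci < 0 or ci > 1:
        logger.debug("CI %g clipped to [0,1]", ci)
    return float(min(max(ci, 0.0), 1.0))


def transfer_entropy_ci(kop: np.ndarray, amplitude: np.ndarray,
                        T: int = T_DEFAULT,
                        shrinkage: float = 0.0) -> tuple[float, float, float]:
    """Returns (CI, I_n, I_total) for one region's amplitude stream.

    The low-level estimators default to the plain sample covariance
    (``shrinkage=0``); the dataset-level routines default to the shrunk
    estimator for profile stability.
    """
    return _Embedding(kop, T, shrinkage=shrinkage).ci(amplitude)


def surrogate_pvalue(
    kop: np.ndarray,
    amplitude: np.ndarray,
    T: int = T_DEFAULT,
    n_surrogates: int = 100,
    seed: int | np.random.Generator = 0,
    shrinkage: float = SHRINKAGE,
) -> float:
    """Circular-shift surrogate p value for one region's CI.

    The amplitude series is rolled by uniform random offsets restricted to
    [T+1, L-T-1] (so surrogate windows are genuinely misaligned), CI is
    recomputed for each, and p = (1 + #{CI_surr >= CI_obs}) / (1 + n).
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates")
    kop = np.asarray(kop, float).ravel()
    if kop.size < 4 * T:
        raise ValueError("series shorter than 4*T")
    emb = _Embedding(kop, T, shrinkage=shrinkage)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs, _, _ = emb.ci(amplitude)
    lo, hi = T + 1, kop.size - T - 1
    if hi <= lo:
        raise ValueError("series too short for circular shifts")
    shifts = rng.integers(lo, hi + 1, size=n_surrogates)
    exceed = sum(
        emb.ci(np.roll(amplitude, int(s)))[0] >= obs for s in shifts
    )
    return (1 + exceed) / (1 + n_surrogates)


def aggregate_stouffer(pvals: np.ndarray) -> float:
    """Stouffer combination: z = sum Phi^{-1}(1-p_s)/sqrt(S); p = 1 - Phi(z)."""
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        raise ValueError("no p values to aggregate")
    p = np.clip(p, 1e-15, 1 - 1e-15)
    z = stats.norm.isf(p).sum() / np.sqrt(p.size)
    return float(stats.norm.sf(z))


def fdr_mask(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up mask over regions."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    reject, *_ = multipletests(np.asarray(pvals, float).ravel(),
                               alpha=q, method="fdr_bh")
    return reject


@dataclass
class CIResult:
    """Per-subject CI with optional surrogate statistics.

    ``ci`` is (subjects, regions); ``group_ci`` its subject mean.  When
    surrogate testing ran, ``pvals`` holds per-subject p values,
    ``group_p`` the Stouffer-aggregated ones and ``mask`` the BH-FDR
    significance mask (derived from empirical data only).
    """

    ci: np.ndarray
    group_ci: np.ndarray
    pvals: np.ndarray | None = None
    group_p: np.ndarray | None = None
    mask: np.ndarray | None = None


def _subject_kop_amp(bold: BOLDDataset, edge_discard: int):
    """Filtered KoP series and amplitude matrix per subject."""
    for s in bold.subjects:
        filt = bandpass_filter(s, bold.tr, *bold.band)
        panel = analytic_signal(filt)
        kop, _ = compute_kop(panel, edge_discard=0)
        amps = panel.amplitudes
        if edge_discard > 0 and kop.size > 2 * edge_discard:
            kop = kop[edge_discard:-edge_discard]
            amps = amps[:, edge_discard:-edge_discard]
        yield kop, amps


def compute_ci_dataset(
    bold: BOLDDataset,
    T: int = T_DEFAULT,
    with_pvalues: bool = False,
    n_surrogates: int = 100,
    q: float = 0.05,
    seed: int = 0,
    edge_discard: int = EDGE_DISCARD,
    shrinkage: float = SHRINKAGE,
) -> CIResult:
    """CI vectors (and optional surrogate statistics) for a whole dataset.

    KoP is computed per subject from filtered BOLD phases; windows advance
    by one sample.  ``with_pvalues`` triggers the full surrogate /
    Stouffer / FDR cascade (used on the empirical arm to build the mask).
    """
    rng = np.random.default_rng(seed)
    ci_rows, p_rows = [], []
    for kop, amps in _subject_kop_amp(bold, edge_discard):
        emb = _Embedding(kop, T, shrinkage=shrinkage)
        ci_rows.append([emb.ci(amps[n])[0] for n in range(amps.shape[0])])
        if with_pvalues:
            p_rows.append([
                surrogate_pvalue(kop, amps[n], T=T,
                                 n_surrogates=n_surrogates, seed=rng,
                                 shrinkage=shrinkage)
                for n in range(amps.shape[0])
            ])
    ci = np.asarray(ci_rows)
    result = CIResult(ci=ci, group_ci=ci.mean(axis=0))
    if with_pvalues:
        pv = np.asarray(p_rows)
        group_p = np.array([aggregate_stouffer(pv[:, n]) for n in range(pv.shape[1])])
        result.pvals = pv
        result.group_p = group_p
        result.mask = fdr_mask(group_p, q=q)
    return result


def ci_fit(emp: CIResult | np.ndarray, mod: CIResult | np.ndarray,
           mask: np.ndarray | None = None) -> float:
    """Pearson correlation of group CI vectors on the empirical mask."""
    emp_v = emp.group_ci if isinstance(emp, CIResult) else np.asarray(emp, float)
    mod_v = mod.group_ci if isinstance(mod, CIResult) else np.asarray(mod, float)
    if mask is None and isinstance(emp, CIResult):
        mask = emp.mask
    if mask is None:
        mask = np.ones(emp_v.size, dtype=bool)
    mask = np.asarray(mask, bool)
    if emp_v.size != mod_v.size or mask.size != emp_v.size:
        raise ValueError("CI vectors and mask must share a length")
    if mask.sum() < 3:
        raise ValueError("fewer than 3 regions survive the mask")
    return float(np.corrcoef(emp_v[mask], mod_v[mask])[0, 1])


def proxy_ci(bold: BOLDDataset, edge_discard: int = EDGE_DISCARD) -> np.ndarray:
    """Low-sampling proxy: corr(A_n(t), KoP(t+1)) per region, group mean.

    Used in place of the full transfer-entropy CI when the repetition
    time is too coarse for the lag embedding.  Constant streams give 0.
    """
    rows = []
    for kop, amps in _subject_kop_amp(bold, edge_discard):
        if kop.size < 3:
            raise ValueError("need at least 3 samples")
        fut = kop[1:]
        out = np.empty(amps.shape[0])
        for n in range(amps.shape[0]):
            a = amps[n, :-1]
            if a.std() == 0 or fut.std() == 0:
                logger.warning("proxy_ci: constant stream for region %d -> 0", n)
                out[n] = 0.0
            else:
                out[n] = np.corrcoef(a, fut)[0, 1]
        rows.append(out)
    return np.mean(rows, axis=0)
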