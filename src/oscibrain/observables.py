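"""Static and dynamic whole-brain observables and their fit statistics.

* FC — region-pair Pearson correlation matrix over the full recording, and
  FCfit, the correlation of the strict upper triangles of group-averaged
  empirical vs modeled FC.
* GBC — per-region mean FC row (diagonal included, so the homogeneous
  shift 1/N is shared by every region), and GBCfit.
* KoP — Kuramoto order parameter of the instantaneous BOLD phases,
  KoP(t) = |sum_p exp(i phi_p(t))| / N, summarized by its temporal mean;
  ErrKoP is the absolute difference between group-mean empirical and
  modeled KoP levels.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import AnalyticPanel, BOLDDataset, analytic_signal, bandpass_filter

__all__ = [
    "compute_fc",
    "fc_fit",
    "compute_gbc",
    "gbc_fit",
    "compute_kop",
    "err_kop",
    "group_fc",
    "dataset_kop_mean",
    "ObservablePanel",
]

logger = logging.getLogger(__name__)

#: Samples dropped at each end after the Hilbert transform (edge effects).
EDGE_DISCARD = 10


def compute_fc(bold: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of an (N, T) signal block.

    Zero-variance regions get zero correlations (diagonal kept at 1).
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if bold.shape[1] < 3:
        raise ValueError("need at least 3 samples for FC")
    sd = bold.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        logger.warning("FC: %d zero-variance region(s); correlations set to 0",
                       int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(bold)
    fc[np.isnan(fc)] = 0.0
    np.fill_diagonal(fc, 1.0)
    return fc


def group_fc(dataset: BOLDDataset, filter_band: bool = True) -> np.ndarray:
    """Group-averaged FC over subjects, optionally band-pass filtering first."""
    mats = []
    for s in dataset.subjects:
        x = bandpass_filter(s, dataset.tr, *dataset.band) if filter_band else s
        mats.append(compute_fc(x))
    return np.mean(mats, axis=0)


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def fc_fit(emp: np.ndarray, mod: np.ndarray) -> float:
    """Pearson correlation of strict upper triangles of two FC matrices."""
    emp, mod = np.asarray(emp, float), np.asarray(mod, float)
    if emp.shape != mod.shape or emp.shape[0] != emp.shape[1]:
        raise ValueError("FC matrices must be square and share a shape")
    if emp.shape[0] < 3:
        raise ValueError("need at least 3 regions for FCfit")
    return float(np.corrcoef(_upper(emp), _upper(mod))[0, 1])


def compute_gbc(fc: np.ndarray) -> np.ndarray:
    """Global brain connectivity: GBC_i = sum_j FC_ij / N (diagonal kept)."""
    fc = np.asarray(fc, dtype=float)
    return fc.sum(axis=1) / fc.shape[0]


def gbc_fit(emp: np.ndarray, mod: np.ndarray) -> float:
    """Pearson correlation of group-averaged GBC vectors."""
    emp, mod = np.ravel(emp), np.ravel(mod)
    if emp.size != mod.size:
        raise ValueError("GBC vectors must share a length")
    return float(np.corrcoef(emp, mod)[0, 1])


def compute_kop(panel: AnalyticPanel | np.ndarray,
                edge_discard: int = EDGE_DISCARD) -> tuple[np.ndarray, float]:
    """Kuramoto order parameter series and its temporal mean.

    Accepts an :class:`AnalyticPanel` or a raw (N, T) phase matrix.
    ``edge_discard`` samples are dropped at each end of the series before
    the temporal mean (Hilbert edge transients); the returned series is the
    trimmed one.
    """
    phases = panel.phases if isinstance(panel, AnalyticPanel) else np.atleast_2d(panel)
    n = phases.shape[0]
    kop = np.abs(np.exp(1j * phases).sum(axis=0)) / n
    if edge_discard > 0 and kop.size > 2 * edge_discard:
        kop = kop[edge_discard:-edge_discard]
    return kop, float(kop.mean())


def dataset_kop_mean(dataset: BOLDDataset, filter_band: bool = True,
                     edge_discard: int = EDGE_DISCARD) -> float:
    """Mean-over-subjects of each subject's temporal-mean KoP."""
    means = []
    for s in dataset.subjects:
        x = bandpass_filter(s, dataset.tr, *dataset.band) if filter_band else s
        _, m = compute_kop(analytic_signal(x), edge_discard=edge_discard)
        means.append(m)
    return float(np.mean(means))


def err_kop(emp: BOLDDataset | float, mod: BOLDDataset | float) -> float:
    """Absolute difference between empirical and modeled group KoP levels.

    Accepts datasets (filtered internally) or precomputed scalar levels.
    """
    a = dataset_kop_mean(emp) if isinstance(emp, BOLDDataset) else float(emp)
    b = dataset_kop_mean(mod) if isinstance(mod, BOLDDataset) else float(mod)
    return abs(a - b)


class ObservablePanel:
    """Convenience bundle: FC, GBC, and KoP of one (N, T) BOLD block."""

    def __init__(self, bold: np.ndarray, tr: float,
                 band: tuple[float, float] = (0.008, 0.08)):
        filtered = bandpass_filter(bold, tr, *band)
        self.fc = compute_fc(filtered)
        self.gbc = compute_gbc(self.fc)
        panel = analytic_signal(filtered)
        self.kop_series, self.kop_mean = compute_kop(panel)
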