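"""Core containers and I/O for whole-brain network modeling.

Holds the structural connectome, regional heterogeneity maps and BOLD
datasets used by every downstream stage, plus the two signal-processing
primitives shared by all observables: zero-phase band-pass filtering in
the resting-state band and Hilbert analytic-signal extraction.

File formats are deliberately plain: whitespace/comma-delimited matrices
for connectomes and BOLD, one value per line for maps, TSV for centroid
coordinates, and an optional HDF5 container bundling multi-subject BOLD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ConnectomeBundle",
    "HeterogeneityMap",
    "BOLDDataset",
    "AnalyticPanel",
    "read_connectome",
    "write_connectome",
    "read_coords",
    "write_coords",
    "read_map",
    "write_map",
    "read_bold",
    "write_bold",
    "read_bold_h5",
    "write_bold_h5",
    "bandpass_filter",
    "analytic_signal",
]

logger = logging.getLogger(__name__)

#: Resting-state narrowband used throughout (Hz).
DEFAULT_BAND = (0.008, 0.08)

#: Maximum coupling weight after connectome normalization.
CONNECTOME_MAX = 0.2


@dataclass
class ConnectomeBundle:
    """Structural coupling matrix with region labels and centroids.

    Attributes
    ----------
    C : (N, N) ndarray
        Symmetric nonnegative coupling weights, zero diagonal.  After
        normalization the maximum entry is exactly 0.2.
    labels : list of str
        Region names, in matrix order.
    coords : (N, 3) ndarray
        Region centroid coordinates in mm.
    """

    C: np.ndarray
    labels: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError(f"coupling matrix must be square, got {self.C.shape}")
        if self.C.shape[0] < 2:
            raise ValueError("connectome needs at least 2 regions")
        if not self.labels:
            self.labels = [f"region_{i}" for i in range(self.C.shape[0])]
        if len(self.labels) != self.C.shape[0]:
            raise ValueError("label count does not match matrix size")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.C.shape[0], 3):
                raise ValueError("coords must be (N, 3)")

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


@dataclass
class HeterogeneityMap:
    """Per-region scalar modulating local bifurcation parameters.

    ``beta`` is dimensionless; empirically it would be a T1w/T2w ratio or a
    node-level global-brain-connectivity value.
    """

    beta: np.ndarray
    source_tag: str = "synthetic"  # one of: t1t2, gbc, synthetic, surrogate

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("heterogeneity map contains non-finite values")
        if self.source_tag not in ("t1t2", "gbc", "synthetic", "surrogate"):
            raise ValueError(f"unknown source_tag {self.source_tag!r}")

    def __len__(self) -> int:
        return self.beta.size


@dataclass
class BOLDDataset:
    """Multi-subject BOLD signals sampled at repetition time ``tr``.

    Each subject is an (N, T) matrix in arbitrary units; all subjects share
    the region count N but may differ in length T.
    """

    subjects: list[np.ndarray]
    tr: float
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        self.subjects = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.subjects]
        if not self.subjects:
            raise ValueError("dataset needs at least one subject")
        n = self.subjects[0].shape[0]
        for s in self.subjects:
            if s.shape[0] != n:
                raise ValueError("all subjects must share the region count")
            if s.shape[1] < 2:
                raise ValueError("subject time series too short")

    @property
    def n_regions(self) -> int:
        return self.subjects[0].shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class AnalyticPanel:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) and amplitudes."""

    phases: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.phases.shape != self.amplitudes.shape:
            raise ValueError("phases and amplitudes must share a shape")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_matrix(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(str(path), delimiter=delim)


def read_connectome(
    path: str | Path,
    normalize: bool = True,
    labels: Sequence[str] | None = None,
    coords: np.ndarray | None = None,
) -> ConnectomeBundle:
    """Load a square coupling matrix, symmetrize, zero the diagonal.

    Asymmetric input is averaged with its transpose.  With ``normalize``
    the matrix is rescaled so its maximum entry equals 0.2 exactly.
    """
    M = np.atleast_2d(_load_matrix(path))
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"connectome file is not square: {M.shape}")
    if np.any(M < 0):
        raise ValueError("connectome has negative weights")
    C = 0.5 * (M + M.T)
    np.fill_diagonal(C, 0.0)
    mx = C.max()
    if mx == 0:
        raise ValueError("connectome has no nonzero off-diagonal weight")
    if normalize:
        C = C * (CONNECTOME_MAX / mx)
        C[C == C.max()] = CONNECTOME_MAX
    return ConnectomeBundle(C=C, labels=list(labels) if labels else [], coords=coords)


def write_connectome(bundle: ConnectomeBundle, path: str | Path) -> None:
    np.savetxt(str(path), bundle.C, fmt="%.17g")


def read_coords(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV with columns label, x, y, z."""
    df = pd.read_csv(path, sep="\t")
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    return df["label"].astype(str).tolist(), df[["x", "y", "z"]].to_numpy(float)


def write_coords(labels: Sequence[str], coords: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"label": list(labels), "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2]}
    ).to_csv(path, sep="\t", index=False)


def read_map(path: str | Path, n_regions: int | None = None,
             source_tag: str = "synthetic") -> HeterogeneityMap:
    """Read a one-value-per-line heterogeneity map."""
    beta = np.loadtxt(str(path)).ravel()
    if n_regions is not None and beta.size != n_regions:
        raise ValueError(f"map length {beta.size} does not match N={n_regions}")
    return HeterogeneityMap(beta=beta, source_tag=source_tag)


def write_map(hmap: HeterogeneityMap, path: str | Path) -> None:
    np.savetxt(str(path), hmap.beta, fmt="%.17g")


def read_bold(paths: Sequence[str | Path], tr: float,
              band: tuple[float, float] = DEFAULT_BAND) -> BOLDDataset:
    """Read one delimited (regions x samples) matrix per subject."""
    return BOLDDataset(subjects=[_load_matrix(p) for p in paths], tr=tr, band=band)


def write_bold(dataset: BOLDDataset, directory: str | Path,
               prefix: str = "subject") -> list[Path]:
    """Write one TSV per subject; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, s in enumerate(dataset.subjects):
        p = directory / f"{prefix}_{i:03d}.tsv"
        np.savetxt(str(p), s, fmt="%.17g", delimiter="\t")
        out.append(p)
    return out


def write_bold_h5(dataset: BOLDDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["tr"] = dataset.tr
        f.attrs["band"] = dataset.band
        for i, s in enumerate(dataset.subjects):
            f.create_dataset(f"subject_{i:03d}", data=s)


def read_bold_h5(path: str | Path) -> BOLDDataset:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f.keys() if k.startswith("subject_"))
        subjects = [f[k][()] for k in keys]
        tr = float(f.attrs["tr"])
        band = tuple(float(b) for b in f.attrs["band"])
    return BOLDDataset(subjects=subjects, tr=tr, band=band)


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

def bandpass_filter(
    signals: np.ndarray,
    tr: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    Rows are demeaned first; the filter is applied forward-backward
    (``filtfilt``) so phase is not distorted — essential for the phase
    observables downstream.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    nyq = 0.5 / tr
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz infeasible for tr={tr} s (Nyquist {nyq:.4g} Hz)"
        )
    sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    demeaned = signals - signals.mean(axis=1, keepdims=True)
    padlen = min(3 * (2 * order + 1), signals.shape[1] - 1)
    return sps.sosfiltfilt(sos, demeaned, axis=1, padlen=padlen)


def analytic_signal(filtered: np.ndarray) -> AnalyticPanel:
    """Per-row Hilbert analytic signal: instantaneous phase and amplitude.

    Zero rows get amplitude 0 and phase 0 by convention (np.angle(0) == 0).
    """
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    z = sps.hilbert(filtered, axis=1)
    phases = np.angle(z)
    # wrap -pi to +pi so the interval is (-pi, pi]
    phases = np.where(phases == -np.pi, np.pi, phases)
    return AnalyticPanel(phases=phases, amplitudes=np.abs(z))
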