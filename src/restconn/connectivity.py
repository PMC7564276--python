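"""Spectral estimation and connectivity metrics.

Two complementary pairwise coupling measures:

* **Magnitude-squared coherence** — ``Coh_xy(f) = |P_xy(f)|^2 / (P_x(f) P_y(f))``
  from Welch-averaged auto/cross spectra. A linear, amplitude-and-phase
  measure; inflated by any zero-lag common signal (volume conduction).

* **Phase lag index** — ``PLI_xy = | (1/N) Σ_t sign(sin(φ_x(t) − φ_y(t))) |``
  with instantaneous phases from the analytic signal. It scores only the
  *asymmetry* of the phase-difference distribution: common sources give
  Δφ ∈ {0, π}, whose sine's sign is 0 or symmetric, so PLI discards
  exactly the coupling coherence cannot.

Both are bounded in [0, 1] and symmetric in their arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import BandSpec, EpochSet, Recording

__all__ = [
    "SpectralEstimate",
    "ConnectivityMatrix",
    "ThresholdedMatrix",
    "welch_psd",
    "msc",
    "band_average",
    "instantaneous_phase",
    "pli",
    "pli_matrix",
    "coherence_matrix",
    "connectivity_matrix",
    "proportional_threshold",
]


@dataclass
class SpectralEstimate:
    """Welch spectra on a common frequency grid (resolution = 1/window)."""

    frequencies: np.ndarray
    auto_psd: np.ndarray          # (n_channels, n_freqs), real >= 0
    cross_psd: np.ndarray | None = None   # (n_ch, n_ch, n_freqs), complex, Hermitian in pair order


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-diagonal ROI x ROI matrix of a coupling metric."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str          # "pli" | "coherence"
    band: str

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("connectivity matrix must have a zero diagonal")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("connectivity values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle index pair (i, j), i < j — the unique edges."""
        return np.triu_indices(self.n_nodes, k=1)


@dataclass
class ThresholdedMatrix:
    """A connectivity matrix after proportional thresholding."""

    labels: tuple[str, ...]
    values: np.ndarray       # non-retained entries zeroed
    mask: np.ndarray         # boolean, symmetric, True on retained edges
    proportion: float
    metric: str
    band: str

    @property
    def n_retained(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(self.mask[iu].sum())


# ---------------------------------------------------------------------------
# spectra

def _welch_params(n: int, fs: float, window_duration: float, overlap: float):
    nperseg = window_duration * fs
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ValueError(f"window_duration * fs must be integral, got {nperseg}")
    nperseg = int(round(nperseg))
    if nperseg > n:
        raise ValueError(
            f"signal of {n} samples is shorter than one {window_duration} s window "
            f"({nperseg} samples)"
        )
    noverlap = int(round(nperseg * overlap))
    return nperseg, noverlap


def welch_psd(
    x: np.ndarray,
    fs: float,
    window_duration: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Welch power spectral density of one channel.

    Tapered, overlapped segments are periodogram-averaged; density
    scaling, so the PSD integrates to the signal variance (Parseval, up
    to taper bias).
    """
    x = np.asarray(x, dtype=float)
    nperseg, noverlap = _welch_params(x.shape[-1], fs, window_duration, overlap)
    f, p = sps.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    return SpectralEstimate(frequencies=f, auto_psd=np.atleast_2d(p))


def _n_segments(n: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    return (n - nperseg) // step + 1


def msc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_duration: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum of two equal-length series.

    Estimated from Welch-averaged auto and cross spectra. A single
    window is refused: averaging over one segment makes the estimator
    identically 1 regardless of the signals (the degenerate case).

    Returns
    -------
    (frequencies, coherence) — coherence in [0, 1] at every frequency.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nperseg, noverlap = _welch_params(x.shape[-1], fs, window_duration, overlap)
    k = _n_segments(x.shape[-1], nperseg, noverlap)
    if k < 2:
        raise ValueError(
            f"coherence needs >= 2 windows ({k} available): with a single averaged "
            "segment the estimate is identically 1 (degenerate)"
        )
    f, coh = sps.coherence(x, y, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    return f, np.clip(coh, 0.0, 1.0)


def band_average(frequencies: np.ndarray, values: np.ndarray, band: BandSpec) -> float:
    """Arithmetic mean of ``values`` over bins with ``low <= f < high``."""
    sel = (frequencies >= band.low) & (frequencies < band.high)
    if not sel.any():
        raise ValueError(
            f"no frequency bins inside band {band.name!r} [{band.low}, {band.high}) Hz"
        )
    return float(np.mean(values[..., sel], axis=-1))


# ---------------------------------------------------------------------------
# phase metrics

def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase: the argument of the analytic signal.

    The input should be narrow-band (the phase of a broadband signal is
    not physically interpretable). Values lie in (−π, π]; the only
    discontinuities are ±π wraps.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x != 0):
        raise ValueError("instantaneous phase is undefined for an all-zero signal")
    return np.angle(sps.hilbert(x, axis=-1))


def pli(phi_x: np.ndarray, phi_y: np.ndarray) -> float:
    """Phase lag index of two instantaneous-phase series.

    The absolute mean of the sign of the sine of the per-sample phase
    difference; ``sign(0)`` contributes 0, so two identical signals give
    exactly 0 (the zero-lag case PLI is built to suppress).
    """
    phi_x = np.asarray(phi_x, dtype=float)
    phi_y = np.asarray(phi_y, dtype=float)
    if phi_x.shape != phi_y.shape:
        raise ValueError(f"length mismatch: {phi_x.shape} vs {phi_y.shape}")
    if phi_x.size == 0:
        raise ValueError("PLI needs at least one sample")
    return float(np.abs(np.mean(np.sign(np.sin(phi_x - phi_y)))))


def _edge_trim_slice(n: int, frac: float) -> slice:
    cut = int(np.floor(n * frac))
    return slice(cut, n - cut if cut else n)


def pli_matrix(epochs: EpochSet, band: str | None = None, edge_trim: float = 0.05) -> ConnectivityMatrix:
    """Per-epoch PLI between every channel pair, averaged over epochs.

    Phases come from the analytic signal of each (already narrow-band)
    epoch; the first and last ``edge_trim`` fraction of samples of each
    epoch are excluded from the sum because the Hilbert transform's
    circular convolution distorts phase near the segment edges.
    """
    if not 0 <= edge_trim < 0.5:
        raise ValueError(f"edge_trim must lie in [0, 0.5), got {edge_trim}")
    data = epochs.data
    # phase per epoch/channel; all-zero traces get phase 0 and contribute
    # sign(sin(0)) = 0, matching the all-zero PLI convention
    phases = np.angle(sps.hilbert(data, axis=-1))
    keep = _edge_trim_slice(epochs.n_samples, edge_trim)
    phases = phases[..., keep]
    n_ch = epochs.n_channels
    mat = np.zeros((n_ch, n_ch))
    iu, ju = np.triu_indices(n_ch, k=1)
    # (epochs, pairs, samples) sign-sine, mean over samples then epochs
    dphi = phases[:, iu, :] - phases[:, ju, :]
    per_epoch = np.abs(np.mean(np.sign(np.sin(dphi)), axis=-1))   # (epochs, pairs)
    vals = per_epoch.mean(axis=0)
    mat[iu, ju] = vals
    mat[ju, iu] = vals
    return ConnectivityMatrix(epochs.labels, mat, metric="pli", band=band or (epochs.band or ""))


def coherence_matrix(
    rec: Recording,
    band: BandSpec,
    window_duration: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> ConnectivityMatrix:
    """Band-averaged magnitude-squared coherence between every pair.

    Welch auto/cross spectra over all ``window_duration`` windows of the
    full recording (not the band-split version: the band is selected by
    averaging the coherence spectrum over the band's frequency bins).
    """
    band.validate_for_fs(rec.fs)
    nperseg, noverlap = _welch_params(rec.n_samples, rec.fs, window_duration, overlap)
    k = _n_segments(rec.n_samples, nperseg, noverlap)
    if k < 2:
        raise ValueError("coherence needs >= 2 Welch windows (degenerate otherwise)")
    f, pxx = sps.welch(rec.data, fs=rec.fs, window=window, nperseg=nperseg, noverlap=noverlap)
    sel = (f >= band.low) & (f < band.high)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name!r}")
    n_ch = rec.n_channels
    mat = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            _, pxy = sps.csd(
                rec.data[i], rec.data[j], fs=rec.fs, window=window,
                nperseg=nperseg, noverlap=noverlap,
            )
            coh = np.abs(pxy) ** 2 / (pxx[i] * pxx[j])
            val = float(np.clip(coh[sel], 0.0, 1.0).mean())
            mat[i, j] = mat[j, i] = val
    return ConnectivityMatrix(rec.labels, mat, metric="coherence", band=band.name)


def connectivity_matrix(
    data: EpochSet | Recording,
    band: BandSpec,
    metric: str,
    edge_trim: float = 0.05,
    window_duration: float = 2.0,
    overlap: float = 0.5,
) -> ConnectivityMatrix:
    """Dispatch to :func:`pli_matrix` or :func:`coherence_matrix`.

    PLI expects band-split epochs; coherence expects the raw (wideband)
    recording, since it selects the band in the frequency domain.
    """
    if metric == "pli":
        if not isinstance(data, EpochSet):
            raise ValueError("PLI requires a band-split EpochSet, got a Recording")
        return pli_matrix(data, band=band.name, edge_trim=edge_trim)
    if metric == "coherence":
        if not isinstance(data, Recording):
            raise ValueError("coherence requires the wideband Recording, got an EpochSet")
        return coherence_matrix(data, band, window_duration=window_duration, overlap=overlap)
    raise ValueError(f"unknown metric {metric!r}; expected 'pli' or 'coherence'")


# ---------------------------------------------------------------------------
# thresholding

def proportional_threshold(m: ConnectivityMatrix, proportion: float = 0.20) -> ThresholdedMatrix:
    """Keep the strongest ``proportion`` of unique edges, zero the rest.

    Retains ``k = floor(proportion * P)`` edges out of the ``P`` unique
    off-diagonal pairs. Ties at the cutoff break deterministically by
    lexicographic (row, column) order.
    """
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must lie in (0, 1], got {proportion}")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    p_pairs = len(iu)
    k = int(np.floor(proportion * p_pairs))
    if k == 0:
        raise ValueError(
            f"proportion {proportion} retains 0 of {p_pairs} edges; nothing to test"
        )
    vals = m.values[iu, ju]
    # stable sort on (-value, row, col): lexicographic tie-break
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    mask |= mask.T
    values = np.where(mask, m.values, 0.0)
    return ThresholdedMatrix(
        labels=m.labels, values=values, mask=mask,
        proportion=proportion, metric=m.metric, band=m.band,
    )
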