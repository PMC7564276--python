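"""Core containers for the connectivity pipeline.

A :class:`Recording` is the raw unit of input: a labeled multichannel
time series with a sampling rate (sensor channels or region-of-interest
traces — the pipeline does not care which). A :class:`BandSpec` names a
frequency band, and an :class:`EpochSet` holds fixed-length segments cut
from a recording; its ``n_samples`` is the N of the phase-lag-index sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Recording", "BandSpec", "EpochSet", "DMN_LABELS"]

#: The 14 default-mode-network regions (Desikan–Killiany parcellation,
#: both hemispheres): medial/lateral orbitofrontal, parahippocampal,
#: isthmus cingulate, precuneus, posterior cingulate and rostral
#: anterior cingulate cortex.
DMN_LABELS: tuple[str, ...] = (
    "L MOF", "R MOF",
    "L LOF", "R LOF",
    "L ParaH", "R ParaH",
    "L ICC", "R ICC",
    "L Precun", "R Precun",
    "L PCC", "R PCC",
    "L RACC", "R RACC",
)


@dataclass
class Recording:
    """Labeled multichannel time series.

    Parameters
    ----------
    labels
        Ordered channel (or ROI) names, one per row of ``data``.
    fs
        Sampling rate in Hz.
    data
        Array of shape ``(n_channels, n_samples)``; finite values only.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got shape {self.data.shape}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, labels: Sequence[str] | None = None) -> "Recording":
        return Recording(tuple(labels) if labels is not None else self.labels, self.fs, data)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    def validate_for_fs(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz reaches the Nyquist "
                f"frequency {fs / 2} Hz"
            )


#: Band definitions used throughout: alpha 7.5-12.5, beta 12.5-30, gamma 30-40 Hz.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("alpha", 7.5, 12.5),
    BandSpec("beta", 12.5, 30.0),
    BandSpec("gamma", 30.0, 40.0),
)
__all__.append("DEFAULT_BANDS")


@dataclass
class EpochSet:
    """Equal-length segments cut from a recording.

    ``data`` has shape ``(n_epochs, n_channels, n_samples)``;
    ``n_samples`` per epoch equals ``epoch_duration * fs`` exactly.
    """

    labels: tuple[str, ...]
    fs: float
    data: np.ndarray
    epoch_duration: float
    overlap: float = 0.0
    band: str | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"epoch data must be 3-D, got shape {self.data.shape}")
        n = round(self.epoch_duration * self.fs)
        if self.data.shape[2] != n:
            raise ValueError(
                f"epoch length {self.data.shape[2]} != epoch_duration*fs = {n}"
            )
        if not 0 <= self.overlap < 1:
            raise ValueError(f"overlap must lie in [0, 1), got {self.overlap}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        """Samples per epoch — the N of the PLI sum."""
        return self.data.shape[2]
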