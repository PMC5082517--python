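"""Core EEG segment container.

A segment is a short (typically 20 s) multichannel excerpt of scalp EEG in
microvolts, together with its sampling rate, 10-20 channel labels and a tag
recording which frequency band it currently occupies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Standard 19-channel 10-20 montage, in conventional order.
MONTAGE_10_20 = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "O2",
)

#: Valid band tags. ``raw`` marks unfiltered data straight from disk or the
#: generator; the three others correspond to the filtering stages.
BAND_TAGS = ("raw", "broadband", "alpha", "low_alpha")


class SegmentValidationError(ValueError):
    """Raised when an EEG segment violates its structural contract."""


@dataclass
class EEGSegment:
    """Channels x samples EEG matrix with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sample_rate : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique 10-20 style labels, stored upper-case.
    band : str
        One of ``raw``, ``broadband``, ``alpha``, ``low_alpha``.
    """

    data: np.ndarray
    sample_rate: float
    channel_labels: tuple = field(default=())
    band: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise SegmentValidationError(
                f"data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        n_ch, n_samp = self.data.shape
        if n_ch < 2:
            raise SegmentValidationError(f"need >= 2 channels, got {n_ch}")
        if not np.isfinite(self.sample_rate) or self.sample_rate <= 0:
            raise SegmentValidationError(f"sample_rate must be positive, got {self.sample_rate}")
        if n_samp < 2 * self.sample_rate:
            raise SegmentValidationError(
                f"need >= 2 s of data ({int(2 * self.sample_rate)} samples at "
                f"{self.sample_rate} Hz), got {n_samp}"
            )
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, samp = np.argwhere(bad)[0]
            raise SegmentValidationError(
                f"non-finite sample in channel {self.channel_labels[ch] if self.channel_labels else ch}"
                f" (index {ch}) at sample {samp}"
            )
        if not self.channel_labels:
            self.channel_labels = tuple(f"CH{i}" for i in range(n_ch))
        self.channel_labels = tuple(str(c).upper() for c in self.channel_labels)
        if len(self.channel_labels) != n_ch:
            raise SegmentValidationError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise SegmentValidationError("duplicate channel labels")
        if self.band not in BAND_TAGS:
            raise SegmentValidationError(f"unknown band tag {self.band!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.data.shape[1] / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, label: str) -> int:
        label = label.upper()
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in segment (have {', '.join(self.channel_labels)})"
            ) from None

    def variances(self) -> np.ndarray:
        """Per-channel signal variance (microvolt^2)."""
        return self.data.var(axis=1)

    def with_data(self, data: np.ndarray, band: str | None = None) -> "EEGSegment":
        return replace(self, data=data, band=self.band if band is None else band)
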