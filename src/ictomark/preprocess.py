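"""Filtering and normalized power spectra for resting-state EEG.

The pipeline applies, in order: a zero-phase Butterworth band-pass
(0.5-70 Hz) with a 48-52 Hz band-stop against power-line interference, then
optionally a narrow band-pass into the alpha (8-13 Hz) or low-alpha (6-9 Hz)
band.  Power spectra are normalized by a single per-recording constant — the
total spectral power averaged across channels — so that between-subject
amplitude differences (skull thickness, electrode impedance) cancel while
between-channel power ratios are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .segment import EEGSegment

#: Band-pass corners in Hz for the narrowband stages.
BANDS = {"alpha": (8.0, 13.0), "low_alpha": (6.0, 9.0)}

_FILTER_ORDER = 4  # applied forward-backward => effective order 8


class PreprocessError(ValueError):
    pass


def _sos_bandpass(lo, hi, fs):
    return signal.butter(_FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")


def broadband_filter(seg: EEGSegment) -> EEGSegment:
    """Zero-phase Butterworth band-pass 0.5-70 Hz plus band-stop 48-52 Hz.

    Requires a sampling rate above 140 Hz so the 70 Hz passband edge stays
    below Nyquist.
    """
    if seg.sample_rate <= 140.0:
        raise PreprocessError(
            f"sample_rate {seg.sample_rate} Hz too low for a 70 Hz passband edge"
        )
    sos_bp = _sos_bandpass(0.5, 70.0, seg.sample_rate)
    sos_notch = signal.butter(
        _FILTER_ORDER, [48.0, 52.0], btype="bandstop", fs=seg.sample_rate, output="sos"
    )
    x = signal.sosfiltfilt(sos_bp, seg.data, axis=1)
    x = signal.sosfiltfilt(sos_notch, x, axis=1)
    return seg.with_data(x, band="broadband")


def band_filter(seg: EEGSegment, band: str) -> EEGSegment:
    """Zero-phase band-pass into ``alpha`` (8-13 Hz) or ``low_alpha`` (6-9 Hz)."""
    try:
        lo, hi = BANDS[band]
    except KeyError:
        raise PreprocessError(
            f"unknown band {band!r}; choose from {sorted(BANDS)}"
        ) from None
    sos = _sos_bandpass(lo, hi, seg.sample_rate)
    x = signal.sosfiltfilt(sos, seg.data, axis=1)
    return seg.with_data(x, band=band)


@dataclass
class NormalizedSpectrum:
    """Per-channel power spectrum normalized by the cross-channel mean total power.

    ``power[c, f]`` is dimensionless; summing it over frequencies and
    averaging over channels gives exactly 1, so relative power differences
    between channels survive normalization.
    """

    freqs: np.ndarray
    power: np.ndarray              # channels x freqs
    norm_constant: float           # microvolt^2, the divisor applied to all channels
    channel_labels: tuple

    def __post_init__(self):
        total = self.power.sum(axis=1).mean()
        if abs(total - 1.0) > 1e-9:
            raise PreprocessError(
                f"normalization invariant violated: channel-mean total power {total}"
            )

    def channel_power(self, labels) -> np.ndarray:
        """Average the normalized spectrum over the given channels."""
        idx = []
        for lab in labels:
            lab = lab.upper()
            if lab not in self.channel_labels:
                raise KeyError(f"channel {lab!r} not in spectrum")
            idx.append(self.channel_labels.index(lab))
        return self.power[idx].mean(axis=0)


def normalized_spectrum(
    seg: EEGSegment,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> NormalizedSpectrum:
    """Welch power spectrum, normalized by the channel-averaged total power.

    Welch estimation uses Hann-tapered windows of ``window_s`` seconds with
    ``overlap`` fractional overlap.  Every channel's spectrum is divided by
    the same constant (the mean over channels of the frequency-integrated
    power), making the result invariant under global amplitude rescaling.
    """
    nper = int(round(window_s * seg.sample_rate))
    freqs, psd = signal.welch(
        seg.data,
        fs=seg.sample_rate,
        window="hann",
        nperseg=nper,
        noverlap=int(round(nper * overlap)),
        axis=1,
    )
    df = freqs[1] - freqs[0]
    total_per_channel = psd.sum(axis=1) * df
    norm = total_per_channel.mean()
    if norm == 0:
        raise PreprocessError("all-zero input: spectral normalization undefined")
    power = psd * df / norm
    return NormalizedSpectrum(
        freqs=freqs, power=power, norm_constant=float(norm),
        channel_labels=seg.channel_labels,
    )
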