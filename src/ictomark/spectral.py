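"""Alpha-peak frequency over occipital channels — comparator biomarker 1.

The dominant posterior alpha rhythm shifts toward lower frequencies in
people with idiopathic generalized epilepsy, so the peak frequency of the
occipital normalized power spectrum is used as a scalar biomarker with
"lower is more IGE-like" polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedSpectrum

#: Default occipital channel set.
OCCIPITAL = ("O1", "O2")

#: Peak search window in Hz (covers the alpha and low-alpha bands).
SEARCH_WINDOW = (6.0, 14.0)


@dataclass
class AlphaPeak:
    peak_freq: float          # Hz
    peak_power: float         # normalized power at the peak bin
    channel_set: tuple        # labels averaged over
    flat: bool = False        # True when the windowed spectrum had no structure

    def __post_init__(self):
        lo, hi = SEARCH_WINDOW
        if not (lo <= self.peak_freq <= hi):
            raise ValueError(f"peak_freq {self.peak_freq} outside search window {SEARCH_WINDOW}")
        if not self.channel_set:
            raise ValueError("channel_set must be non-empty")


def alpha_peak(
    spectrum: NormalizedSpectrum,
    channels=OCCIPITAL,
    window: tuple = SEARCH_WINDOW,
) -> AlphaPeak:
    """Frequency of maximal normalized power over a channel set.

    The normalized spectra of the requested channels are averaged and the
    argmax within the search window returned.  Exact ties are broken toward
    the lower frequency.  A completely flat windowed spectrum still returns
    the (lowest-frequency) argmax but sets ``flat=True``.
    """
    mean_power = spectrum.channel_power(channels)
    lo, hi = window
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside window {window}")
    freqs = spectrum.freqs[mask]
    power = mean_power[mask]
    best = int(np.argmax(power))  # argmax returns the first (lowest-f) maximum
    flat = bool(np.ptp(power) == 0)
    return AlphaPeak(
        peak_freq=float(freqs[best]),
        peak_power=float(power[best]),
        channel_set=tuple(c.upper() for c in channels),
        flat=flat,
    )
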