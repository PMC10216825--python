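"""EEG frequency-band extraction by discrete wavelet reconstruction.

Each signal is decomposed with a level-5 Daubechies DWT (db4 by default)
and a band is reconstructed by zeroing every coefficient vector outside
that band and inverse-transforming, so the output is a time series of the
same length as the input — the form the Granger-causality stage needs.

Band definitions follow the classical EEG ranges: delta 0–4 Hz, theta
4–8 Hz, alpha 8–16 Hz, beta 16–32 Hz and gamma 32–64 Hz.  At the 128 Hz
reference rate a level-5 DWT splits the spectrum dyadically into
A5 ≈ 0–2, D5 ≈ 2–4, D4 ≈ 4–8, D3 ≈ 8–16, D2 ≈ 16–32 and D1 ≈ 32–64 Hz, so
each band maps onto the coefficient sets whose dyadic intervals cover its
range (delta takes both A5 and D5).  Sampling rates other than 128 Hz are
accepted; the dyadic intervals are recomputed and a warning is logged
because the nominal band names then shift in frequency.

Theta is implemented but excluded from the default band list, and the
pass-through band ``"all"`` returns the signal unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .data_model import Trial, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BAND_RANGES_HZ",
    "DEFAULT_BANDS",
    "BandSpec",
    "band_components",
    "band_set",
    "extract_band",
]

#: Nominal EEG band ranges in Hz at the 128 Hz reference rate.
BAND_RANGES_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 64.0),
}

#: Bands used by default; theta is defined but excluded.
DEFAULT_BANDS: tuple[str, ...] = ("delta", "alpha", "beta", "gamma", "all")

DEFAULT_WAVELET_ORDER = 4
DEFAULT_LEVEL = 5
_DWT_MODE = "symmetric"


@dataclass(frozen=True)
class BandSpec:
    """A named band with its frequency range and DWT coefficient indices.

    ``components`` are indices into the ``pywt.wavedec`` coefficient list
    ``[A_L, D_L, D_{L-1}, ..., D_1]``; the ``"all"`` band has none and
    bypasses decomposition.
    """

    name: str
    freq_range: tuple[float, float] | None
    components: tuple[int, ...]


def _dyadic_intervals(fs: float, level: int) -> list[tuple[float, float]]:
    """Frequency interval of each wavedec coefficient vector, A_L first."""
    nyquist = fs / 2.0
    edges = [nyquist / 2**k for k in range(level + 1)]  # nyquist .. nyquist/2^L
    intervals = [(0.0, edges[level])]  # approximation A_L
    for k in range(level, 0, -1):  # D_L ... D_1
        intervals.append((edges[k], edges[k - 1]))
    return intervals


def band_components(band: str, fs: float = 128.0, level: int = DEFAULT_LEVEL) -> BandSpec:
    """Resolve a band name to its coefficient indices for ``fs`` and ``level``.

    A coefficient vector belongs to a band when the majority of its dyadic
    interval lies inside the band's nominal range.
    """
    if band == "all":
        return BandSpec("all", None, ())
    if band not in BAND_RANGES_HZ:
        raise ValidationError(
            f"unknown band {band!r}; expected one of "
            f"{sorted(BAND_RANGES_HZ)} or 'all'"
        )
    if fs != 128.0:
        logger.warning(
            "sampling rate %.6g Hz differs from the 128 Hz reference; "
            "dyadic band edges recomputed accordingly", fs,
        )
    lo, hi = BAND_RANGES_HZ[band]
    members = []
    for idx, (c_lo, c_hi) in enumerate(_dyadic_intervals(fs, level)):
        overlap = max(0.0, min(hi, c_hi) - max(lo, c_lo))
        if overlap > 0.5 * (c_hi - c_lo):
            members.append(idx)
    return BandSpec(band, (lo, hi), tuple(members))


def extract_band(
    signal: np.ndarray,
    fs: float,
    band: str | BandSpec,
    wavelet_order: int = DEFAULT_WAVELET_ORDER,
    level: int = DEFAULT_LEVEL,
) -> np.ndarray:
    """Reconstruct one frequency band of ``signal`` at the original length.

    All DWT coefficient vectors outside the band are zeroed before the
    inverse transform.  Band ``"all"`` returns a copy of the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValidationError(f"expected 1-D signal, got shape {signal.shape}")
    spec = band if isinstance(band, BandSpec) else band_components(band, fs, level)
    if spec.name == "all":
        return signal.copy()
    min_len = 2**level
    if len(signal) < min_len:
        raise ValidationError(
            f"signal of length {len(signal)} too short for a level-{level} "
            f"DWT; minimum length is {min_len}"
        )
    wavelet = pywt.Wavelet(f"db{wavelet_order}")
    coeffs = pywt.wavedec(signal, wavelet, level=level, mode=_DWT_MODE)
    kept = [
        c if idx in spec.components else np.zeros_like(c)
        for idx, c in enumerate(coeffs)
    ]
    recon = pywt.waverec(kept, wavelet, mode=_DWT_MODE)
    return recon[: len(signal)]


def band_set(
    trial: Trial,
    bands: tuple[str, ...] = DEFAULT_BANDS,
    wavelet_order: int = DEFAULT_WAVELET_ORDER,
    level: int = DEFAULT_LEVEL,
) -> dict[str, Trial]:
    """Apply :func:`extract_band` channel-wise for each requested band.

    Returns a mapping band name → derived :class:`Trial` with unchanged
    channel order and metadata.
    """
    out: dict[str, Trial] = {}
    for band in bands:
        spec = band_components(band, trial.fs, level)
        data = np.vstack(
            [
                extract_band(row, trial.fs, spec, wavelet_order, level)
                for row in trial.data
            ]
        )
        out[band] = Trial(
            data=data,
            fs=trial.fs,
            channel_names=trial.channel_names,
            subject_id=trial.subject_id,
            trial_id=trial.trial_id,
        )
    return out
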