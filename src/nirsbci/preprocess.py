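"""Filtering chain: detrend (0.01 Hz), smooth (0.15 Hz), CBSI motion correction.

The chain mirrors common fNIRS practice: subtract a very-low-pass
Savitzky–Golay estimate of the baseline (detrending), low-pass the result
to suppress cardiac/respiratory oscillations (smoothing), then apply
correlation-based signal improvement (CBSI), which exploits the assumed
perfect anticorrelation of true ΔHbO/ΔHb and the common-mode nature of
motion artifacts.  Filters run over whole continuous block recordings —
a 0.01 Hz filter is meaningless on a 30 s trial — and trials are sliced
out afterwards.  Channels are never mixed.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .params import FilterSettings
from .recording import HemoRecording

#: empirical Savitzky–Golay −3 dB approximation: f_c·Δt ≈ (p+1)/(3.2·W − 4.6)
_SG_NUM = 3.2
_SG_DEN = 4.6


def sg_window_for_cutoff(cutoff: float, rate: float, degree: int = 1) -> int:
    """Odd window length whose degree-``degree`` SG smoother has its −3 dB
    point closest to ``cutoff`` Hz.

    The empirical approximation f_c·Δt ≈ (p+1)/(3.2·W − 4.6) seeds the
    search; because it drifts for low polynomial orders, the window is
    then refined against the numerically measured transfer function (the
    −3 dB point is monotone decreasing in W).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz is at or above the Nyquist frequency "
            f"{rate / 2} Hz"
        )
    w = int(round(((degree + 1) * rate / cutoff + _SG_DEN) / _SG_NUM))
    w = max(w | 1, 5)

    def realized(win: int) -> float:
        return measured_cutoff(win, degree, rate)

    lo = hi = w
    while realized(lo) < cutoff and lo > 5:
        lo = max(lo - max(2, lo // 4) | 1, 5)
    while realized(hi) > cutoff:
        hi = hi * 2 + 1
    while hi - lo > 2:
        mid = ((lo + hi) // 2) | 1
        if mid in (lo, hi):
            break
        if realized(mid) > cutoff:
            lo = mid
        else:
            hi = mid
    return min((lo, hi), key=lambda win: abs(realized(win) - cutoff))


def sg_response(window: int, degree: int, rate: float,
                n_freq: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies Hz, |H|) of the SG smoother's transfer function."""
    coeffs = sps.savgol_coeffs(window, degree)
    freqs, h = sps.freqz(coeffs, worN=n_freq, fs=rate)
    return freqs, np.abs(h)


@lru_cache(maxsize=256)
def measured_cutoff(window: int, degree: int, rate: float) -> float:
    """Realized −3 dB frequency of the SG smoother, from its response."""
    freqs, mag = sg_response(window, degree, rate)
    below = np.nonzero(mag <= 1 / np.sqrt(2))[0]
    if len(below) == 0:
        return float(freqs[-1])
    i = below[0]
    if i == 0:
        return float(freqs[0])
    # linear interpolation across the -3 dB crossing
    f0, f1 = freqs[i - 1], freqs[i]
    m0, m1 = mag[i - 1], mag[i]
    target = 1 / np.sqrt(2)
    return float(f0 + (target - m0) / (m1 - m0) * (f1 - f0))


def _sg_lowpass(x: np.ndarray, cutoff: float, rate: float,
                degree: int) -> np.ndarray:
    w = sg_window_for_cutoff(cutoff, rate, degree)
    if len(x) < w:
        raise ValueError(
            f"series of {len(x)} samples is shorter than the "
            f"{w}-sample filter window; record at least "
            f"{w / rate:.1f} s at {rate} Hz"
        )
    # mirror padding avoids ramp artifacts leaking into the edge trials
    return sps.savgol_filter(x, w, degree, mode="mirror")


def _per_series(rec: HemoRecording, fn) -> HemoRecording:
    out = rec.copy()
    for ch in out.channels:
        for chromo in ("HbO", "Hb"):
            out.series[ch][chromo] = fn(out.series[ch][chromo])
    return out


def detrend(rec: HemoRecording,
            settings: FilterSettings = FilterSettings()) -> HemoRecording:
    """Subtract the sub-``detrend_cut`` baseline from every series."""
    w = sg_window_for_cutoff(settings.detrend_cut, rec.rate,
                             settings.sg_degree)
    out = _per_series(
        rec,
        lambda x: x - _sg_lowpass(x, settings.detrend_cut, rec.rate,
                                  settings.sg_degree),
    )
    out.log("detrend", cutoff_hz=settings.detrend_cut, window=w,
            degree=settings.sg_degree,
            realized_cutoff_hz=measured_cutoff(w, settings.sg_degree,
                                               rec.rate))
    return out


def smooth(rec: HemoRecording,
           settings: FilterSettings = FilterSettings()) -> HemoRecording:
    """Low-pass every series at ``smooth_cut`` Hz."""
    w = sg_window_for_cutoff(settings.smooth_cut, rec.rate,
                             settings.sg_degree)
    out = _per_series(
        rec,
        lambda x: _sg_lowpass(x, settings.smooth_cut, rec.rate,
                              settings.sg_degree),
    )
    out.log("smooth", cutoff_hz=settings.smooth_cut, window=w,
            degree=settings.sg_degree,
            realized_cutoff_hz=measured_cutoff(w, settings.sg_degree,
                                               rec.rate))
    return out


def cbsi(hbo: np.ndarray, hb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-based signal improvement for one channel.

    Assumes the true responses satisfy hbo = −α·hb with α the ratio of
    their standard deviations, and that motion artifacts enter both
    series identically.  With mean-centered x = hbo, y = hb and
    α = sd(x)/sd(y):

        hbo' = (x − α·y) / 2,   hb' = −hbo'/α

    The corrected pair is exactly anticorrelated by construction.
    """
    hbo = np.asarray(hbo, float)
    hb = np.asarray(hb, float)
    if hbo.shape != hb.shape or hbo.ndim != 1:
        raise ValueError("hbo and hb must be 1-D arrays of equal length")
    if len(hbo) < 2:
        raise ValueError("need at least two samples")
    x = hbo - hbo.mean()
    y = hb - hb.mean()
    sy = y.std()
    if sy == 0:
        raise ValueError("sd(hb) = 0: CBSI scaling factor is undefined")
    alpha = x.std() / sy
    hbo_c = (x - alpha * y) / 2.0
    hb_c = -hbo_c / alpha
    return hbo_c, hb_c


def preprocess_pipeline(
    rec: HemoRecording, settings: FilterSettings = FilterSettings()
) -> HemoRecording:
    """detrend → smooth → per-channel CBSI, in that order.

    Zero-variance channels skip CBSI with a warning instead of failing
    the whole run (degenerate synthetic inputs must not kill batches).
    """
    out = smooth(detrend(rec, settings), settings)
    if not settings.cbsi_enabled:
        return out
    alphas = {}
    for ch in out.channels:
        hbo = out.series[ch]["HbO"]
        hb = out.series[ch]["Hb"]
        if hb.std() == 0 or hbo.std() == 0:
            warnings.warn(
                f"channel {ch!r} has zero variance; skipping CBSI",
                stacklevel=2,
            )
            continue
        hbo_c, hb_c = cbsi(hbo, hb)
        out.series[ch]["HbO"] = hbo_c
        out.series[ch]["Hb"] = hb_c
        alphas[ch] = float(hbo.std() / hb.std())
    out.log("cbsi", alpha=alphas)
    return out
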