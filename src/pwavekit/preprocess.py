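"""Filtering stages feeding the detectors.

Three length-preserving, delay-compensated linear filters:

* :func:`bandpass_qrs` — linear-phase FIR band-pass (Hamming window,
  12–19 Hz passband) that enhances QRS complexes while suppressing the
  slower P and T waves.  DC gain is forced to exactly zero.
* :func:`highpass_lynn` — baseline-wander removal realized as identity minus
  a Lynn-type linear-phase moving-average low-pass (two cascaded boxcar
  sections, i.e. a triangular kernel), cut-off 0.67 Hz.
* :func:`clean` — the generic pre-cleaning stage: baseline removal followed
  by 50/60 Hz zero-phase notch filters.  This stage is an explicit stand-in
  for unspecified upstream preprocessing and can be switched off via
  ``DetectorConfig.apply_clean``.

All filters use reflect padding at the edges (trimmed afterwards) so that
isolated peaks do not move and no spurious edge transients feed the
detectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .config import DetectorConfig
from .io import EcgRecord

__all__ = ["FilteredSignal", "bandpass_qrs", "highpass_lynn", "clean"]


@dataclass
class FilteredSignal:
    """A filtered copy of a record, same length and time axis as the input."""

    samples: np.ndarray
    fs: float
    kind: str  # {"qrs_band", "baseline_free", "cleaned"}

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("filtered signal contains non-finite values")


def _conv_same(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Zero-delay convolution with a symmetric odd-length kernel.

    Reflect-pads by half the kernel, convolves in 'valid' mode and returns
    a signal of the original length aligned with the input.
    """
    half = len(h) // 2
    if len(x) == 0 or half == 0:
        return np.convolve(x, h, mode="same")
    # reflect padding needs pad <= len(x) - 1; fall back to edge replication
    # for signals shorter than the kernel half-length
    mode = "reflect" if half <= len(x) - 1 else "edge"
    xp = np.pad(x, half, mode=mode)
    if len(h) > 128:  # overlap-add is much faster for the long Lynn kernel
        return sp_signal.oaconvolve(xp, h, mode="valid")
    return np.convolve(xp, h, mode="valid")


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def bandpass_qrs(rec: EcgRecord, cfg: DetectorConfig | None = None) -> FilteredSignal:
    """Band-pass the record into the QRS-dominant 12–19 Hz band.

    The FIR length is ``bp_order_factor * fs`` taps (odd), long enough to
    keep the transition bands of the Hamming design below ~5 Hz while
    keeping the impulse-response ringing short.  The mean tap is removed so
    a constant input maps to exactly zero.
    """
    cfg = cfg or DetectorConfig()
    lo, hi = cfg.qrs_band
    if rec.fs < 2.0 * hi + 2.0:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {lo}-{hi} Hz passband"
        )
    numtaps = _odd(max(31, round(cfg.bp_order_factor * rec.fs)))
    h = sp_signal.firwin(numtaps, [lo, hi], pass_zero=False,
                         window="hamming", fs=rec.fs)
    h = h - h.mean()  # exact zero DC gain
    return FilteredSignal(_conv_same(rec.samples, h), rec.fs, "qrs_band")


def _lynn_lowpass_kernel(fs: float, fc: float) -> np.ndarray:
    """Triangular kernel = two cascaded moving averages of length fs/fc."""
    n = max(2, round(fs / fc))
    box = np.ones(n) / n
    tri = np.convolve(box, box)  # length 2n-1, odd, symmetric
    return tri


def highpass_lynn(rec: EcgRecord, cfg: DetectorConfig | None = None) -> FilteredSignal:
    """Remove baseline wander: input minus a Lynn-type moving-average low-pass."""
    cfg = cfg or DetectorConfig()
    tri = _lynn_lowpass_kernel(rec.fs, cfg.lynn_fc)
    baseline = _conv_same(rec.samples, tri)
    return FilteredSignal(rec.samples - baseline, rec.fs, "baseline_free")


def _notch(x: np.ndarray, fs: float, freq: float, q: float) -> np.ndarray:
    b, a = sp_signal.iirnotch(freq, q, fs=fs)
    return sp_signal.filtfilt(b, a, x)


def clean(rec: EcgRecord, cfg: DetectorConfig | None = None) -> FilteredSignal:
    """Baseline removal followed by powerline notches (zero-phase).

    Notch frequencies above 90% of Nyquist are skipped (e.g. 60 Hz at
    fs = 128 Hz).  With ``cfg.apply_clean`` false the record is passed
    through untouched.
    """
    cfg = cfg or DetectorConfig()
    if not cfg.apply_clean:
        return FilteredSignal(rec.samples.copy(), rec.fs, "cleaned")
    y = highpass_lynn(rec, cfg).samples
    for f0 in cfg.notch_freqs:
        if f0 < 0.9 * (rec.fs / 2.0):
            y = _notch(y, rec.fs, f0, cfg.notch_q)
    return FilteredSignal(y, rec.fs, "cleaned")
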