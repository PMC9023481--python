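"""Detector configuration.

Every numeric constant of the detection pipeline lives here, so a run is
fully described by one :class:`DetectorConfig` instance.  The defaults are
the published operating point of the algorithm; each is overridable through
a flat TOML config file (``key = value`` per line) consumed by the CLI.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple


@dataclass
class DetectorConfig:
    # Phasor enhancement factors (one per detection stage).  Smaller values
    # magnify low-amplitude deflections more strongly.
    rv_qrs: float = 0.001
    rv_t: float = 0.1
    rv_p: float = 0.05

    # QRS stage: band-pass passband [Hz], candidate sliding window [s],
    # moving-std window [s], threshold multiple, refractory merge distance [s],
    # backward-search trigger (RR ratio) and amplitude fraction.
    qrs_band: Tuple[float, float] = (12.0, 19.0)
    slide_window: float = 0.3
    std_window: float = 2.0
    std_factor: float = 2.0
    refractory: float = 0.2
    rr_gap_factor: float = 1.75
    back_thresh: float = 0.3

    # T search window: R(i) + t_win[0]*RR .. R(i) + t_win[1]*RR + t_win[2] [s].
    t_win: Tuple[float, float, float] = (0.12, 0.57, 0.060)

    # PVC stage: half-width of the QRS-area window [s], area ratio over the
    # running median, and the bundle-branch-block reset fraction.
    pvc_win: float = 0.150
    pvc_factor: float = 1.3
    pvc_reset_frac: float = 0.75

    # Baseline-removal high-pass cut-off [Hz] (Lynn-type filter).
    lynn_fc: float = 0.67

    # AFIB stage: symbolic-dynamics word-segment length (beats), normalized
    # Shannon-entropy threshold, PVC-count override within the segment,
    # heart-rate quantization bin [bpm] and clip ceiling [bpm].
    sh_window: int = 59
    sh_thresh: float = 0.737
    sh_pvc_override: int = 30
    hr_bin: float = 5.0
    hr_max: float = 315.0

    # Dissociated-P gate: RR ratio, absolute RR floor [s], relaxed ratio when
    # the previous interval already held a dissociated P, and the window
    # margins after T(i-1) / before P(i) [s].
    diss_rr_factor: float = 1.6
    diss_rr_min: float = 1.6
    diss_rr_relax: float = 0.8
    diss_after_t: float = 0.200
    diss_before_p: float = 0.400

    # Normal-P search window: R(i-1) + p_win[0]*RR .. R(i) - p_win[1]*RR -
    # p_win[2] [s]; first beat uses the fixed window R - first_p_win[0] ..
    # R - first_p_win[1].
    p_win: Tuple[float, float, float] = (0.71, 0.07, 0.060)
    first_p_win: Tuple[float, float] = (0.300, 0.080)

    # Voltage verification: candidate amplitude must exceed up_factor times
    # the QRS amplitude of the current beat.
    up_factor: float = 0.05

    # Evaluation matching tolerance [s] (not printed in the source method;
    # configurable, see docs/methods.md).
    eval_tolerance: float = 0.100

    # Pre-cleaning: powerline notch frequencies [Hz] and quality factor;
    # the whole cleaning stage can be switched off.
    notch_freqs: Tuple[float, ...] = (50.0, 60.0)
    notch_q: float = 30.0
    apply_clean: bool = True

    # Band-pass FIR length as a fraction of fs (odd tap count enforced).
    bp_order_factor: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rv_qrs", "rv_t", "rv_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in (
            "slide_window", "std_window", "std_factor", "refractory",
            "rr_gap_factor", "back_thresh", "pvc_win", "pvc_factor",
            "pvc_reset_frac", "lynn_fc", "sh_thresh", "hr_bin", "hr_max",
            "diss_rr_factor", "diss_rr_min", "diss_rr_relax", "diss_after_t",
            "diss_before_p", "up_factor", "eval_tolerance", "notch_q",
            "bp_order_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sh_window < 1 or self.sh_window % 2 == 0:
            raise ValueError("sh_window must be a positive odd beat count")

    # -- flat-file round trip -------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write the config as flat TOML (every field on one line)."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(float(x)) for x in v)}]")
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load a config written by :meth:`to_file` (or any flat TOML subset).

        Keys missing from the file keep their defaults; unknown keys raise.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if isinstance(v, list):
                v = tuple(float(x) for x in v)
            coerced[f.name] = v
        return cls(**coerced)

    def replace(self, **kw) -> "DetectorConfig":
        return dataclasses.replace(self, **kw)
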