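"""Record and annotation I/O.

Two on-disk dialects are supported and normalized to the internal types:

* **WFDB (PhysioNet dialect)** — ``.hea`` text headers with ``.dat`` signal
  files (formats 16 and 212) and MIT-format annotation files.  The codec is
  implemented here from the published format description, covering the
  layouts used by the MITDB / QTDB / BUT PDB record families (no EDF, no
  DICOM-ECG, no streaming).
* **CSV** — one or two numeric columns for signals (value, or time+value with
  the time column ignored) plus an explicit sampling frequency; annotations
  as ``record_id,sample_index,code`` rows.

Sample indices are 0-based everywhere internally; index ``i`` always means
``i/fs`` seconds — readers never rescale time.
"""

from __future__ import annotations

import csv as _csv
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "WaveAnnotations",
    "read_wfdb",
    "write_wfdb",
    "read_csv_record",
    "write_csv_record",
    "read_annotations",
    "write_annotations",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class EcgRecord:
    """A single-lead ECG: physical samples (mV), sampling rate and labels."""

    samples: np.ndarray
    fs: float
    lead: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def require_min_duration(self, seconds: float = 2.0) -> None:
        """Detectors refuse records shorter than ``seconds`` (default 2 s)."""
        if len(self.samples) < seconds * self.fs:
            raise ValueError(
                f"record {self.record_id!r} is {self.duration:.3f} s long; "
                f"at least {seconds} s are required"
            )


def _as_index_array(v) -> np.ndarray:
    a = np.asarray([] if v is None else v, dtype=np.int64).ravel()
    return a


@dataclass
class WaveAnnotations:
    """P (and optionally T, R) peak sample indices, reference or detected."""

    p_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    t_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    r_peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    source: str = "reference"
    record_id: str = ""
    n_samples: int | None = None  # when set, indices are validated against it

    def __post_init__(self) -> None:
        for name in ("p_peaks", "t_peaks", "r_peaks"):
            a = _as_index_array(getattr(self, name))
            if a.size and np.any(np.diff(a) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if a.size and a[0] < 0:
                raise ValueError(f"{name} contains negative indices")
            if self.n_samples is not None and a.size and a[-1] >= self.n_samples:
                raise ValueError(
                    f"{name} contains indices beyond the signal length "
                    f"({a[-1]} >= {self.n_samples})"
                )
            setattr(self, name, a)
        if self.source not in ("reference", "detected"):
            raise ValueError("source must be 'reference' or 'detected'")

    def pairs(self) -> list[tuple[int, str]]:
        """All (sample_index, code) pairs, sorted by index then code."""
        out = [(int(i), "p") for i in self.p_peaks]
        out += [(int(i), "t") for i in self.t_peaks]
        out += [(int(i), "N") for i in self.r_peaks]
        return sorted(out)


# WFDB annotation code numbers <-> display symbols (MIT convention).
_CODE_SYMBOLS = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODES = {s: c for c, s in _CODE_SYMBOLS.items()}

#: Symbols counted as QRS/beat labels when routing annotations to r_peaks.
BEAT_SYMBOLS = frozenset("NLRaVFJASEj/QBe nrf!".replace(" ", ""))

#: Default mapping of which annotation symbols denote a P-wave peak.  The
#: BUT PDB / MIT PDB P-wave annotation files use the WFDB 'p' code; the table
#: is configurable because databases differ.
DEFAULT_P_SYMBOLS = frozenset({"p"})


# ---------------------------------------------------------------------------
# WFDB signals
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        fname = f[0]
        fmt = int(f[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline, units = 200.0, None, "mV"
        if len(f) > 2:
            g = f[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if g else 200.0
            if gain == 0:
                gain = 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(f[8:]) if len(f) > 8 else f"ch{len(signals)}"
        signals.append(
            dict(file=fname, fmt=fmt, gain=gain, baseline=baseline,
                 units=units, desc=desc)
        )
    return record_name, nsig, fs, nsamp, signals


def _read_dat(path: Path, fmt: int, nsig: int) -> np.ndarray:
    """Return the interleaved ADC samples as shape (nframes, nsig)."""
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8).astype(np.int64)
        b = b[: 3 * (len(b) // 3)]
        b0, b1, b2 = b[0::3], b[1::3], b[2::3]
        s1 = ((b1 & 0x0F) << 8) | b0
        s2 = ((b1 & 0xF0) << 4) | b2
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        s2 = np.where(s2 > 2047, s2 - 4096, s2)
        adc = np.empty(2 * len(s1), dtype=np.int64)
        adc[0::2], adc[1::2] = s1, s2
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    nframes = len(adc) // nsig
    return adc[: nframes * nsig].reshape(nframes, nsig)


def read_wfdb(path: str | Path, channel: int = 0) -> EcgRecord:
    """Read one channel of a WFDB record (path without extension).

    The selected channel is returned in physical units,
    ``(adc - baseline) / gain``, with fs taken from the header.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    record_name, nsig, fs, nsamp, signals = _parse_header(hea)
    if not (0 <= channel < nsig):
        raise ValueError(f"channel {channel} out of range for {nsig} signal(s)")
    sig = signals[channel]
    fmts = {s["fmt"] for s in signals}
    if len(fmts) != 1:
        raise ValueError("mixed per-signal formats are not supported")
    dat = path.parent / sig["file"]
    if not dat.exists():
        raise FileNotFoundError(f"signal file not found: {dat}")
    adc = _read_dat(dat, sig["fmt"], nsig)
    if nsamp:
        adc = adc[:nsamp]
    phys = (adc[:, channel] - sig["baseline"]) / sig["gain"]
    return EcgRecord(phys, fs=fs, lead=sig["desc"], record_id=record_name)


def write_wfdb(
    path: str | Path,
    channels: Sequence[np.ndarray] | np.ndarray,
    fs: float,
    record_id: str | None = None,
    leads: Sequence[str] | None = None,
    gain: float = 1000.0,
) -> None:
    """Write channels as a WFDB record (format 16, common gain/baseline 0)."""
    path = Path(path)
    if isinstance(channels, np.ndarray) and channels.ndim == 1:
        channels = [channels]
    channels = [np.asarray(c, dtype=float) for c in channels]
    n = len(channels[0])
    if any(len(c) != n for c in channels):
        raise ValueError("all channels must have the same length")
    record_id = record_id or path.stem
    leads = list(leads or [f"ch{i}" for i in range(len(channels))])
    adc = np.rint(np.stack(channels, axis=1) * gain).astype(np.int64)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("samples exceed the 16-bit ADC range at this gain")
    dat_name = path.stem + ".dat"
    lines = [f"{record_id} {len(channels)} {fs:g} {n}"]
    for i, lead in enumerate(leads):
        first = int(adc[0, i]) if n else 0
        lines.append(
            f"{dat_name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}"
        )
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    (path.parent / dat_name).write_bytes(
        adc.reshape(-1).astype("<i2").tobytes()
    )


# ---------------------------------------------------------------------------
# CSV signals
# ---------------------------------------------------------------------------


def read_csv_record(
    path: str | Path, fs: float, lead: str = "", record_id: str = ""
) -> EcgRecord:
    """Read a plain numeric series: one column (value) or two (time, value).

    The time column, when present, is ignored — ``fs`` is authoritative.
    """
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    values = data[:, -1]
    return EcgRecord(values, fs=fs, lead=lead,
                     record_id=record_id or Path(path).stem)


def write_csv_record(rec: EcgRecord, path: str | Path) -> None:
    t = np.arange(len(rec.samples)) / rec.fs
    np.savetxt(path, np.column_stack([t, rec.samples]), delimiter=",",
               fmt="%.9g")


# ---------------------------------------------------------------------------
# annotations (MIT format and CSV)
# ---------------------------------------------------------------------------

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _read_atr_pairs(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    pairs: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise ValueError(f"truncated SKIP in {path}")
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            v = (hi << 16) | lo
            if v >= 1 << 31:
                v -= 1 << 32
            pending += v
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += interval + (interval & 1)
        else:
            t += interval + pending
            pending = 0
            sym = _CODE_SYMBOLS.get(code)
            if sym is None:
                raise ValueError(f"unknown annotation code {code} in {path}")
            pairs.append((t, sym))
    return pairs


def _write_atr_pairs(path: Path, pairs: Iterable[tuple[int, str]]) -> None:
    out = bytearray()
    t = 0
    for idx, sym in sorted(pairs):
        code = _SYMBOL_CODES.get(sym)
        if code is None:
            raise ValueError(f"symbol {sym!r} has no WFDB annotation code")
        dt = idx - t
        if dt < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if dt > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (code << 10) | dt)
        t = idx
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


def _read_csv_pairs(path: Path) -> list[tuple[int, str]]:
    pairs = []
    with open(path, newline="") as fh:
        for row in _csv.reader(fh):
            if not row or row[0].strip().startswith("#"):
                continue
            if row[0].strip() == "record_id":  # header line
                continue
            if len(row) >= 3:
                idx, sym = int(row[1]), row[2].strip()
            else:
                idx, sym = int(row[0]), row[1].strip()
            pairs.append((idx, sym))
    return sorted(pairs)


def read_annotations(
    path: str | Path,
    symbol_filter: Iterable[str] | None = None,
    source: str = "reference",
) -> WaveAnnotations:
    """Read P/T/R peak annotations from a MIT-format or CSV file.

    ``symbol_filter`` keeps only the listed annotation codes (an explicitly
    empty set keeps nothing).  Retained codes are routed by convention:
    ``p`` to ``p_peaks``, ``t`` to ``t_peaks``, beat symbols to ``r_peaks``;
    other retained symbols are dropped.  Indices are returned sorted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() == ".csv":
            pairs = _read_csv_pairs(path)
        else:
            pairs = _read_atr_pairs(path)
    except (ValueError, struct.error) as exc:
        raise ValueError(f"unparseable annotation file {path}: {exc}") from exc
    if symbol_filter is not None:
        keep = set(symbol_filter)
        pairs = [(i, s) for i, s in pairs if s in keep]
    p = sorted({i for i, s in pairs if s == "p"})
    t = sorted({i for i, s in pairs if s == "t"})
    r = sorted({i for i, s in pairs if s in BEAT_SYMBOLS})
    return WaveAnnotations(p_peaks=p, t_peaks=t, r_peaks=r, source=source,
                           record_id=path.stem)


def write_annotations(ann: WaveAnnotations, path: str | Path) -> None:
    """Write annotations as MIT format (or CSV when the path ends in .csv).

    P peaks are written with code ``p``, T peaks with ``t`` and R peaks with
    ``N``; ``read_annotations`` inverts the mapping, so read∘write is the
    identity on (index, code) pairs.
    """
    path = Path(path)
    pairs = ann.pairs()
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["record_id", "sample_index", "code"])
            for idx, sym in pairs:
                w.writerow([ann.record_id, idx, sym])
    else:
        _write_atr_pairs(path, pairs)
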