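"""Reading and writing WFDB-format ECG records and beat annotations.

Implements the subset of the PhysioNet WFDB conventions this package needs:
text headers (``.hea``), 16-bit two's-complement signal files (format 16,
``.dat``), and the MIT annotation format (``.atr``).  Also houses the beat
symbol -> AAMI class mapping and the policy that turns the beats inside a
fixed-length window into one segment label.

AAMI groups the MIT-BIH beat vocabulary into five classes:

====== =========================================================
class  member symbols
====== =========================================================
N      N (normal), L/R (bundle branch block), e, j (escape beats)
S      A, a, S, J (supraventricular ectopy)
V      V, E (ventricular ectopy)
F      F (fusion of ventricular and normal)
Q      / (paced), f (paced fusion), Q, U and any unknown beat code
====== =========================================================

Non-beat annotations (rhythm changes '+', signal-quality marks '~', comments
'"', ...) carry no beat class and are dropped before labelling.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BeatAnnotation", "RawRecord", "ClassScheme", "MITBIH_SCHEME",
    "ICENTIA_SCHEME", "NON_BEAT_SYMBOLS", "map_symbol", "label_segment",
    "read_record", "write_record", "read_annotations", "write_annotations",
]

# ---------------------------------------------------------------- annotation
# Standard WFDB annotation code table (code <-> mnemonic symbol).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}

#: Annotation symbols that do not mark a beat (rhythm / quality / fiducial).
NON_BEAT_SYMBOLS = frozenset(
    {"~", "|", "s", "T", "*", "D", '"', "=", "p", "^", "t", "+", "u", "!",
     "[", "]", "@", "x", "(", ")"})

_SKIP = 59  # annotation pseudo-codes
_NUM, _SUB, _CHN, _AUX = 60, 61, 62, 63


@dataclass
class BeatAnnotation:
    sample_index: int
    symbol: str
    aami_class: str | None = None


@dataclass
class RawRecord:
    record_id: str
    samples: np.ndarray          # physical units (mV)
    fs: float
    lead_name: str = "MLII"
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("record has no samples")
        idx = [a.sample_index for a in self.annotations]
        if idx != sorted(idx):
            raise ValueError("annotations must be sorted by sample_index")
        if idx and (idx[0] < 0 or idx[-1] >= self.samples.size):
            raise ValueError("annotation index outside the record")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class ClassScheme:
    labels: tuple[str, ...]
    symbol_map: dict[str, str]
    tie_priority: tuple[str, ...] = ("V", "S", "F", "Q")

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("class labels must be distinct")
        bad = set(self.symbol_map.values()) - set(self.labels)
        if bad:
            raise ValueError(f"symbol_map targets outside labels: {bad}")


_MITBIH_SYMBOLS = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "S": "S", "J": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q", "U": "Q",
}

#: MIT-BIH five-class AAMI scheme (N, S, V, F, Q).
MITBIH_SCHEME = ClassScheme(("N", "S", "V", "F", "Q"), dict(_MITBIH_SYMBOLS))

#: Icentia11k-style four-class scheme (no fusion class; F folds into Q).
ICENTIA_SCHEME = ClassScheme(
    ("N", "S", "V", "Q"),
    {**{k: v for k, v in _MITBIH_SYMBOLS.items() if v != "F"}, "F": "Q"},
    tie_priority=("V", "S", "Q"),
)


def map_symbol(symbol: str, scheme: ClassScheme = MITBIH_SCHEME) -> str | None:
    """Map one annotation symbol to its AAMI class.

    Returns ``None`` for non-beat annotations; unknown beat codes fall back
    to the unclassified class ``"Q"``.  Total and idempotent by construction.
    """
    if symbol in NON_BEAT_SYMBOLS:
        return None
    return scheme.symbol_map.get(symbol, "Q")


def label_segment(beats_in_window, scheme: ClassScheme = MITBIH_SCHEME) -> str | None:
    """Collapse the mapped beat classes inside one window to a segment label.

    Policy: no beats -> ``None`` (exclude the segment); all-normal -> ``"N"``;
    otherwise the most frequent non-N class, ties broken by
    ``scheme.tie_priority`` (most clinically severe first).  Order-invariant.
    """
    labels = [b for b in beats_in_window if b is not None]
    if not labels:
        return None
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    non_n = {k: v for k, v in counts.items() if k != "N"}
    if not non_n:
        return "N"
    best = max(non_n.values())
    tied = [k for k, v in non_n.items() if v == best]
    for cls in scheme.tie_priority:
        if cls in tied:
            return cls
    return sorted(tied)[0]


# ------------------------------------------------------------------- signals

def _header_path(path) -> Path:
    p = Path(path)
    return p if p.suffix == ".hea" else p.with_suffix(".hea")


def write_record(directory, record: RawRecord, gain: float = 200.0,
                 baseline: int = 0, fmt: int = 16) -> Path:
    """Write a record as ``<dir>/<record_id>.hea/.dat`` (+ ``.atr`` if it has
    annotations).  Returns the header path.  Format 16 quantises the signal
    to ``round(x * gain) + baseline`` 16-bit integers, so a round-trip
    reproduces samples to within 0.5/gain.
    """
    if fmt != 16:
        raise ValueError("only format 16 is supported")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rid = record.record_id
    adc = np.round(record.samples * gain).astype(np.int64) + baseline
    if adc.min() < -32768 or adc.max() > 32767:
        raise ValueError("signal exceeds the 16-bit ADC range at this gain")
    adc16 = adc.astype("<i2")
    (directory / f"{rid}.dat").write_bytes(adc16.tobytes())
    checksum = int(adc16.astype(np.int64).sum() % 65536)
    n = record.samples.size
    header = (
        f"{rid} 1 {_fmt_num(record.fs)} {n}\n"
        f"{rid}.dat 16 {_fmt_num(gain)}({baseline})/mV 16 0 "
        f"{int(adc16[0])} {checksum} 0 {record.lead_name}\n"
    )
    (directory / f"{rid}.hea").write_text(header)
    if record.annotations:
        write_annotations(directory / f"{rid}.atr", record.annotations)
    return directory / f"{rid}.hea"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _parse_gain(tok: str) -> tuple[float, int]:
    """Parse a header gain token like ``200``, ``200(0)`` or ``200(0)/mV``."""
    tok = tok.split("/")[0]
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(", 1)
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    if gain == 0:
        gain = 200.0  # WFDB convention: 0 means "unspecified", default 200
    return gain, baseline


def read_record(path, channel: int = 0, annotation_ext: str = "atr") -> RawRecord:
    """Read a WFDB record (header + format-16 signal + optional annotations).

    ``path`` may point at the ``.hea`` file or be the record path without
    extension.  One lead is selected (default channel 0).
    """
    hea = _header_path(path)
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    rid = head[0].split("/")[0]
    n_sig = int(head[1])
    if n_sig < 1:
        raise ValueError(f"record {rid} declares no signals")
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0
    if channel >= n_sig:
        raise ValueError(f"channel {channel} not in record with {n_sig} signals")

    sig_line = lines[1 + channel].split()
    dat_name = sig_line[0]
    fmt = sig_line[1].split("x")[0]
    if fmt != "16":
        raise ValueError(f"unsupported signal format {fmt!r} (only 16)")
    gain, baseline = _parse_gain(sig_line[2]) if len(sig_line) > 2 else (200.0, 0)
    lead = sig_line[-1] if len(sig_line) > 9 else f"ch{channel}"

    dat = hea.parent / dat_name
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    if n_sig > 1:
        raw = raw.reshape(-1, n_sig)[:, channel]
    if n_samples:
        raw = raw[:n_samples]
    samples = (raw.astype(float) - baseline) / gain

    ann_path = hea.with_suffix(f".{annotation_ext}")
    annotations = read_annotations(ann_path) if ann_path.exists() else []
    return RawRecord(rid, samples, fs, lead, annotations)


# --------------------------------------------------------------- annotations

def write_annotations(path, annotations: list[BeatAnnotation]):
    """Write MIT-format annotations (sorted by sample index)."""
    words = bytearray()
    t_prev = 0
    for ann in annotations:
        code = _SYMBOL_TO_CODE.get(ann.symbol)
        if code is None:
            code = _SYMBOL_TO_CODE["Q"]
        delta = ann.sample_index - t_prev
        if 0 <= delta <= 1023:
            words += struct.pack("<H", (code << 10) | delta)
        else:
            words += struct.pack("<H", _SKIP << 10)
            words += struct.pack("<h", delta >> 16)  # arithmetic shift: works for <0
            words += struct.pack("<H", delta & 0xFFFF)
            words += struct.pack("<H", code << 10)
        t_prev = ann.sample_index
    words += struct.pack("<H", 0)  # end of file
    Path(path).write_bytes(bytes(words))


def read_annotations(path) -> list[BeatAnnotation]:
    """Read MIT-format annotations; symbols preserved verbatim."""
    buf = Path(path).read_bytes()
    out: list[BeatAnnotation] = []
    t = 0
    i = 0
    pending_skip = 0
    n = len(buf) // 2
    while i < n:
        (word,) = struct.unpack_from("<H", buf, 2 * i)
        i += 1
        if word == 0:
            break
        code, interval = word >> 10, word & 0x3FF
        if code == _SKIP:
            (hi,) = struct.unpack_from("<h", buf, 2 * i)
            (lo,) = struct.unpack_from("<H", buf, 2 * i + 2)
            i += 2
            pending_skip = (hi << 16) | lo
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            i += (interval + 1) // 2  # skip aux bytes (padded to words)
        else:
            t += interval + pending_skip
            pending_skip = 0
            symbol = _CODE_TO_SYMBOL.get(code, "Q")
            out.append(BeatAnnotation(t, symbol))
    return out
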