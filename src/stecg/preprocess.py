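"""The eight-stage ECG preprocessing pipeline.

Raw single-lead ECG is turned into normalised 10-second segments through:

1. partition into 50-s windows (drop the trailing remainder),
2. zero-phase 30 Hz Butterworth low-pass (order 4, forward-backward),
3. polyphase resampling to 100 Hz,
4. smoothness-priors detrending — the trend is ``(I + λ² D₂ᵀD₂)⁻¹ x`` with
   D₂ the second-difference operator, solved through its banded structure,
5. partition into 10-s segments,
6. Tukey-fence outlier rejection on a per-segment statistic (default
   peak-to-peak amplitude, fences Q1 − k·IQR / Q3 + k·IQR, k = 1.5),
7. Min-Max normalisation to [0, 1],
8. per-segment class labelling from the beat annotations.

All stages are pure functions of their inputs and the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.linalg import solveh_banded

from .io_wfdb import ClassScheme, MITBIH_SCHEME, RawRecord, label_segment, map_symbol

__all__ = [
    "PreprocessConfig", "Segment", "window", "lowpass", "resample",
    "detrend_sp", "iqr_reject", "minmax", "run_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    window_long_s: float = 50.0
    lpf_cutoff_hz: float = 30.0
    lpf_order: int = 4
    fs_target: float = 100.0
    detrend_lambda: float = 500.0
    window_short_s: float = 10.0
    iqr_k: float = 1.5
    iqr_feature: str = "ptp"       # per-segment statistic for outlier fences
    exclude_constant: bool = True  # drop degenerate (flat) segments downstream

    def __post_init__(self):
        if self.window_long_s % self.window_short_s:
            raise ValueError("long window must be a multiple of the short window")
        if self.lpf_cutoff_hz >= self.fs_target / 2:
            raise ValueError("low-pass cutoff must be below the target Nyquist")


@dataclass
class Segment:
    samples: np.ndarray
    fs: float
    record_id: str = ""
    start_time_s: float = 0.0
    label: str | None = None
    degenerate: bool = False


def window(x: np.ndarray, fs: float, length_s: float) -> list[np.ndarray]:
    """Split into consecutive non-overlapping windows of fs*length_s samples;
    a trailing remainder shorter than one window is dropped."""
    x = np.asarray(x)
    n = fs * length_s
    if n <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError("fs * length_s must be a positive integer")
    n = int(round(n))
    k = len(x) // n
    return [x[i * n:(i + 1) * n] for i in range(k)]


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float = 30.0,
            order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass (applied forward and backward, so the
    effective magnitude response is |H|² and the phase is exactly zero)."""
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase rational-ratio downsampling with built-in anti-aliasing."""
    if fs_out > fs_in:
        raise ValueError("upsampling is out of scope (fs_out must be <= fs_in)")
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_in == fs_out:
        return np.asarray(x, dtype=float).copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    return sps.resample_poly(np.asarray(x, dtype=float), ratio.numerator,
                             ratio.denominator)


def detrend_sp(x: np.ndarray, lam: float = 500.0) -> np.ndarray:
    """Smoothness-priors detrending.

    The low-frequency trend is the ridge solution
    ``trend = (I + λ² D₂ᵀD₂)⁻¹ x`` where D₂ is the (N−2)×N second-difference
    operator; the detrended signal is ``x − trend``.  Affine signals lie in
    the null space of D₂ and are removed exactly for every λ.  The system is
    symmetric positive definite and pentadiagonal, so it is solved in O(N)
    with a banded Cholesky solver.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("detrend_sp needs at least 3 samples")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return np.zeros_like(x)
    l2 = lam * lam
    # Diagonals of I + λ² D₂ᵀ D₂ (upper banded storage for solveh_banded).
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.full(n - 2, 1.0)
    ab = np.zeros((3, n))
    ab[0, 2:] = l2 * d2
    ab[1, 1:] = l2 * d1
    ab[2, :] = 1.0 + l2 * main
    trend = solveh_banded(ab, x, lower=False)
    return x - trend


def _feature(samples: np.ndarray, name: str) -> float:
    if name == "ptp":
        return float(np.ptp(samples))
    if name == "std":
        return float(np.std(samples))
    if name == "max_abs":
        return float(np.max(np.abs(samples)))
    raise ValueError(f"unknown IQR feature {name!r}")


def iqr_reject(segments: list, k: float = 1.5, feature: str = "ptp"):
    """Tukey-fence rejection on a per-segment statistic.

    Returns ``(kept, rejected)`` preserving input order.  With fewer than 4
    segments the fences are meaningless and everything is kept.  Percentiles
    use numpy's linear-interpolation convention.
    """
    if len(segments) < 4:
        return list(segments), []
    r = np.array([_feature(s.samples if isinstance(s, Segment) else np.asarray(s),
                           feature) for s in segments])
    q1, q3 = np.percentile(r, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    kept, rejected = [], []
    for s, ri in zip(segments, r):
        (kept if lo <= ri <= hi else rejected).append(s)
    return kept, rejected


def minmax(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale to [0, 1]; a constant segment maps to all zeros with a flag."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def run_pipeline(record: RawRecord, config: PreprocessConfig = PreprocessConfig(),
                 scheme: ClassScheme = MITBIH_SCHEME) -> list[Segment]:
    """Run the full pipeline on one record and label the surviving segments.

    Annotation indices are rescaled into the 100 Hz time base with
    round-half-even; a segment's beats are those whose rescaled index falls
    in its half-open sample interval.  Outlier rejection operates across all
    10-s segments of the record (per-record fences).
    """
    if record.fs < config.fs_target:
        raise ValueError("record sampling rate below the pipeline target rate")
    n_short = int(round(config.fs_target * config.window_short_s))

    # beat annotations in the target time base
    scale = config.fs_target / record.fs
    beats = []
    for ann in record.annotations:
        cls = map_symbol(ann.symbol, scheme)
        if cls is not None:
            beats.append((int(np.round(ann.sample_index * scale)), cls))

    segments: list[Segment] = []
    for w_idx, long_win in enumerate(window(record.samples, record.fs,
                                            config.window_long_s)):
        y = lowpass(long_win, record.fs, config.lpf_cutoff_hz, config.lpf_order)
        y = resample(y, record.fs, config.fs_target)
        y = detrend_sp(y, config.detrend_lambda)
        for s_idx, short in enumerate(window(y, config.fs_target,
                                             config.window_short_s)):
            start_s = (w_idx * config.window_long_s
                       + s_idx * config.window_short_s)
            segments.append(Segment(short, config.fs_target, record.record_id,
                                    start_s))

    kept, _ = iqr_reject(segments, config.iqr_k, config.iqr_feature)

    out: list[Segment] = []
    for seg in kept:
        norm, degenerate = minmax(seg.samples)
        g0 = int(round(seg.start_time_s * config.fs_target))
        in_win = [cls for idx, cls in beats if g0 <= idx < g0 + n_short]
        out.append(replace(seg, samples=norm, degenerate=degenerate,
                           label=label_segment(in_win, scheme)))
    return out
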