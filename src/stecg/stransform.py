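"""Discrete Stockwell transform (S-transform) of a 1-D signal.

The S-transform localises each frequency with a Gaussian window whose width
scales as 1/f, combining the absolutely-referenced phase of the Fourier
transform with wavelet-like multiresolution.  The discrete transform is
computed per frequency "voice" in the spectral domain:

    S[n, k] = IDFT_m { X[(m + n) mod N] · exp(−2π² m̃² / n²) }[k]

where ``X`` is the DFT of the signal, ``n`` the frequency bin, ``k`` the time
index, and ``m̃`` the symmetric alias of ``m`` (m for m ≤ N/2, m − N above).
The Gaussian factor equals 1 at m = 0, which yields the time-marginal
identity  Σ_k S[n, k] = X[n]  used as an inversion-grade check.

The zero-frequency voice has no finite-width window; by convention the 0 Hz
row is the signal mean replicated across time.  For ECG work the matrix is
band-limited (default 0–15 Hz) since diagnostic beat morphology lives below
15 Hz and muscle/ESU artifacts above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["STConfig", "STMatrix", "stockwell", "brute_stockwell",
           "to_channels", "recombine"]


@dataclass(frozen=True)
class STConfig:
    fmin_hz: float = 0.0
    fmax_hz: float = 15.0
    zero_freq_rule: str = "mean"   # value convention for the 0 Hz row

    def validate(self, fs: float):
        if not (0 <= self.fmin_hz < self.fmax_hz <= fs / 2):
            raise ValueError("frequency band must satisfy 0 <= fmin < fmax <= fs/2")


@dataclass
class STMatrix:
    """Complex time-frequency matrix: rows are frequency voices (inclusive
    band edges), columns are the N time samples."""
    values: np.ndarray      # complex, [n_rows, N]
    freqs_hz: np.ndarray    # [n_rows]
    fs: float

    @property
    def shape(self):
        return self.values.shape


def _band_bins(N: int, fs: float, config: STConfig) -> np.ndarray:
    nmin = math.ceil(config.fmin_hz * N / fs - 1e-12)
    nmax = math.floor(config.fmax_hz * N / fs + 1e-12)
    return np.arange(nmin, nmax + 1)


def _symmetric_alias(N: int) -> np.ndarray:
    m = np.arange(N)
    return np.where(m <= N / 2, m, m - N).astype(float)


def stockwell(x: np.ndarray, fs: float, config: STConfig = STConfig()) -> STMatrix:
    """FFT-based S-transform, band-limited per ``config``.

    Complexity O(R · N log N) for R in-band voices.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 2:
        raise ValueError("signal must have at least 2 samples")
    config.validate(fs)
    bins = _band_bins(N, fs, config)
    X = np.fft.fft(x)
    mt = _symmetric_alias(N)
    m = np.arange(N)

    S = np.empty((bins.size, N), dtype=complex)
    nz = bins > 0
    if nz.any():
        n_nz = bins[nz].astype(float)
        shifted = X[(m[None, :] + bins[nz, None]) % N]           # [R', N]
        gauss = np.exp(-2.0 * np.pi ** 2 * mt[None, :] ** 2 / n_nz[:, None] ** 2)
        S[nz] = np.fft.ifft(shifted * gauss, axis=1)
    if (~nz).any():  # the n = 0 voice
        if config.zero_freq_rule == "mean":
            S[~nz] = np.mean(x)
        elif config.zero_freq_rule == "zero":
            S[~nz] = 0.0
        else:
            raise ValueError(f"unknown zero_freq_rule {config.zero_freq_rule!r}")
    return STMatrix(S, bins * fs / N, fs)


def brute_stockwell(x: np.ndarray, fs: float, config: STConfig = STConfig(),
                    max_n: int = 512) -> STMatrix:
    """Reference S-transform by direct summation (explicit DFT matrices, no
    FFT anywhere).  Quadratic in N; guarded to small inputs — this exists as
    an independent equivalence oracle for :func:`stockwell`."""
    x = np.asarray(x, dtype=float)
    N = x.size
    if N > max_n:
        raise ValueError(f"brute_stockwell is limited to N <= {max_n}")
    if N < 2:
        raise ValueError("signal must have at least 2 samples")
    config.validate(fs)
    bins = _band_bins(N, fs, config)
    j = np.arange(N)
    # forward DFT by explicit summation
    F = np.exp(-2j * np.pi * np.outer(j, j) / N)
    X = F @ x.astype(complex)
    mt = _symmetric_alias(N)
    Finv = np.exp(2j * np.pi * np.outer(j, j) / N)  # rows: m, cols: k

    S = np.empty((bins.size, N), dtype=complex)
    for r, n in enumerate(bins):
        if n == 0:
            if config.zero_freq_rule == "mean":
                S[r] = np.mean(x)
            else:
                S[r] = 0.0
            continue
        voice = np.empty(N, dtype=complex)
        coeff = X[(j + n) % N] * np.exp(-2.0 * np.pi ** 2 * mt ** 2 / float(n) ** 2)
        for k in range(N):
            voice[k] = np.sum(coeff * Finv[:, k]) / N
        S[r] = voice
    return STMatrix(S, bins * fs / N, fs)


def to_channels(S: STMatrix) -> np.ndarray:
    """Split into a real 2-channel tensor [2, rows, cols]: channel 0 the real
    part, channel 1 the imaginary part.  Lossless."""
    return np.stack([S.values.real, S.values.imag])


def recombine(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_channels`."""
    if channels.shape[0] != 2:
        raise ValueError("expected a [2, rows, cols] tensor")
    return channels[0] + 1j * channels[1]


def save_spectrogram_png(S: STMatrix, path) -> None:
    """Write a magnitude spectrogram image for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    t = np.arange(S.values.shape[1]) / S.fs
    im = ax.pcolormesh(t, S.freqs_hz, np.abs(S.values), shading="auto",
                       cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(im, ax=ax, label="|S|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
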