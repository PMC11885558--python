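"""Synthetic single-lead ECG with per-beat class annotations.

Beats are sums of Gaussian bumps approximating the P, Q, R, S and T waves;
the five AAMI classes get distinct, learnable morphologies:

* **N** — full PQRST complex;
* **S** (supraventricular ectopy) — normal-width QRS but no P wave, and the
  beat arrives prematurely (shortened preceding RR interval);
* **V** (ventricular ectopy) — no P wave, QRS widened by >= 2x with enlarged
  amplitude and an inverted T, also premature with a compensatory pause;
* **F** (fusion) — the pointwise average of the N and V templates;
* **Q** (paced/unknown) — a narrow low-amplitude pacer-spike-like deflection.

Records add configurable baseline wander (~0.33 Hz), powerline interference
(50/60 Hz) and white noise, and are fully determined by their seed.  The
generator writes MIT-BIH annotation symbols ('N', 'A', 'V', 'F', '/') so the
WFDB I/O layer is exercised unchanged.  It emulates beat-class morphology and
stationary noise only — not rhythm disorders, ectopy coupling patterns, or
electrode artifacts of real Holter data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_wfdb import BeatAnnotation, ClassScheme, MITBIH_SCHEME, RawRecord

__all__ = ["BeatTemplate", "SynthConfig", "beat_template", "synth_record",
           "make_labeled_dataset", "CLASS_SYMBOLS"]

#: annotation symbol written for each synthetic beat class
CLASS_SYMBOLS = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "/"}

# Gaussian components (amplitude mV, centre offset s, width s) per wave.
# Widths give a ~90 ms normal QRS and keep >= 95 % of the beat's spectral
# energy below 15 Hz, as in adult surface ECG.
_N_WAVES = (
    (0.12, -0.220, 0.028),  # P
    (-0.12, -0.045, 0.016),  # Q
    (1.00, 0.000, 0.022),   # R
    (-0.22, 0.045, 0.016),  # S
    (0.30, 0.300, 0.070),   # T
)
_V_WAVES = (
    (-0.15, -0.100, 0.040),  # widened, bizarre QRS: no P wave
    (1.40, 0.000, 0.050),
    (-0.45, 0.120, 0.045),
    (-0.35, 0.360, 0.090),   # discordant (inverted) T
)
_Q_WAVES = (
    (0.45, 0.000, 0.006),   # pacer-like narrow spike
    (0.12, 0.160, 0.070),   # small evoked wave
)


@dataclass(frozen=True)
class BeatTemplate:
    label: str
    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if any(w <= 0 for _, _, w in self.components):
            raise ValueError("component widths must be positive")


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 360.0
    duration_s: float = 60.0
    mean_hr_bpm: float = 70.0
    class_mix: dict = field(default_factory=lambda: {
        "N": 0.90, "S": 0.04, "V": 0.04, "F": 0.01, "Q": 0.01})
    baseline_wander: tuple[float, float] = (0.1, 0.33)   # (mV, Hz)
    powerline: tuple[float, float] = (0.05, 60.0)        # (mV, Hz)
    white_noise_sd: float = 0.02                         # mV
    rr_jitter: float = 0.02        # s.d. of multiplicative RR jitter
    premature_factor: float = 0.65  # RR shortening before S/V beats
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        if (self.baseline_wander[0] < 0 or self.powerline[0] < 0
                or self.white_noise_sd < 0):
            raise ValueError("noise amplitudes must be non-negative")


_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate("N", _N_WAVES),
    "S": BeatTemplate("S", tuple(_N_WAVES[1:])),   # P wave absent
    "V": BeatTemplate("V", _V_WAVES),
    "Q": BeatTemplate("Q", _Q_WAVES),
}

#: half-width of the sampled template support, seconds
_SUPPORT_S = 0.45


def _sample(components, fs: float) -> np.ndarray:
    n = int(round(_SUPPORT_S * fs))
    t = np.arange(-n, n + 1) / fs
    y = np.zeros_like(t)
    for a, c, w in components:
        y += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return y


def beat_template(cls: str, fs: float) -> np.ndarray:
    """Sampled waveform of one beat class, centred on the R peak (or the
    pacer spike).  Deterministic per (class, fs); F is the pointwise average
    of the N and V templates."""
    if cls == "F":
        return 0.5 * (_sample(_N_WAVES, fs) + _sample(_V_WAVES, fs))
    if cls not in _TEMPLATES:
        raise ValueError(f"unknown beat class {cls!r}")
    return _sample(_TEMPLATES[cls].components, fs)


def synth_record(config: SynthConfig = SynthConfig(),
                 record_id: str = "synth") -> RawRecord:
    """Generate one annotated record.

    Beats are laid out at RR intervals around 60/mean_hr with mild
    multiplicative jitter; S and V beats shorten the preceding RR (premature)
    and stretch the following one (compensatory pause), preserving the mean
    rate.  Each beat is annotated at its R-peak sample.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    if n < 2 * int(_SUPPORT_S * fs) + 2:
        raise ValueError("duration too short for even a single beat")
    rng = np.random.default_rng(config.seed)

    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    templates = {c: beat_template(c, fs) for c in classes}
    half = (len(next(iter(templates.values()))) - 1) // 2

    rr_mean = 60.0 / config.mean_hr_bpm
    signal = np.zeros(n)
    annotations: list[BeatAnnotation] = []
    t = _SUPPORT_S + 0.05                      # first R peak
    pending_pause = 0.0
    limit = config.duration_s - _SUPPORT_S - 0.05
    while t <= limit:
        cls = classes[int(rng.choice(len(classes), p=probs))]
        rr = rr_mean * (1.0 + config.rr_jitter * rng.standard_normal())
        if cls in ("S", "V"):
            # premature: shortened preceding RR.  A compensatory pause is
            # scheduled but only granted to a following non-premature beat,
            # so sustained ectopic runs stay fast (as in real tachycardia)
            # while isolated ectopics preserve the mean rate.
            rr *= config.premature_factor
            next_pause = rr_mean * (1.0 - config.premature_factor)
        else:
            rr += pending_pause
            next_pause = 0.0
        pending_pause = next_pause
        rr = max(0.3, rr)
        # rr computed for *this* beat relative to the previous one
        if annotations:
            t = annotations[-1].sample_index / fs + rr
            if t > limit:
                break
        center = int(round(t * fs))
        tpl = templates[cls]
        lo, hi = center - half, center + half + 1
        signal[max(0, lo):min(n, hi)] += tpl[max(0, -lo):len(tpl) - max(0, hi - n)]
        annotations.append(BeatAnnotation(center, CLASS_SYMBOLS[cls]))

    tt = np.arange(n) / fs
    bw_a, bw_f = config.baseline_wander
    pl_a, pl_f = config.powerline
    if bw_a:
        signal += bw_a * np.sin(2 * np.pi * bw_f * tt
                                + rng.uniform(0, 2 * np.pi))
    if pl_a:
        signal += pl_a * np.sin(2 * np.pi * pl_f * tt
                                + rng.uniform(0, 2 * np.pi))
    if config.white_noise_sd:
        signal += config.white_noise_sd * rng.standard_normal(n)

    return RawRecord(record_id, signal, fs, "MLII", annotations)


def make_labeled_dataset(n_per_class: int, scheme: ClassScheme = MITBIH_SCHEME,
                         config: SynthConfig = SynthConfig(), seed: int = 0,
                         mode: str = "records"):
    """Build a class-balanced labelled dataset.

    ``mode="records"`` returns ``(records, labels)`` with single-class
    records (every beat of the record belongs to the target class), so the
    full pipeline — WFDB round-trip included — can be exercised end to end.
    ``mode="segments"`` runs the preprocessing pipeline and returns exactly
    ``n_per_class`` labelled, normalised 10-s segments per class (extra
    records are generated to compensate for outlier rejection).
    Deterministic per seed.
    """
    from dataclasses import replace as _replace

    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    if mode == "records":
        records, labels = [], []
        for cls in scheme.labels:
            for i in range(n_per_class):
                cfg = _replace(config, class_mix={cls: 1.0},
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
                records.append(synth_record(cfg, record_id=f"{cls}{i:03d}"))
                labels.append(cls)
        return records, labels
    if mode == "segments":
        from .preprocess import PreprocessConfig, run_pipeline

        pp = PreprocessConfig()
        segments, labels = [], []
        for cls in scheme.labels:
            got = 0
            i = 0
            while got < n_per_class:
                cfg = _replace(config, class_mix={cls: 1.0},
                               seed=int(rng.integers(0, 2 ** 31 - 1)))
                rec = synth_record(cfg, record_id=f"{cls}{i:03d}")
                i += 1
                for seg in run_pipeline(rec, pp, scheme):
                    if seg.label == cls and not seg.degenerate:
                        segments.append(seg)
                        labels.append(cls)
                        got += 1
                        if got == n_per_class:
                            break
        return segments, labels
    raise ValueError(f"unknown mode {mode!r}")
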