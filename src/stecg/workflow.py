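"""End-to-end workflows: records -> preprocessing -> S-transform tensors ->
training -> evaluation.

These functions wire the library modules together the way the command-line
interface and the reproducibility script use them.  The desk-scale study
trains a reduced-width instance of the hybrid architecture (see
:func:`stecg.model.desk_config`) on a synthetic four-class dataset; sizes are
chosen so a full run completes on a single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eval_metrics import MetricReport, report
from .io_wfdb import ClassScheme, ICENTIA_SCHEME
from .model import ModelConfig, build_model, desk_config
from .preprocess import PreprocessConfig, run_pipeline
from .stransform import STConfig, stockwell, to_channels
from .synthetic_ecg import SynthConfig, make_labeled_dataset
from .train import (History, TrainConfig, fit, predict, smote_oversample,
                    stratified_split)

__all__ = ["decimate_tf", "segments_to_tensors", "records_to_dataset",
           "build_desk_dataset", "DeskStudyResult", "run_desk_study"]


def build_desk_dataset(seed: int, n_records_per_class: int = 50,
                       scheme: ClassScheme = ICENTIA_SCHEME,
                       synth_config=None, decimate: tuple[int, int] = (2, 4)):
    """The desk study's dataset, computed separately so repeated runs with
    the same seed can share it.  Uses the same seed stream as
    :func:`run_desk_study`, so passing the result back via ``dataset=``
    reproduces the single-call run exactly."""
    from .synthetic_ecg import SynthConfig as _SC

    rng = np.random.default_rng(seed)
    synth_config = synth_config or _SC(duration_s=50.0)
    records, _ = make_labeled_dataset(
        n_records_per_class, scheme, synth_config,
        seed=int(rng.integers(0, 2 ** 31 - 1)), mode="records")
    return records_to_dataset(records, scheme, decimate=decimate)


def decimate_tf(t: np.ndarray, step: tuple[int, int]) -> np.ndarray:
    """Subsample a [..., H, W] time-frequency tensor by strided slicing.

    Used to shrink tensors for CPU-scale training without touching the model
    architecture.  Strided decimation (not averaging) on purpose: the real
    and imaginary channels oscillate at each voice's own frequency, so block
    averaging along time low-passes the phase carriers and destroys exactly
    the high-band structure that separates subtle classes, whereas the
    S-transform's time axis is heavily oversampled and strided columns keep
    it intact."""
    sh, sw = step
    return t[..., ::sh, ::sw]


def segments_to_tensors(segments, st_config: STConfig = STConfig(),
                        decimate: tuple[int, int] = (1, 1),
                        dtype=np.float32) -> np.ndarray:
    """S-transform each normalised segment into a [2, rows, N] tensor
    (optionally decimated to a coarser time-frequency grid)."""
    out = []
    for seg in segments:
        S = stockwell(seg.samples, seg.fs, st_config)
        out.append(decimate_tf(to_channels(S), decimate).astype(dtype))
    return np.stack(out)


def records_to_dataset(records, scheme: ClassScheme,
                       pp_config: PreprocessConfig = PreprocessConfig(),
                       st_config: STConfig = STConfig(),
                       decimate: tuple[int, int] = (1, 1)):
    """Full front end: preprocess every record, drop unlabelled/degenerate
    segments, S-transform the survivors.  Returns (X, y, class_labels)."""
    segments = []
    for rec in records:
        for seg in run_pipeline(rec, pp_config, scheme):
            if seg.label is not None and not seg.degenerate:
                segments.append(seg)
    if not segments:
        raise ValueError("no labelled segments produced")
    X = segments_to_tensors(segments, st_config, decimate)
    label_to_idx = {lab: i for i, lab in enumerate(scheme.labels)}
    y = np.array([label_to_idx[s.label] for s in segments])
    return X, y, scheme.labels


@dataclass
class DeskStudyResult:
    history: History
    test_report: MetricReport
    y_test: np.ndarray
    y_pred: np.ndarray
    n_segments: int
    class_labels: tuple[str, ...]
    model: object = field(repr=False, default=None)


def run_desk_study(seed: int = 0, n_records_per_class: int = 50,
                   scheme: ClassScheme = ICENTIA_SCHEME,
                   synth_config: SynthConfig | None = None,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   test_frac: float = 0.2, val_frac: float = 0.2,
                   decimate: tuple[int, int] = (2, 4),
                   keep_model: bool = False,
                   dataset: tuple | None = None) -> DeskStudyResult:
    """Simulate records, run the full pipeline, train, and evaluate.

    The defaults define the package's desk-scale study: 50 single-class
    50-second records per class of the four-class scheme, time-frequency
    tensors decimated 2x in frequency and 4x in time, the reduced-width
    hybrid model, batch 64, RAdam, early stopping with patience 15.
    All randomness derives from ``seed``.  ``dataset`` may carry a
    pre-computed ``(X, y, labels)`` triple (it must come from the same seed
    for the run to be reproducible).
    """
    rng = np.random.default_rng(seed)
    if dataset is not None:
        X, y, labels = dataset
        rng.integers(0, 2 ** 31 - 1)  # keep the seed stream aligned
    else:
        synth_config = synth_config or SynthConfig(duration_s=50.0)
        records, _ = make_labeled_dataset(
            n_records_per_class, scheme, synth_config,
            seed=int(rng.integers(0, 2 ** 31 - 1)), mode="records")
        X, y, labels = records_to_dataset(records, scheme, decimate=decimate)

    idx_test, idx_rest = stratified_split(y, test_frac,
                                          seed=int(rng.integers(0, 2 ** 31 - 1)))
    y_rest = y[idx_rest]
    idx_val_rel, idx_tr_rel = stratified_split(
        y_rest, val_frac, seed=int(rng.integers(0, 2 ** 31 - 1)))
    idx_val, idx_tr = idx_rest[idx_val_rel], idx_rest[idx_tr_rel]

    # draw seeds unconditionally so overriding one config never shifts the
    # seed stream of the others
    fit_seed = int(rng.integers(0, 2 ** 31 - 1))
    # desk-scale optimizer: lr rescaled for a ~10^3-segment corpus (the
    # full-scale default of 3e-4 assumes ~10^6 segments; see docs/methods.md)
    train_config = train_config or TrainConfig(lr=1e-3, max_epochs=30,
                                               patience=15, seed=fit_seed)

    X_tr, y_tr = X[idx_tr], y[idx_tr]
    if train_config.smote_enabled:
        counts = np.bincount(y_tr, minlength=len(labels))
        if counts.min() != counts.max():
            flat = X_tr.reshape(len(y_tr), -1)
            flat, y_tr = smote_oversample(flat, y_tr, train_config.smote_k,
                                          seed=train_config.seed)
            X_tr = flat.reshape((-1,) + X.shape[1:])

    model_config = model_config or desk_config(n_classes=len(labels),
                                               input_shape=X.shape[2:])
    model = build_model(model_config, seed=int(rng.integers(0, 2 ** 31 - 1)))

    _, history = fit(model, (X_tr, y_tr), (X[idx_val], y[idx_val]),
                     train_config)
    y_pred = predict(model, X[idx_test], train_config.batch_size)
    rep = report(y[idx_test], y_pred, len(labels), labels)
    return DeskStudyResult(history, rep, y[idx_test], y_pred, len(y), labels,
                           model=model if keep_model else None)
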