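"""The desk-scale end-to-end study: synthetic records -> full pipeline ->
hybrid-model training -> held-out evaluation.

Uses a reduced-width instance of the architecture and pooled time-frequency
tensors so the whole study runs on one CPU; see docs/methods.md for the
scaling choices.  Expect a run time of a few minutes.
"""

from stecg.eval_metrics import per_class_metrics
from stecg.workflow import run_desk_study

result = run_desk_study(seed=7, n_records_per_class=25)

h = result.history
print(f"{result.n_segments} segments, classes {result.class_labels}")
print(f"stopped: {h.stop_reason} (best epoch {h.best_epoch})")
print(f"validation accuracy per epoch: "
      f"{[round(a, 2) for a in h.val_acc]}")

rep = result.test_report
se, ppv, f1 = per_class_metrics(rep.confusion)
print(f"held-out accuracy {rep.overall_acc:.3f}, kappa {rep.kappa:.3f}, "
      f"MCC {rep.mcc:.3f}")
for i, lab in enumerate(result.class_labels):
    print(f"  {lab}: Se={se[i]:.2f} PPV={ppv[i]:.2f} F1={f1[i]:.2f}")
print("confusion matrix (rows true, cols predicted):")
print(rep.confusion.counts)
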