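"""Derive all report metrics from a printed five-class confusion matrix.

Useful for auditing published results: given only the confusion matrix of
a five-class liver-lesion classifier, recompute the per-class sensitivity,
the column-wise "specificity" convention, one-vs-other accuracies and the
benign/malignant split.
"""

import numpy as np

import liverlesion as ll

counts = np.array(
    [
        [32, 0, 2, 4, 2],
        [0, 27, 2, 0, 0],
        [3, 2, 47, 0, 4],
        [3, 0, 0, 22, 5],
        [3, 0, 6, 13, 36],
    ]
)
cm = ll.ConfusionMatrix(counts)
metrics = ll.class_metrics(cm).rounded()
bm = ll.benign_malignant_metrics(cm).rounded()

print(f"{cm.total} lesions; overall accuracy {metrics.overall_accuracy:.2f}\n")
print(f"{'class':>12} {'sens':>6} {'spec*':>6} {'spec(TN)':>8} {'1-vs-other':>10}")
for cls in ll.CLASS_ORDER:
    print(
        f"{cls:>12} {metrics.sensitivity[cls]:>6.2f} "
        f"{metrics.specificity_as_printed[cls]:>6.2f} "
        f"{metrics.specificity_tn[cls]:>8.2f} "
        f"{metrics.one_vs_other_accuracy[cls]:>10.2f}"
    )
print(
    "\n* column-wise convention (diagonal / predicted-column total), i.e. the\n"
    "  positive predictive value; the TN-based textbook specificity is also shown."
)
print(
    f"\nbenign/malignant split: sensitivity {bm.sensitivity['benign']:.2f}/"
    f"{bm.sensitivity['malignant']:.2f}, specificity* {bm.specificity_as_printed['benign']:.2f}/"
    f"{bm.specificity_as_printed['malignant']:.2f}, accuracy {bm.overall_accuracy:.2f}"
)
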