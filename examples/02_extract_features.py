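"""Extract the full per-lesion feature table from a phantom cohort.

Per lesion the pipeline computes 164 image-derived features (kinetic curve
descriptors, gray-level histogram statistics, GLCM Haralick texture) plus
3 risk-factor flags and the lesion area.
"""

import liverlesion as ll

records = ll.generate_cohort(ll.PhantomConfig(n_patients=5, seed=42))
table = ll.extract_cohort(records)

n_features = table.shape[1] - 3  # minus patient_id, lesion_id, label
print(f"feature table: {table.shape[0]} lesions x {n_features} features")

cols = [
    "label",
    "curve.tic.max_enhancement",
    "curve.cec.washout_rate",
    "hist.t2.mean",
    "hist.ring_enhancement.mean",
    "area_cm2",
]
print(table[cols].round(3).to_string(index=False))
print(
    "\ncysts show ~0 enhancement and the brightest T2; HCC has the largest\n"
    "washout rate; fill-in hemangiomas score below 1 on the ring-enhancement\n"
    "histogram because their strongest portal-phase transition sits inside\n"
    "the lesion rather than at its boundary."
)
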