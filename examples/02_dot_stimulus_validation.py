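"""Validate kernel recovery against the white dot ensemble.

For model cells with known difference-of-Gaussians kernels, compares the
STA computed from structured half-plane labels with the STA from the
exhaustive single-cell +/-1 dot set (a white ensemble on which recovery
is analytically exact for rectified-linear cells).
"""

import fgfield as fg

labels = fg.gen_curved_labels(n=105, grid_size=25, curvature_sd=1.5, seed=0)
truths = fg.default_truth_kernels(n_kernels=10, grid_size=25, seed=0)
report = fg.run_validation(truths, labels, seed=0)

print(report.round(3).to_string(index=False))
print()
print(f"mean cosine(truth, STA_dot)   : {report['cos_truth_dot'].mean():.4f}")
print(f"mean cosine(STA_label, STA_dot): {report['cos_label_dot'].mean():.4f}")
print()
print("Dot-derived estimates match the true kernels exactly (cosine 1.0);")
print("label-derived estimates are blurred by the labels' spatial")
print("correlation, so their agreement with the dot estimates quantifies")
print("how far the structured ensemble can be treated as pseudo-white.")
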