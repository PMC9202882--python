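"""Estimate the kernel by recursive least squares and compare with the STA.

The adaptive filter makes no whiteness assumption about the label
ensemble, so agreement between the two estimators supports the
veridicality of both.  Uses the standard configuration (forgetting
beta = 0.99, initial inverse-correlation 1e-5, periodic
re-regularization every 100 updates, 4200 input pairs).
"""

import numpy as np

import fgfield as fg
from fgfield.af import AFConfig
from fgfield.crf_estimation import CRF

labels = fg.gen_halfplane_labels(n_orientations=105, grid_size=25)
crf = CRF(center=(12.0, 8.0), sd_major=3.0, sd_minor=3.0, orientation=0.0, amplitude=20.0)
ideal = fg.ideal_rffg(labels, crf, "figure")
k = ideal.grid / np.linalg.norm(ideal.grid)

neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=k, gain=30.0, noise="poisson")
spikes = fg.simulate_responses(neuron, labels, n_trials=10, seed=6)

config = AFConfig(beta=0.99, delta_inv=1e-5, Q=100, n_pairs_target=4200, seed=1)
kernel_af = fg.estimate_af(labels, spikes, config)
kernel_sta = fg.compute_sta(labels, spikes)

print(f"cosine(AF, STA)        : {fg.cosine_similarity(kernel_af, kernel_sta):.3f}")
print(f"cosine(AF, true kernel) : {fg.cosine_similarity(kernel_af, k):.3f}")
print()
print("Both estimators recover the same spatial structure; high agreement")
print("between the assumption-free filter and the bias-compensated average")
print("indicates the estimated subregions are not an artifact of either.")
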