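"""Expose a nonlinear (energy) cell's kernel with spike-triggered covariance.

An energy cell responds to |<k, label>|: its drive has zero mean on a
swap-closed ensemble, so the spike-triggered average is flat and
non-significant — but the kernel reappears as the top eigenvector of the
spike-weighted covariance difference, flagged by the randomized
eigenvalue-difference rule.
"""

import numpy as np

import fgfield as fg
from fgfield.crf_estimation import CRF

labels = fg.gen_curved_labels(n=105, grid_size=25, curvature_sd=1.5, seed=5)
crf = CRF(center=(12.0, 8.0), sd_major=3.0, sd_minor=3.0, orientation=0.0, amplitude=20.0)
ideal = fg.ideal_rffg(labels, crf, "figure")
k = ideal.grid / np.linalg.norm(ideal.grid)

neuron = fg.VirtualNeuron(kind="energy", kernel=k, gain=30.0, noise="exact")
spikes = fg.simulate_responses(neuron, labels, n_trials=1, seed=0)

sta = fg.compute_sta(labels, spikes)
p = fg.permutation_test(labels, spikes, n_perm=300, seed=0)
weights = fg.normalize_spikes(spikes, order=labels.ids)
stc = fg.compute_stc(labels, weights, sta)
stc = fg.significant_stcs(stc, labels, spikes, n_rand=300, seed=1)

top = stc.kernel("1+")
print(f"STA magnitude             : {sta.magnitude:.6f}")
print(f"STA permutation p         : {p:.3f}")
print(f"significant STC kernels   : {int(stc.significant.sum())}")
print(f"top eigenvalue (rank 1+)  : {top.eigenvalue:.3f}")
print(f"|cosine(1+ kernel, truth)|: {abs(fg.cosine_similarity(top, k)):.3f}")
print()
print("The mean-based estimator sees nothing (zero magnitude, p = 1) while")
print("the covariance analysis recovers the hidden kernel with |cosine| near 1.")
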