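"""Fit the rectified STA and STA+STC response models and test linearity.

For a cell that is linear up to rectification, the covariance kernels add
nothing (the neural correlation of the two models agrees); the binned
Bayesian diagnostic P(stimulus|spike)/P(stimulus) rises linearly with the
projection rank.
"""

import numpy as np

import fgfield as fg
from fgfield.crf_estimation import CRF

labels = fg.gen_curved_labels(n=52, grid_size=25, curvature_sd=1.5, seed=8)
crf = CRF(center=(12.0, 8.0), sd_major=3.0, sd_minor=3.0, orientation=0.0, amplitude=20.0)
base = fg.ideal_rffg(labels, crf, "figure")
k = base.grid / np.linalg.norm(base.grid)

neuron = fg.VirtualNeuron(kind="rectified_linear", kernel=k, gain=2.0, noise="poisson")
spikes = fg.simulate_responses(neuron, labels, n_trials=10, seed=20)

sta = fg.compute_sta(labels, spikes)
weights = fg.normalize_spikes(spikes, order=labels.ids)
stc = fg.compute_stc(labels, weights, sta)
fg.significant_stcs(stc, labels, spikes, n_rand=100, seed=30)

fit_sta = fg.fit_sta_model(sta, labels, spikes)
fit_both = fg.fit_sta_stc_model(sta, stc, labels, spikes)
curve = fg.linearity_diagnostic(sta, labels, spikes)

print(f"STA model     : w = {fit_sta.w_sta:.3f}, RMSE = {fit_sta.rmse:.3f}, r = {fit_sta.pearson_r:.3f}")
print(f"STA+STC model : RMSE = {fit_both.rmse:.3f}, r = {fit_both.pearson_r:.3f} "
      f"({fit_both.n_stc} covariance kernels)")
print(f"delta r       : {fit_both.pearson_r - fit_sta.pearson_r:+.4f}")
print(f"linearity R^2 : {curve.r_squared:.3f}  (binned rate vs projection rank)")
print()
print("delta r near zero says the covariance kernels add no predictive power")
print("for this cell. The diagnostic curve is linear over the suprathreshold")
print("bins and flat below threshold, so its overall linear R^2 reflects the")
print("half-wave rectification, not hidden nonlinear structure.")
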