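"""Bias-compensated spike-triggered averaging of figure-ground labels.

The estimator is the spike-count-weighted mean FG label with the
ensemble-mean label subtracted:

    RF-FG = sum_i label_i * spike_i / sum_i spike_i  -  mean_i label_i

The subtraction cancels the bias a structured (non-white) label ensemble
would otherwise imprint on the kernel: for a neuron whose responses do
not depend on figure-ground organization the two terms coincide and the
kernel is exactly zero.  Kernel values lie in [-1, +1]; positive cells
prefer figure, negative cells prefer ground.

Significance is assessed by permuting the stimulus -> spike-count
assignment and comparing kernel magnitudes (squared sum of elements);
convergence with ensemble size is summarized by a saturating-curve fit
whose value at the full set size, relative to the asymptote, gates
kernel effectiveness (ratio >= 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .stimulus_labels import RFFG, SpikeTable, StimulusSet

__all__ = [
    "compute_sta",
    "sta_magnitude",
    "permutation_test",
    "permuted_magnitudes",
    "convergence_curve",
    "fit_convergence",
    "ConvergenceFit",
    "ideal_rffg",
    "ideal_spike_table",
]


def _sta_grid(grids: np.ndarray, totals: np.ndarray) -> np.ndarray:
    s = totals.sum()
    if s <= 0:
        raise ValueError("total spike count is zero: STA undefined")
    weighted = np.tensordot(totals, grids, axes=(0, 0)) / s
    return weighted - grids.mean(axis=0)


def compute_sta(labels: StimulusSet, spikes: SpikeTable) -> RFFG:
    """The bias-compensated spike-triggered average kernel.

    Per-stimulus spike counts are summed over trials (the estimator is
    invariant to the positive scale of the counts, so summing and
    averaging over trials are equivalent).
    """
    totals = spikes.totals(order=labels.ids)
    if np.isnan(totals).any():
        missing = [s for s, t in zip(labels.ids, totals) if np.isnan(t)]
        raise ValueError(f"spike table has no rows for stimuli {missing[:5]}")
    grid = _sta_grid(labels.grids(), totals)
    return RFFG(grid=grid, estimator="STA")


def sta_magnitude(labels: StimulusSet, spikes: SpikeTable) -> float:
    """Magnitude (squared element sum) of the STA kernel."""
    return compute_sta(labels, spikes).magnitude


def permuted_magnitudes(
    labels: StimulusSet, totals: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    """Kernel magnitudes after shuffling the stimulus -> count assignment.

    Vectorized: all permutations are applied to the flattened label matrix
    in one pass.
    """
    rng = np.random.default_rng(seed)
    N = len(totals)
    X = labels.grids().reshape(N, -1)  # N x G^2
    mean = X.mean(axis=0)
    perms = np.stack([rng.permutation(totals) for _ in range(n_perm)])  # P x N
    s = perms.sum(axis=1)
    if (s <= 0).any():
        raise ValueError("permuted totals sum to zero")
    K = perms @ X / s[:, None] - mean  # P x G^2
    return np.sum(K * K, axis=1)


def permutation_test(
    labels: StimulusSet,
    spikes: SpikeTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the STA magnitude.

    p = (1 + #{permuted magnitude >= observed}) / (n_perm + 1); the
    add-one estimator never returns 0.  With degenerate (all-equal)
    counts every permutation reproduces the observed kernel and p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    totals = spikes.totals(order=labels.ids)
    obs = compute_sta(labels, spikes).magnitude
    if np.ptp(totals) == 0:
        return 1.0
    null = permuted_magnitudes(labels, totals, n_perm, seed)
    return float((1 + np.sum(null >= obs)) / (n_perm + 1))


def convergence_curve(
    labels: StimulusSet,
    spikes: SpikeTable,
    step: int = 20,
    reps: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean STA magnitude at increasing ensemble sizes.

    For each subset size n in {step, 2*step, ..., N} a without-replacement
    random subset of n labels is drawn and the STA (with the subset's own
    ensemble mean) recomputed; the magnitude is averaged over ``reps``
    draws.  Returns (sizes, mean magnitudes).  Subsets with zero total
    spikes are redrawn.
    """
    if step < 1 or reps < 1:
        raise ValueError("step and reps must be >= 1")
    rng = np.random.default_rng(seed)
    N = labels.N
    totals = spikes.totals(order=labels.ids)
    X = labels.grids().reshape(N, -1)
    sizes = list(range(step, N + 1, step))
    if not sizes or sizes[-1] != N:
        sizes.append(N)
    sizes = np.array(sizes)
    curve = np.empty(len(sizes))
    for j, n in enumerate(sizes):
        if n == N:
            grid = _sta_grid_flat(X, totals)
            curve[j] = float(np.sum(grid**2))
            continue
        mags = np.empty(reps)
        for r in range(reps):
            for _ in range(100):
                idx = rng.choice(N, size=n, replace=False)
                if totals[idx].sum() > 0:
                    break
            else:
                raise RuntimeError("could not draw a subset with nonzero spikes")
            grid = _sta_grid_flat(X[idx], totals[idx])
            mags[r] = np.sum(grid**2)
        curve[j] = mags.mean()
    return sizes, curve


def _sta_grid_flat(X: np.ndarray, totals: np.ndarray) -> np.ndarray:
    return totals @ X / totals.sum() - X.mean(axis=0)


@dataclass
class ConvergenceFit:
    """Fit of the saturating magnitude-vs-ensemble-size curve.

    ``a`` is the asymptotic magnitude (the convergent point at infinity);
    ``ratio`` = y(N) / a gates effectiveness at 0.9.
    """

    params: np.ndarray  # a, b, c, d, e, f
    sizes: np.ndarray
    curve: np.ndarray
    ratio: float
    rss: float

    @property
    def a(self) -> float:
        return float(self.params[0])

    @property
    def convergent(self) -> bool:
        return self.ratio >= 0.9

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _conv_model(np.asarray(x, dtype=float), self.params)


def _conv_model(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    a, b, c, d, e, f = p
    return a * (1.0 - b * np.exp(-((x / c) ** d)) + b * e) ** f


def fit_convergence(
    sizes: np.ndarray,
    curve: np.ndarray,
    n_starts: int = 6,
) -> ConvergenceFit:
    """Constrained least-squares fit of the saturating six-parameter family.

    y(x) = a * (1 - b*exp(-(x/c)^d) + b*e)^f with a > 0, b in [0, 1],
    e bounded near zero (so a is the asymptote) and d, f box-constrained
    to keep the curve positive and monotone over the fitted range.
    The convergence ratio is y(N)/a evaluated at the largest size.
    """
    sizes = np.asarray(sizes, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if len(sizes) < 6:
        raise ValueError("need at least 6 curve points (6 free parameters)")
    scale = float(np.max(np.abs(curve)))
    if scale == 0:
        raise ValueError("all-zero curve cannot be fitted")
    N = sizes.max()

    def resid(p):
        return _conv_model(sizes, p) - curve

    lo = [1e-12 * scale, 0.0, sizes.min() / 10, 0.3, 0.0, 0.5]
    hi = [10 * scale, 1.0, 10 * N, 3.0, 0.05, 2.0]
    rng = np.random.default_rng(0)
    best = None
    for k in range(n_starts):
        a0 = curve[-1] if k % 2 == 0 else curve.mean()
        b0 = min(1.0, max(0.0, 1.0 - curve[0] / max(a0, 1e-12)))
        c0 = N / (2 + k)
        x0 = np.clip([max(a0, 1e-9), b0, c0, 1.0, 0.0, 1.0], lo, hi)
        if k >= 2:
            x0 = np.clip(x0 * rng.uniform(0.7, 1.3, size=6), lo, hi)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, max_nfev=2000
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if not np.isfinite(rss) or sol.x[0] <= 0:
            continue
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("convergence-curve fit failed from all starts")
    params = best[1]
    ratio = float(_conv_model(np.array([N]), params)[0] / params[0])
    return ConvergenceFit(params=params, sizes=sizes, curve=curve, ratio=ratio, rss=best[0])


# ---------------------------------------------------------------------------
# ideal figure-ground cells


def ideal_spike_table(labels: StimulusSet, crf, preference: str) -> SpikeTable:
    """Spike table of the ideal FG cell: one spike per trial whenever the
    preferred side covers the CRF-center cell, zero otherwise."""
    from .synthetic_data import VirtualNeuron, simulate_responses

    r, c = crf.center_cell(labels.grid_size) if hasattr(crf, "center_cell") else crf
    neuron = VirtualNeuron(kind="ideal_fg", preference=preference, crf_center=(r, c))
    return simulate_responses(neuron, labels, n_trials=1, seed=0)


def ideal_rffg(labels: StimulusSet, crf, preference: str = "figure") -> RFFG:
    """The ideal figure-ground kernel for a CRF location and preference.

    Equal to the mean of the labels whose preferred side covers the
    CRF-center cell, minus the ensemble-mean label.  On a boundary-
    through-center ensemble this is an antagonistic kernel: preferred
    subregion on the CRF side of the patch center, anti-preferred
    opposite.
    """
    if preference not in ("figure", "ground"):
        raise ValueError("preference must be 'figure' or 'ground'")
    spikes = ideal_spike_table(labels, crf, preference)
    totals = spikes.totals(order=labels.ids)
    if totals.sum() == 0 or totals.sum() == labels.N:
        raise ValueError("ideal cell fires for none or all stimuli: classes empty")
    kern = compute_sta(labels, spikes)
    kern.estimator = "STA"
    return kern
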