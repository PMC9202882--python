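"""Rectified response models built from the estimated kernels.

The STA model predicts the per-stimulus rate as a half-wave-rectified
weighted projection, r_i = max(0, w_sta * <STA, label_i>).  The STA+STC
model adds the significant covariance kernels to the drive — projections
onto positive-eigenvalue kernels are added, those onto negative-
eigenvalue kernels subtracted — before the same rectification.  Weights
minimize the RMS error against the neural per-stimulus mean rates; the
combined model is initialized at the STA optimum with zero covariance
weights, so its RMSE can never exceed the STA model's.

The linearity diagnostic ranks stimuli by their projection onto a kernel
and compares P(stimulus|spike)/P(stimulus) across equal-count bins: a
linear(-rectified) cell gives a monotone, nearly linear curve, an
energy-type cell a U-shaped one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .stimulus_labels import RFFG, SpikeTable, StimulusSet
from .stc import STCResult

__all__ = [
    "ModelFit",
    "sta_model_response",
    "fit_sta_model",
    "fit_sta_stc_model",
    "linearity_diagnostic",
    "LinearityCurve",
]


@dataclass
class ModelFit:
    """Optimized weights and goodness-of-fit of a rectified response model."""

    w_sta: float
    w_stc_pos: np.ndarray
    w_stc_neg: np.ndarray
    rmse: float
    pearson_r: float
    degenerate: bool = False
    optimizer_warning: str | None = None

    @property
    def n_stc(self) -> int:
        return len(self.w_stc_pos) + len(self.w_stc_neg)


def _projections(kernel: np.ndarray, labels: StimulusSet) -> np.ndarray:
    return labels.grids().reshape(labels.N, -1) @ np.asarray(kernel, float).ravel()


def sta_model_response(kernel: RFFG, label, w: float) -> float:
    """max(0, w * <kernel, label>): the rectified STA-model prediction."""
    grid = label.grid if hasattr(label, "grid") else np.asarray(label)
    drive = w * float(np.sum(kernel.grid * grid))
    return max(0.0, drive)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0])


def fit_sta_model(kernel: RFFG, labels: StimulusSet, spikes: SpikeTable) -> ModelFit:
    """Optimize w_sta >= 0 to minimize RMSE against per-stimulus mean rates.

    Because the model is w * max(0, p_i) for w >= 0, the optimum has the
    closed form w* = max(0, sum r_i p_i+ / sum p_i+^2) over the positive
    projections p_i+.
    """
    rates = spikes.mean_rates(order=labels.ids)
    proj = _projections(kernel.grid, labels)
    pos = np.maximum(proj, 0.0)
    denom = float(np.sum(pos**2))
    if denom == 0:
        return ModelFit(
            w_sta=0.0,
            w_stc_pos=np.zeros(0),
            w_stc_neg=np.zeros(0),
            rmse=float(np.sqrt(np.mean(rates**2))),
            pearson_r=0.0,
            degenerate=True,
        )
    w = max(0.0, float(np.sum(rates * pos) / denom))
    pred = w * pos
    rmse = float(np.sqrt(np.mean((pred - rates) ** 2)))
    return ModelFit(
        w_sta=w,
        w_stc_pos=np.zeros(0),
        w_stc_neg=np.zeros(0),
        rmse=rmse,
        pearson_r=_safe_pearson(pred, rates),
    )


def fit_sta_stc_model(
    sta_kernel: RFFG,
    stc: STCResult,
    labels: StimulusSet,
    spikes: SpikeTable,
) -> ModelFit:
    """Jointly optimize (w_sta, w_stc+) and (w_stc-) weights by RMSE.

    Drive = w_sta*<STA,l> + sum_j w+_j*<STC+_j,l> - sum_k w-_k*<STC-_k,l>,
    then half-wave rectification.  Initialized at the STA-model optimum
    with all covariance weights zero; if the optimizer cannot improve,
    the STA-only solution is returned (with a warning flag on failure),
    so the combined RMSE never exceeds the STA RMSE.
    """
    sta_fit = fit_sta_model(sta_kernel, labels, spikes)
    sig = stc.significant_kernels() if stc.significant is not None else []
    pos_k = [k for k in sig if (k.eigenvalue or 0) > 0]
    neg_k = [k for k in sig if (k.eigenvalue or 0) < 0]
    if not pos_k and not neg_k:
        return sta_fit

    rates = spikes.mean_rates(order=labels.ids)
    p_sta = _projections(sta_kernel.grid, labels)
    P_pos = (
        np.stack([_projections(k.grid, labels) for k in pos_k], axis=1)
        if pos_k
        else np.zeros((labels.N, 0))
    )
    P_neg = (
        np.stack([_projections(k.grid, labels) for k in neg_k], axis=1)
        if neg_k
        else np.zeros((labels.N, 0))
    )
    npos, nneg = P_pos.shape[1], P_neg.shape[1]

    def predict(theta: np.ndarray) -> np.ndarray:
        drive = (
            theta[0] * p_sta
            + P_pos @ theta[1 : 1 + npos]
            - P_neg @ theta[1 + npos :]
        )
        return np.maximum(0.0, drive)

    def loss(theta: np.ndarray) -> float:
        return float(np.sqrt(np.mean((predict(theta) - rates) ** 2)))

    x0 = np.concatenate([[sta_fit.w_sta], np.zeros(npos + nneg)])
    bounds = [(0.0, None)] + [(None, None)] * (npos + nneg)
    warning = None
    try:
        sol = optimize.minimize(
            loss, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-10}
        )
        theta = sol.x if sol.fun <= loss(x0) else x0
        if not sol.success:
            warning = str(sol.message)
    except Exception as exc:  # pragma: no cover - optimizer failure path
        theta = x0
        warning = f"optimizer failure: {exc}"
    pred = predict(theta)
    rmse = loss(theta)
    # initialization guarantee: never worse than the STA-only model
    if rmse > sta_fit.rmse:
        theta, rmse, pred = x0, sta_fit.rmse, predict(x0)
    return ModelFit(
        w_sta=float(theta[0]),
        w_stc_pos=theta[1 : 1 + npos].copy(),
        w_stc_neg=theta[1 + npos :].copy(),
        rmse=rmse,
        pearson_r=_safe_pearson(pred, rates),
        optimizer_warning=warning,
    )


@dataclass
class LinearityCurve:
    """Binned P(stimulus|spike)/P(stimulus) ratios along the projection rank."""

    bin_rank: np.ndarray
    p_stimulus: np.ndarray
    p_stimulus_given_spike: np.ndarray
    ratio: np.ndarray
    r_squared: float
    slope: float


def linearity_diagnostic(
    kernel: RFFG,
    labels: StimulusSet,
    spikes: SpikeTable,
    n_bins: int = 10,
) -> LinearityCurve:
    """Bayesian linearity check of a kernel against the observed rates.

    Stimuli are ranked by their projection onto the kernel and split into
    ``n_bins`` equal-count bins (ties broken by stable stimulus order).
    Per bin, P(stimulus) is the fraction of stimuli and
    P(stimulus|spike) the fraction of total spikes; their ratio is
    proportional to P(spike|stimulus).  The returned R^2 is from an
    ordinary linear regression of the ratio on bin rank: near 1 for a
    linear(-rectified) cell, low for a U-shaped (energy) response.
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    rates = spikes.mean_rates(order=labels.ids)
    if rates.sum() <= 0:
        raise ValueError("no spikes: diagnostic undefined")
    proj = _projections(kernel.grid, labels)
    order = np.argsort(proj, kind="stable")
    edges = np.linspace(0, labels.N, n_bins + 1).astype(int)
    p_stim = np.empty(n_bins)
    p_stim_spike = np.empty(n_bins)
    total = rates.sum()
    for b in range(n_bins):
        idx = order[edges[b] : edges[b + 1]]
        p_stim[b] = len(idx) / labels.N
        p_stim_spike[b] = rates[idx].sum() / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_stim > 0, p_stim_spike / p_stim, 0.0)
    rank = np.arange(1, n_bins + 1, dtype=float)
    if np.std(ratio) == 0:
        return LinearityCurve(rank, p_stim, p_stim_spike, ratio, 0.0, 0.0)
    res = stats.linregress(rank, ratio)
    return LinearityCurve(
        bin_rank=rank,
        p_stimulus=p_stim,
        p_stimulus_given_spike=p_stim_spike,
        ratio=ratio,
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
    )
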