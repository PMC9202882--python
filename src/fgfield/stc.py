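"""Spike-triggered covariance of figure-ground labels.

The covariance kernel is the difference between the spike-weighted and
baseline covariances of the STA-centered labels:

    C_spike = 1/(N-1) * sum_i w_i (l_i - sta)(l_i - sta)'
    C_base  = 1/(N-1) * sum_i     (l_i - sta)(l_i - sta)'

with normalized weights w_i = spike_i / mean(spike) (mean weight 1).
Subtracting C_base compensates the structured-label covariance the same
way the ensemble-mean subtraction compensates the spike-triggered
average; with uniform weights the difference is exactly zero.  The
eigenvectors of the symmetric difference expose response-relevant
variance directions invisible to the mean (e.g. the kernel of an
energy-type cell), ranked 1+, 2+, ... from the largest positive and
1-, 2-, ... from the smallest negative eigenvalue.

Eigenvector significance follows a randomization rule: spike counts are
shuffled across stimuli, the eigenvalue spectrum recomputed, and the
consecutive-rank eigenvalue differences summarized per rank by mean and
SD.  An observed kernel is significant if (1) its rank-local eigenvalue
difference exceeds the null mean + 1 SD at that rank, and (2)
its nearest neighbor in the more-extreme direction along the rank is
also significant (chaining inward from 1+ and 1-).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus_labels import RFFG, SpikeTable, StimulusSet
from .sta import compute_sta

__all__ = ["STCResult", "normalize_spikes", "compute_stc", "significant_stcs"]


@dataclass
class STCResult:
    """Full eigendecomposition of the covariance difference.

    ``eigenvalues`` are sorted descending; ``eigenvectors[i]`` is the
    unit-norm G x G kernel for ``eigenvalues[i]``.  ``significant`` is
    filled by :func:`significant_stcs`.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (G^2, G, G), sorted to match eigenvalues
    grid_size: int
    mode: str = "weighted"
    significant: np.ndarray | None = None
    null_diff_mean: np.ndarray | None = None
    null_diff_sd: np.ndarray | None = None

    @property
    def n_eigen(self) -> int:
        return len(self.eigenvalues)

    def rank_label(self, index: int) -> str:
        """'1+', '2+', ... from the top; '1-', '2-', ... from the bottom."""
        n = self.n_eigen
        from_top = index + 1
        from_bottom = n - index
        if from_top <= from_bottom:
            return f"{from_top}+"
        return f"{from_bottom}-"

    def kernel(self, rank: str) -> RFFG:
        """The eigenvector at a rank label such as '1+' or '2-'."""
        idx = self._rank_index(rank)
        return RFFG(
            grid=self.eigenvectors[idx],
            estimator="STC",
            eigenvalue=float(self.eigenvalues[idx]),
            rank=rank,
        )

    def _rank_index(self, rank: str) -> int:
        k = int(rank[:-1])
        if rank.endswith("+"):
            return k - 1
        if rank.endswith("-"):
            return self.n_eigen - k
        raise ValueError(f"bad rank label {rank!r}")

    def significant_kernels(self) -> list[RFFG]:
        if self.significant is None:
            raise ValueError("run significant_stcs first")
        out = []
        for i in np.nonzero(self.significant)[0]:
            out.append(
                RFFG(
                    grid=self.eigenvectors[i],
                    estimator="STC",
                    eigenvalue=float(self.eigenvalues[i]),
                    rank=self.rank_label(int(i)),
                )
            )
        return out


def normalize_spikes(spikes: SpikeTable, order=None) -> np.ndarray:
    """Per-stimulus totals divided by their mean (weights averaging to 1)."""
    totals = spikes.totals(order=order)
    m = totals.mean()
    if m <= 0:
        raise ValueError("all-zero spike counts cannot be normalized")
    return totals / m


def _cov_difference(
    X: np.ndarray, weights: np.ndarray, sta_flat: np.ndarray, mode: str
) -> np.ndarray:
    N = X.shape[0]
    if mode == "weighted":
        D = X - sta_flat
        C = (D * (weights - 1.0)[:, None]).T @ D / (N - 1)
    elif mode == "literal":
        # the typeset form: spike counts multiply the labels inside the
        # outer product; kept for comparison, not the default
        Ds = X * weights[:, None] - sta_flat
        D = X - sta_flat
        C = (Ds.T @ Ds - D.T @ D) / (N - 1)
    else:
        raise ValueError(f"unknown STC mode {mode!r}")
    return (C + C.T) / 2.0


def compute_stc(
    labels: StimulusSet,
    weights: np.ndarray,
    sta: RFFG,
    mode: str = "weighted",
) -> STCResult:
    """Eigendecomposition of C_spike - C_base.

    ``weights`` are the normalized per-stimulus spike weights in set
    order; ``sta`` the bias-compensated STA of the same data (subtracted
    because the response-triggering stimulus distribution is shifted).
    Yields exactly G^2 orthonormal eigenpairs.
    """
    G = labels.grid_size
    X = labels.grids().reshape(labels.N, -1)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != labels.N:
        raise ValueError("one weight per label required")
    C = _cov_difference(X, weights, sta.grid.ravel(), mode)
    vals, vecs = np.linalg.eigh(C)  # ascending
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    return STCResult(
        eigenvalues=vals,
        eigenvectors=vecs.T.reshape(-1, G, G),
        grid_size=G,
        mode=mode,
    )


def _rank_local_differences(vals: np.ndarray) -> np.ndarray:
    """Gap between each eigenvalue and its neighbor toward the spectrum center.

    For position i in the descending spectrum, positions in the top half
    use gap d_i = lambda_i - lambda_{i+1}; positions in the bottom half
    use the gap to the neighbor above, d_{i-1}.  Both ends therefore use
    the gap separating them from the rest of the spectrum.
    """
    n = len(vals)
    gaps = vals[:-1] - vals[1:]  # length n-1, non-negative
    local = np.empty(n)
    half = n // 2
    local[:half] = gaps[:half]
    local[half:] = gaps[half - 1 :]
    return local


def significant_stcs(
    result: STCResult,
    labels: StimulusSet,
    spikes: SpikeTable,
    n_rand: int = 1000,
    seed: int = 0,
) -> STCResult:
    """Mark significant eigenvectors by the randomized eigenvalue-difference rule.

    Null spectra come from shuffling the stimulus -> spike assignment and
    recomputing the covariance difference (the STA is recomputed for each
    shuffle so the null mirrors the full estimator).  Criterion (1):
    the observed rank-local eigenvalue difference exceeds the null
    mean + 1 SD at that rank.  Criterion (2): chaining — a kernel on the
    positive side is significant only if its neighbor toward rank 1+ is,
    and symmetrically on the negative side.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    N = labels.N
    X = labels.grids().reshape(N, -1)
    totals = spikes.totals(order=labels.ids)
    mean_flat = X.mean(axis=0)

    n = result.n_eigen
    null_local = np.empty((n_rand, n))
    for r in range(n_rand):
        perm = rng.permutation(totals)
        w = perm / perm.mean()
        sta_flat = perm @ X / perm.sum() - mean_flat
        C = _cov_difference(X, w, sta_flat, result.mode)
        vals = np.linalg.eigvalsh(C)[::-1]
        null_local[r] = _rank_local_differences(vals)

    mu = null_local.mean(axis=0)
    sd = null_local.std(axis=0, ddof=1) if n_rand > 1 else np.zeros(n)
    obs_local = _rank_local_differences(result.eigenvalues)
    # one-sided: the kernel's separating gap must EXCEED the null band.
    # (A gap below the band means the eigenvalue is closer to the bulk
    # than chance, which is evidence of nothing.)
    outside = obs_local > mu + sd

    sig = np.zeros(n, dtype=bool)
    # positive side: chain inward from the largest eigenvalue
    for i in range(n):
        if result.eigenvalues[i] <= 0:
            break
        if outside[i] and (i == 0 or sig[i - 1]):
            sig[i] = True
        else:
            break
    # negative side: chain inward from the smallest eigenvalue
    for i in range(n - 1, -1, -1):
        if result.eigenvalues[i] >= 0:
            break
        if outside[i] and (i == n - 1 or sig[i + 1]):
            sig[i] = True
        else:
            break
    result.significant = sig
    result.null_diff_mean = mu
    result.null_diff_sd = sd
    return result
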