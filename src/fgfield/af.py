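"""Adaptive-filter (recursive least squares) estimation of linear kernels.

An exponentially weighted RLS filter is run over a randomized stream of
(FG label, spike rate) pairs.  The predicted response is the inner
product of the current kernel with the label (the summed Hadamard
product); each pair updates the kernel by gain x prediction-error.  With
forgetting factor beta = 1 and no leakage the final kernel equals the
ridge-regularized batch least-squares solution, which serves as the
oracle in tests.  Unlike the spike-triggered average, RLS makes no
spherical-symmetry (whiteness) assumption on the label ensemble, so
agreement between the two estimators supports the veridicality of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stimulus_labels import RFFG, SpikeTable, StimulusSet

__all__ = ["AFConfig", "prepare_pairs", "run_rls", "estimate_af", "batch_ridge"]

STIM_WINDOW_S = 0.16  # 40-200 ms stimulus window


@dataclass
class AFConfig:
    """Free parameters of the RLS estimator.

    delta_inv: initial scale of the inverse-correlation matrix P(0) =
      delta_inv * I (equivalently ridge strength 1/delta_inv).
    mu: leakage applied to the kernel each update (0 disables).
    beta: exponential forgetting factor in (0, 1].
    Q: interval (in updates) of the periodic numerical re-symmetrization
      of P; inert when updates are well-conditioned.
    n_pairs_target: the pair list is duplicated whole until it reaches
      this length (4200 = 210 stimuli x 2 contrasts x 10 trials).
    """

    delta_inv: float = 0.00001
    mu: float = 0.0
    beta: float = 0.99
    Q: int = 100
    n_pairs_target: int = 4200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")
        if self.delta_inv <= 0:
            raise ValueError("delta_inv must be positive")


def prepare_pairs(
    labels: StimulusSet, spikes: SpikeTable, config: AFConfig
) -> list[tuple[str, np.ndarray, float]]:
    """Build the randomized (label, spike-rate) input stream.

    One pair per spike-table row (stimulus, trial), rate in Hz = count /
    stimulus window.  The whole list is duplicated until it reaches
    ``n_pairs_target``, then ordered randomly under the config seed such
    that no two consecutive pairs share a stimulus.
    """
    base: list[tuple[str, np.ndarray, float]] = []
    for row in spikes.frame.itertuples(index=False):
        lab = labels[row.stimulus_id]
        base.append(
            (row.stimulus_id, lab.grid.astype(float).ravel(), float(row.stim_count) / STIM_WINDOW_S)
        )
    if not base:
        raise ValueError("no (stimulus, trial) pairs")
    pairs = list(base)
    while len(pairs) < config.n_pairs_target:
        pairs.extend(base)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    pairs = _fix_consecutive(pairs, rng)
    return pairs


def _fix_consecutive(pairs, rng, max_passes: int = 50):
    """Repair the ordering so no two consecutive pairs share stimulus_id."""
    n_distinct = len({sid for sid, _, _ in pairs})
    if n_distinct < 2 and len(pairs) > 1:
        raise ValueError("cannot order pairs without repeats: only one stimulus")
    pairs = list(pairs)
    for _ in range(max_passes):
        bad = [
            i
            for i in range(1, len(pairs))
            if pairs[i][0] == pairs[i - 1][0]
        ]
        if not bad:
            return pairs
        for i in bad:
            if pairs[i][0] != pairs[i - 1][0]:
                continue
            # swap with a random position that breaks both neighborhoods
            for _ in range(200):
                j = int(rng.integers(len(pairs)))
                if _swap_ok(pairs, i, j):
                    pairs[i], pairs[j] = pairs[j], pairs[i]
                    break
    raise RuntimeError("failed to order pairs without consecutive repeats")


def _swap_ok(pairs, i, j):
    if i == j:
        return False
    # simulate the swap and check both neighborhoods
    pairs[i], pairs[j] = pairs[j], pairs[i]
    good = (
        (i == 0 or pairs[i][0] != pairs[i - 1][0])
        and (i == len(pairs) - 1 or pairs[i][0] != pairs[i + 1][0])
        and (j == 0 or pairs[j][0] != pairs[j - 1][0])
        and (j == len(pairs) - 1 or pairs[j][0] != pairs[j + 1][0])
    )
    pairs[i], pairs[j] = pairs[j], pairs[i]  # undo
    return good


def run_rls(
    pairs: list[tuple[str, np.ndarray, float]], config: AFConfig
) -> RFFG:
    """Exponentially weighted RLS over the pair stream; returns w(N+1).

    P is initialized to delta_inv * I; per pair, with input x and desired
    response d:

        k = P x / (beta + x' P x)
        e = d - w' x
        w <- (1 - mu) w + k e
        P <- (P - k x' P) / beta

    Every Q updates P is re-symmetrized as a numerical guard.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    dim = pairs[0][1].size
    G = int(round(np.sqrt(dim)))
    if G * G != dim:
        raise ValueError("label vectors must flatten a square grid")
    P = np.eye(dim) * config.delta_inv
    w = np.zeros(dim)
    for t, (_, x, d) in enumerate(pairs, start=1):
        if x.size != dim:
            raise ValueError("inconsistent label dimensions in pair stream")
        Px = P @ x
        denom = config.beta + x @ Px
        if not np.isfinite(denom) or denom <= 0:
            # regularized restart of the covariance only
            P = np.eye(dim) * config.delta_inv
            Px = P @ x
            denom = config.beta + x @ Px
            if not np.isfinite(denom) or denom <= 0:
                raise FloatingPointError("RLS update singular after restart")
        k = Px / denom
        e = d - w @ x
        w = (1.0 - config.mu) * w + k * e
        P = (P - np.outer(k, Px)) / config.beta
        if config.Q and config.beta < 1.0 and t % config.Q == 0:
            # periodic re-regularization: restore the inverse-correlation
            # matrix to its initial scale so that forgetting (beta < 1)
            # cannot inflate it without bound over a finite label ensemble.
            # With beta = 1 the matrix shrinks monotonically and the guard
            # is unnecessary (kept off to preserve exact batch equivalence).
            P = np.eye(dim) * config.delta_inv
    return RFFG(grid=w.reshape(G, G), estimator="AF")


def estimate_af(
    labels: StimulusSet, spikes: SpikeTable, config: AFConfig | None = None
) -> RFFG:
    """End-to-end adaptive-filter kernel estimate."""
    config = config or AFConfig()
    pairs = prepare_pairs(labels, spikes, config)
    return run_rls(pairs, config)


def batch_ridge(
    pairs: list[tuple[str, np.ndarray, float]], delta_inv: float
) -> np.ndarray:
    """Ridge least-squares solution on the same pairs (RLS oracle at beta=1).

    Solves (I/delta_inv + sum x x') w = sum x d.
    """
    dim = pairs[0][1].size
    A = np.eye(dim) / delta_inv
    b = np.zeros(dim)
    for _, x, d in pairs:
        A += np.outer(x, x)
        b += x * d
    return np.linalg.solve(A, b)
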