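"""Synthetic figure-ground label ensembles and virtual neurons.

The generators reproduce the structural constraints of the stimulus design
that the estimators rely on — every non-dot boundary passes through the
patch center, every boundary shape appears with both figure/ground
polarities (so the ensemble mean cancels exactly), and boundary shapes are
diverse — while remaining seedable and valid by construction.  Virtual
neurons with known ground-truth kernels (ideal figure-ground cells,
rectified-linear cells, energy cells, and non-FG cells) make every
estimator testable without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stimulus_labels import FGLabel, SpikeTable, StimulusSet

__all__ = [
    "VirtualNeuron",
    "gen_halfplane_labels",
    "gen_curved_labels",
    "gen_dot_stimuli",
    "gen_translated_labels",
    "make_dog_kernel",
    "simulate_responses",
    "gen_grating_response_map",
    "grid_coords",
    "center_cell",
]

DEFAULT_GRID = 25


def center_cell(grid_size: int) -> tuple[int, int]:
    """The patch-center cell, (12, 12) for the default 25 x 25 grid."""
    return (grid_size // 2, grid_size // 2)


def grid_coords(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dy) cell-center offsets from the patch center.

    dx increases rightward (columns), dy downward (rows); both arrays are
    (G, G), row-major.
    """
    c = grid_size // 2
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    return (cols - c).astype(float), (rows - c).astype(float)


@dataclass
class VirtualNeuron:
    """A model neuron with a known response rule.

    kind:
      * ``ideal_fg`` — exactly 1 spike whenever the preferred side (figure
        or ground) covers the CRF-center cell, else 0.
      * ``rectified_linear`` — expected rate =
        gain * max(0, <kernel, label> + offset); a positive offset moves
        the operating point above threshold (toward a purely linear cell).
      * ``energy`` — expected rate = gain * |<kernel, label>|; zero mean
        drive, hence invisible to the spike-triggered average but visible
        to covariance analysis.
      * ``non_fg`` — a constant expected count for every stimulus.

    ``crf_center`` is the (row, col) cell the ideal cell monitors.
    ``baseline_rate`` is the expected pre-stimulus-window count.
    """

    kind: str
    preference: str = "figure"
    kernel: np.ndarray | None = None
    crf_center: tuple[int, int] | None = None
    gain: float = 1.0
    offset: float = 0.0
    constant_rate: float = 1.0
    noise: str = "none"  # none | exact | poisson
    baseline_rate: float = 0.0

    def expected_rates(self, labels: StimulusSet) -> np.ndarray:
        """Expected stimulus-window count for every label, in set order."""
        if self.kind == "ideal_fg":
            if self.crf_center is None:
                raise ValueError("ideal_fg neuron needs a crf_center cell")
            want = 1 if self.preference == "figure" else -1
            r, c = self.crf_center
            return np.array(
                [1.0 if lab.grid[r, c] == want else 0.0 for lab in labels]
            )
        if self.kind == "non_fg":
            return np.full(labels.N, float(self.constant_rate))
        if self.kernel is None:
            raise ValueError(f"{self.kind} neuron needs a kernel")
        k = np.asarray(self.kernel, dtype=float).ravel()
        drive = labels.grids().reshape(labels.N, -1) @ k
        if self.kind == "rectified_linear":
            return self.gain * np.maximum(0.0, drive + self.offset)
        if self.kind == "energy":
            return self.gain * np.abs(drive)
        raise ValueError(f"unknown neuron kind {self.kind!r}")


# ---------------------------------------------------------------------------
# label generators


def _halfplane_grid(grid_size: int, orientation: float) -> np.ndarray:
    """Half-plane label: boundary through the center at the given orientation.

    The boundary direction is (cos phi, sin phi); the figure side is the
    positive side of the normal (-sin phi, cos phi).  Cells whose center
    falls exactly on the line go to the figure side.
    """
    dx, dy = grid_coords(grid_size)
    nx, ny = -np.sin(orientation), np.cos(orientation)
    # snap components that are zero up to floating-point noise so that
    # axis-aligned boundaries are exactly axis-aligned
    if abs(nx) < 1e-12:
        nx = 0.0
    if abs(ny) < 1e-12:
        ny = 0.0
    s = nx * dx + ny * dy
    grid = np.where(s >= 0, 1, -1).astype(np.int8)
    return grid


def gen_halfplane_labels(n_orientations: int, grid_size: int = DEFAULT_GRID) -> StimulusSet:
    """Straight boundaries through the center at uniformly spaced orientations.

    For each of ``n_orientations`` orientations in [0, pi) two labels are
    produced, one with the figure on each side, linked as mirror partners;
    the resulting set is exactly closed under figure/ground swap.
    """
    if n_orientations < 2:
        raise ValueError("need at least 2 orientations")
    labels: list[FGLabel] = []
    for j in range(n_orientations):
        phi = np.pi * j / n_orientations
        base = _halfplane_grid(grid_size, phi)
        id_a, id_b = f"hp{j:03d}a", f"hp{j:03d}b"
        labels.append(
            FGLabel(base, id_a, "synthetic", mirror_partner=id_b)
        )
        labels.append(
            FGLabel(-base, id_b, "synthetic", mirror_partner=id_a)
        )
    return StimulusSet(labels)


def _curved_grid(
    grid_size: int, orientation: float, coeffs: np.ndarray
) -> np.ndarray:
    """Label whose boundary is the graph v = c2*u^2/R + c3*u^3/R^2 in the
    frame rotated by ``orientation``; the curve passes through the center."""
    dx, dy = grid_coords(grid_size)
    ct, st = np.cos(orientation), np.sin(orientation)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    R = grid_size / 2.0
    curve = coeffs[0] * u**2 / R + coeffs[1] * u**3 / R**2
    return np.where(v - curve >= 0, 1, -1).astype(np.int8)


def gen_curved_labels(
    n: int,
    grid_size: int = DEFAULT_GRID,
    curvature_sd: float = 1.0,
    seed: int = 0,
    max_retries: int = 100,
) -> StimulusSet:
    """Smooth random boundaries through the center; 2*n labels (both polarities).

    Each boundary is a straight line at a random orientation perturbed by a
    low-order polynomial whose amplitude scales with ``curvature_sd``
    (cells).  Being a function graph in the rotated frame, every curve
    partitions the grid into two simply connected regions; draws leaving
    one side empty are rejected and resampled.  ``curvature_sd = 0``
    reduces to half-plane labels at the drawn orientations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if curvature_sd < 0:
        raise ValueError("curvature_sd must be >= 0")
    rng = np.random.default_rng(seed)
    labels: list[FGLabel] = []
    cc = center_cell(grid_size)
    for j in range(n):
        for attempt in range(max_retries + 1):
            phi = rng.uniform(0.0, np.pi)
            coeffs = rng.normal(0.0, curvature_sd, size=2)
            grid = _curved_grid(grid_size, phi, coeffs)
            # both sides present and the boundary still crosses the center
            r, c = cc
            neighbors = []
            for rr, ccol in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < grid_size and 0 <= ccol < grid_size:
                    neighbors.append(grid[rr, ccol])
            ok = (
                (grid == 1).any()
                and (grid == -1).any()
                and any(v == -grid[r, c] for v in neighbors)
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not generate a valid curved boundary after {max_retries} retries"
            )
        id_a, id_b = f"cv{j:03d}a", f"cv{j:03d}b"
        labels.append(FGLabel(grid, id_a, "synthetic", mirror_partner=id_b))
        labels.append(FGLabel(-grid, id_b, "synthetic", mirror_partner=id_a))
    return StimulusSet(labels)


def gen_dot_stimuli(grid_size: int = DEFAULT_GRID) -> StimulusSet:
    """The exhaustive set of 2*G^2 single-cell +/-1 dot stimuli.

    Dots approximate white noise: their ensemble mean is exactly zero and
    their covariance is diagonal, so spike-triggered averages computed on
    them are free of the structured-label bias.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    labels: list[FGLabel] = []
    for r in range(grid_size):
        for c in range(grid_size):
            for sign, tag in ((1, "p"), (-1, "m")):
                g = np.zeros((grid_size, grid_size), dtype=np.int8)
                g[r, c] = sign
                labels.append(FGLabel(g, f"dot_{r:02d}_{c:02d}{tag}", "dot"))
    return StimulusSet(labels)


def gen_translated_labels(
    base: StimulusSet, shifts: Sequence[tuple[int, int]]
) -> StimulusSet:
    """Copies of each base label displaced by (dx, dy) cells.

    Vacated cells are filled with the value of the nearest remaining edge
    (so each half grows inward from its own side).  Shifted copies no
    longer satisfy the boundary-through-center invariant; they are flagged
    by class 'synthetic' with the shift encoded in the id.
    """
    G = base.grid_size
    out: list[FGLabel] = []
    for dx, dy in shifts:
        if abs(dx) >= G or abs(dy) >= G:
            raise ValueError(f"shift ({dx}, {dy}) exceeds the grid")
        for lab in base:
            g = lab.grid
            shifted = np.empty_like(g)
            rows = np.clip(np.arange(G) - dy, 0, G - 1)
            cols = np.clip(np.arange(G) - dx, 0, G - 1)
            shifted = g[np.ix_(rows, cols)]
            out.append(
                FGLabel(
                    shifted,
                    f"{lab.stimulus_id}@{dx:+d}{dy:+d}",
                    lab.stimulus_class,
                )
            )
    return StimulusSet(out)


def make_dog_kernel(
    center: tuple[float, float],
    orientation: float,
    sigma_center: float,
    sigma_surround: float,
    grid_size: int = DEFAULT_GRID,
) -> np.ndarray:
    """Odd-symmetric difference-of-Gaussians kernel, unit Euclidean norm.

    Two opposed anisotropic Gaussian lobes straddle ``center`` along the
    ``orientation`` axis: the positive lobe on one side and its exact
    negative on the other (along-axis SD ``sigma_center``, cross-axis SD
    ``sigma_surround``, lobe offset ``sigma_center``).  Reflecting the grid
    through the center negates the kernel.
    """
    if sigma_center <= 0 or sigma_surround <= 0:
        raise ValueError("sigmas must be positive")
    rows, cols = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    dx = cols - center[1]
    dy = rows - center[0]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = ct * dx + st * dy
    w = -st * dx + ct * dy
    d = sigma_center
    env = np.exp(-(w**2) / (2 * sigma_surround**2))
    k = env * (
        np.exp(-((u - d) ** 2) / (2 * sigma_center**2))
        - np.exp(-((u + d) ** 2) / (2 * sigma_center**2))
    )
    norm = np.linalg.norm(k)
    if norm == 0:
        raise ValueError("degenerate kernel (zero norm)")
    return k / norm


# ---------------------------------------------------------------------------
# response simulation


def simulate_responses(
    neuron: VirtualNeuron,
    labels: StimulusSet,
    n_trials: int = 10,
    seed: int = 0,
) -> SpikeTable:
    """Simulate a spike table for a virtual neuron.

    Per-trial counts follow the neuron's expected rate: ``noise='none'``
    rounds the expected count to the nearest integer, ``'exact'`` keeps
    the real-valued expectation (for analytic identities), ``'poisson'``
    draws Poisson counts with that mean.  Pre-stimulus counts are Poisson
    with mean ``baseline_rate`` (identically zero when the baseline is 0).
    """
    if neuron.kernel is not None:
        k = np.asarray(neuron.kernel)
        if k.shape != (labels.grid_size, labels.grid_size):
            raise ValueError(
                f"kernel shape {k.shape} does not match grid "
                f"({labels.grid_size}, {labels.grid_size})"
            )
    rng = np.random.default_rng(seed)
    rates = neuron.expected_rates(labels)
    rows = []
    for i, lab in enumerate(labels):
        for t in range(n_trials):
            if neuron.noise == "poisson":
                n = int(rng.poisson(rates[i]))
            elif neuron.noise == "exact":
                n = float(rates[i])
            elif neuron.noise == "none":
                n = int(np.rint(rates[i]))
            else:
                raise ValueError(f"unknown noise mode {neuron.noise!r}")
            if neuron.baseline_rate > 0:
                pre = int(rng.poisson(neuron.baseline_rate))
            else:
                pre = 0
            rows.append((lab.stimulus_id, t, pre, n))
    frame = pd.DataFrame(rows, columns=["stimulus_id", "trial", "pre_count", "stim_count"])
    return SpikeTable(frame)


def gen_grating_response_map(
    crf,
    positions: np.ndarray | None = None,
    gain: float = 20.0,
    seed: int | None = None,
    grid_size: int = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean spike counts to grating probes on a 5 x 5 position grid.

    Counts are proportional to the CRF Gaussian evaluated at each probe
    position (plus the CRF baseline); with a seed, Poisson noise is added.
    Returns ``(map, positions)`` where positions is (5, 5, 2) in (row, col)
    cell units.  Used to test CRF fitting.
    """
    if positions is None:
        lo, hi = 2.0, grid_size - 3.0
        g = np.linspace(lo, hi, 5)
        rr, cc = np.meshgrid(g, g, indexing="ij")
        positions = np.stack([rr, cc], axis=-1)
    counts = crf.baseline + gain * crf.shape(positions[..., 0], positions[..., 1])
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return counts, positions
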