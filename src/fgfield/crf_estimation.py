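"""Classical-receptive-field geometry and response screens.

The classical receptive field (CRF) is summarized by an elliptical 2D
Gaussian fitted to mean spike counts from grating probes on a 5 x 5
position grid.  This module also classifies each stimulus as
figure-at-CRF or ground-at-CRF, and applies the responsiveness
(t / Welch) and figure-ground-modulation (one-way ANOVA) screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimulus_labels import FGLabel, SpikeTable

__all__ = [
    "CRF",
    "CRFFitError",
    "fit_crf",
    "classify_stimulus_fg",
    "responsiveness_test",
    "fg_modulation_anova",
]


class CRFFitError(RuntimeError):
    """The 2D-Gaussian CRF fit failed from every start."""


@dataclass
class CRF:
    """Elliptical 2D-Gaussian receptive-field geometry.

    ``center`` is (row, col) in cell units; ``sd_major >= sd_minor`` are
    the 1-SD semi-axes (the CRF "extent"); ``orientation`` is the angle of
    the major axis (radians, measured from the column axis toward rows);
    ``amplitude`` and ``baseline`` are in spikes.
    """

    center: tuple[float, float]
    sd_major: float
    sd_minor: float
    orientation: float
    amplitude: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sd_major >= self.sd_minor > 0):
            raise ValueError("require sd_major >= sd_minor > 0")

    @property
    def mean_sd(self) -> float:
        """Geometric-mean SD, the scalar CRF size used for scaling."""
        return float(np.sqrt(self.sd_major * self.sd_minor))

    def center_cell(self, grid_size: int) -> tuple[int, int]:
        """The grid cell nearest the CRF center (clipped to the grid)."""
        r = int(np.clip(round(self.center[0]), 0, grid_size - 1))
        c = int(np.clip(round(self.center[1]), 0, grid_size - 1))
        return r, c

    def shape(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile at (row, col)."""
        dr = np.asarray(row, dtype=float) - self.center[0]
        dc = np.asarray(col, dtype=float) - self.center[1]
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        u = ct * dc + st * dr  # along major axis
        v = -st * dc + ct * dr
        return np.exp(-(u**2) / (2 * self.sd_major**2) - v**2 / (2 * self.sd_minor**2))

    def evaluate(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        """Expected count at (row, col): baseline + amplitude * shape."""
        return self.baseline + self.amplitude * self.shape(row, col)

    def ellipse_mask(self, grid_size: int, n_sd: float = 1.0) -> np.ndarray:
        """Boolean mask of cells whose center lies inside the n-SD ellipse."""
        rows, cols = np.mgrid[0:grid_size, 0:grid_size].astype(float)
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        ct, st = np.cos(self.orientation), np.sin(self.orientation)
        u = ct * dc + st * dr
        v = -st * dc + ct * dr
        return (u / (n_sd * self.sd_major)) ** 2 + (v / (n_sd * self.sd_minor)) ** 2 <= 1.0


def _pack(crf_params: np.ndarray) -> CRF:
    r0, c0, s1, s2, th, amp, base = crf_params
    sd_major, sd_minor = (s1, s2) if s1 >= s2 else (s2, s1)
    if s1 < s2:
        th = th + np.pi / 2
    th = ((th + np.pi / 2) % np.pi) - np.pi / 2
    return CRF((r0, c0), sd_major, sd_minor, th, amp, base)


def fit_crf(
    count_map: np.ndarray,
    positions: np.ndarray,
    n_starts: int = 5,
    tol: float = 1e-8,
) -> CRF:
    """Least-squares fit of an elliptical 2D Gaussian to a probe count map.

    ``count_map`` is the (typically 5 x 5) matrix of mean counts and
    ``positions`` the matching (..., 2) probe coordinates in (row, col)
    cell units.  The fit is multi-started from the map's peak cell with
    perturbed widths; the best-RSS parameter set wins.  A flat map (no
    dynamic range) raises :class:`CRFFitError`.
    """
    count_map = np.asarray(count_map, dtype=float)
    positions = np.asarray(positions, dtype=float)
    finite = np.isfinite(count_map)
    if finite.sum() < 6:
        raise CRFFitError("need at least 6 finite map entries")
    y = count_map[finite]
    pr = positions[..., 0][finite]
    pc = positions[..., 1][finite]
    if np.ptp(y) <= 0:
        raise CRFFitError("flat count map: amplitude degenerate")

    peak = np.argmax(y)
    r0, c0 = pr[peak], pc[peak]
    span = max(np.ptp(pr), np.ptp(pc), 1.0)
    base0 = float(y.min())
    amp0 = float(y.max() - y.min())

    def resid(p):
        r, c, s1, s2, th, amp, base = p
        ct, st = np.cos(th), np.sin(th)
        u = ct * (pc - c) + st * (pr - r)
        v = -st * (pc - c) + ct * (pr - r)
        model = base + amp * np.exp(-(u**2) / (2 * s1**2) - v**2 / (2 * s2**2))
        return model - y

    lo = [pr.min() - span, pc.min() - span, 0.05, 0.05, -np.pi, 0.0, -np.inf]
    hi = [pr.max() + span, pc.max() + span, 4 * span, 4 * span, np.pi, np.inf, np.inf]
    rng = np.random.default_rng(0)
    best = None
    for k in range(n_starts):
        w = span / 4 * (1.0 + 0.5 * k)
        jitter = rng.normal(0, 0.2, 2) if k else np.zeros(2)
        x0 = [r0 + jitter[0], c0 + jitter[1], w, w * 0.8, 0.0, amp0, base0]
        x0 = np.clip(x0, lo, hi)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=tol, ftol=tol, gtol=tol
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol.x)
    if best is None:
        raise CRFFitError("2D-Gaussian fit did not converge from any start")
    return _pack(best[1])


def classify_stimulus_fg(label: FGLabel, crf: CRF) -> str:
    """'figure' or 'ground': the label's sign at the cell nearest the CRF center."""
    G = label.grid_size
    r, c = crf.center_cell(G)
    if not (0 <= crf.center[0] <= G - 1 and 0 <= crf.center[1] <= G - 1):
        raise ValueError("CRF center lies outside the label grid")
    v = label.grid[r, c]
    if v == 0:
        raise ValueError(
            f"CRF-center cell ({r}, {c}) is masked in label {label.stimulus_id!r}"
        )
    return "figure" if v > 0 else "ground"


def responsiveness_test(spikes: SpikeTable, alpha_var: float = 0.05) -> float:
    """Two-sided p-value for stimulus-window vs pre-stimulus counts.

    Pools all trials of all stimuli.  A two-sided F-test on the variances
    at ``alpha_var`` selects Student's t-test (equal variance) or Welch's
    t-test.  A neuron is responsive at p < 0.05.  If both samples have
    zero variance the comparison is degenerate and p = 1 is returned.
    """
    pre = spikes.frame["pre_count"].to_numpy(dtype=float)
    stim = spikes.frame["stim_count"].to_numpy(dtype=float)
    if len(pre) < 2 or len(stim) < 2:
        raise ValueError("need at least 2 trials")
    v1, v2 = pre.var(ddof=1), stim.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return 1.0
    equal_var = True
    if v1 > 0 and v2 > 0:
        f = v1 / v2
        d1, d2 = len(pre) - 1, len(stim) - 1
        p_f = 2 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
        equal_var = p_f >= alpha_var
    else:
        equal_var = False
    _, p = stats.ttest_ind(stim, pre, equal_var=equal_var)
    return float(p)


def fg_modulation_anova(spikes: SpikeTable, classes: dict[str, str]) -> float:
    """One-way ANOVA p-value for figure-ground modulation of mean counts.

    ``classes`` maps stimulus_id -> 'figure' | 'ground' (from
    :func:`classify_stimulus_fg`).  Per-stimulus mean counts are grouped
    by class; significant FG modulation at p < 0.05.
    """
    means = spikes.frame.groupby("stimulus_id")["stim_count"].mean()
    fig = [means[s] for s, cl in classes.items() if cl == "figure" and s in means]
    gnd = [means[s] for s, cl in classes.items() if cl == "ground" and s in means]
    if len(fig) < 2 or len(gnd) < 2:
        raise ValueError("each class needs at least 2 stimuli")
    _, p = stats.f_oneway(fig, gnd)
    return float(p)
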