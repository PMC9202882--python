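"""Data model and I/O for figure-ground label stimulus sets.

A figure-ground (FG) label is a small square grid tagging each cell as
figure (+1), ground (-1), or masked (0).  Label ensembles carry the
metadata needed by the estimators: mirror partners (same boundary with
figure and ground sides exchanged), contrast partners (identical label
shown at opposite luminance polarity, whose responses are pooled), and
the ensemble-mean label used to compensate the non-uniformity bias of a
structured, non-white stimulus set.

Storage formats are deliberately plain: 8-bit PNG masks (0 = ground,
255 = figure, 128 = masked) with a JSON metadata table, tab-delimited
kernel matrices with a JSON sidecar, and CSV spike tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "FGLabel",
    "StimulusSet",
    "SpikeTable",
    "RFFG",
    "LabelValidationError",
    "load_labels",
    "save_labels",
    "pool_contrast_pairs",
    "ensemble_mean_label",
    "write_kernel",
    "read_kernel",
]

VALID_CLASSES = ("filled", "natural", "dot", "synthetic")


class LabelValidationError(ValueError):
    """A label grid violates the {+1, -1, 0} value-set or boundary invariants."""


@dataclass
class FGLabel:
    """One figure-ground label: a G x G grid of {+1, -1, 0}.

    +1 marks figure, -1 ground, 0 masked cells (excluded from extent
    computations).  For non-dot labels the figure/ground boundary passes
    through the grid center.
    """

    grid: np.ndarray
    stimulus_id: str
    stimulus_class: str = "synthetic"
    mirror_partner: str | None = None
    contrast_partner: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise LabelValidationError(
                f"label {self.stimulus_id!r}: grid must be square 2-D, got {self.grid.shape}"
            )
        bad = ~np.isin(self.grid, (-1, 0, 1))
        if bad.any():
            cells = [(int(r), int(c)) for r, c in zip(*np.nonzero(bad))][:10]
            raise LabelValidationError(
                f"label {self.stimulus_id!r}: values outside {{+1,-1,0}} at cells {cells}"
            )
        if self.stimulus_class != "dot":
            if not (self.grid == 1).any() or not (self.grid == -1).any():
                raise LabelValidationError(
                    f"label {self.stimulus_id!r}: non-dot label needs at least one "
                    "figure (+1) and one ground (-1) cell"
                )

    @property
    def grid_size(self) -> int:
        return self.grid.shape[0]

    def swapped(self, stimulus_id: str | None = None) -> "FGLabel":
        """The figure/ground-swapped copy of this label."""
        return FGLabel(
            grid=-self.grid,
            stimulus_id=stimulus_id or f"{self.stimulus_id}~swap",
            stimulus_class=self.stimulus_class,
            mirror_partner=self.stimulus_id,
        )


@dataclass
class StimulusSet:
    """An ordered ensemble of FG labels with its ensemble-mean label."""

    labels: list[FGLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = {lab.grid_size for lab in self.labels}
        if len(sizes) > 1:
            raise LabelValidationError(f"mixed grid sizes in set: {sorted(sizes)}")
        ids = [lab.stimulus_id for lab in self.labels]
        if len(set(ids)) != len(ids):
            raise LabelValidationError("duplicate stimulus_id in set")
        self._index = {lab.stimulus_id: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __getitem__(self, stimulus_id: str) -> FGLabel:
        return self.labels[self._index[stimulus_id]]

    @property
    def N(self) -> int:
        """Number of distinct labels (after any contrast pooling)."""
        return len(self.labels)

    @property
    def grid_size(self) -> int:
        if not self.labels:
            raise ValueError("empty stimulus set has no grid size")
        return self.labels[0].grid_size

    @property
    def ids(self) -> list[str]:
        return [lab.stimulus_id for lab in self.labels]

    def grids(self) -> np.ndarray:
        """All label grids stacked into an (N, G, G) float array."""
        return np.stack([lab.grid for lab in self.labels]).astype(float)

    @property
    def mean_label(self) -> np.ndarray:
        return ensemble_mean_label(self)


@dataclass
class SpikeTable:
    """Per-stimulus, per-trial spike counts.

    One row per (stimulus_id, trial) with the pre-stimulus-window count
    (100-0 ms before onset) and the stimulus-window count (40-200 ms
    after onset).  Counts are non-negative; they are integers for
    recorded or discretized synthetic data and may be real-valued for
    the exact synthetic mode.
    """

    frame: pd.DataFrame

    REQUIRED = ("stimulus_id", "trial", "pre_count", "stim_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"spike table missing columns: {missing}")
        if (self.frame["stim_count"] < 0).any() or (self.frame["pre_count"] < 0).any():
            raise ValueError("spike counts must be non-negative")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_trials(self) -> int:
        return int(self.frame.groupby("stimulus_id")["trial"].size().max())

    def totals(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Per-stimulus total spikes (summed over trials), in the given id order."""
        tot = self.frame.groupby("stimulus_id")["stim_count"].sum()
        if order is None:
            return tot.to_numpy(dtype=float)
        return tot.reindex(list(order)).to_numpy(dtype=float)

    def mean_rates(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Per-stimulus mean stimulus-window count over trials."""
        m = self.frame.groupby("stimulus_id")["stim_count"].mean()
        if order is None:
            return m.to_numpy(dtype=float)
        return m.reindex(list(order)).to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpikeTable":
        return cls(pd.read_csv(path))


@dataclass
class RFFG:
    """A figure-ground responsive field: a real-valued kernel on the label grid.

    Positive cells mark locations where a figure increases the response,
    negative cells where a ground does.  Carries estimator provenance and
    the significance / convergence annotations used to screen kernels.
    """

    grid: np.ndarray
    estimator: str = "STA"
    p_perm: float | None = None
    convergence_ratio: float | None = None
    eigenvalue: float | None = None
    rank: str | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)

    @property
    def magnitude(self) -> float:
        """Squared sum of all elements."""
        return float(np.sum(self.grid**2))

    @property
    def effective(self) -> bool:
        """Significant magnitude (p < 0.05) and good convergence (ratio >= 0.9)."""
        return (
            self.p_perm is not None
            and self.p_perm < 0.05
            and self.convergence_ratio is not None
            and self.convergence_ratio >= 0.9
        )

    def preference(self, crf_center_cell: tuple[int, int]) -> str:
        """'figure' or 'ground' from the kernel sign at the CRF-center cell."""
        v = self.grid[crf_center_cell]
        return "figure" if v >= 0 else "ground"


# ---------------------------------------------------------------------------
# operations


def ensemble_mean_label(labels: StimulusSet) -> np.ndarray:
    """Element-wise mean of all label grids (the STA bias-compensation term)."""
    if labels.N == 0:
        raise ValueError("cannot take the ensemble mean of an empty stimulus set")
    return labels.grids().mean(axis=0)


def pool_contrast_pairs(
    labels: StimulusSet, spikes: SpikeTable
) -> tuple[StimulusSet, SpikeTable]:
    """Collapse contrast pairs to single labels, summing counts trial-wise.

    Two stimuli with identical FG labels but opposite luminance polarity are
    merged: the pair's spike counts are added per trial, so downstream
    estimates are contrast invariant.  Unpaired labels pass through.
    """
    index = {lab.stimulus_id: lab for lab in labels}
    for lab in labels:
        p = lab.contrast_partner
        if p is None:
            continue
        if p not in index:
            raise KeyError(f"dangling contrast_partner {p!r} on {lab.stimulus_id!r}")
        if index[p].contrast_partner != lab.stimulus_id:
            raise ValueError(
                f"contrast_partner link not symmetric: {lab.stimulus_id!r} <-> {p!r}"
            )

    keep: list[FGLabel] = []
    merged_into: dict[str, str] = {}
    seen: set[str] = set()
    for lab in labels:
        if lab.stimulus_id in seen:
            continue
        seen.add(lab.stimulus_id)
        p = lab.contrast_partner
        if p is not None:
            seen.add(p)
            merged_into[p] = lab.stimulus_id
        merged_into[lab.stimulus_id] = lab.stimulus_id
        keep.append(
            FGLabel(
                grid=lab.grid,
                stimulus_id=lab.stimulus_id,
                stimulus_class=lab.stimulus_class,
                mirror_partner=lab.mirror_partner,
                contrast_partner=None,
            )
        )

    df = spikes.frame.copy()
    df["stimulus_id"] = df["stimulus_id"].map(lambda s: merged_into.get(s, s))
    pooled = (
        df.groupby(["stimulus_id", "trial"], as_index=False)[["pre_count", "stim_count"]]
        .sum()
    )
    return StimulusSet(keep), SpikeTable(pooled)


# ---------------------------------------------------------------------------
# I/O

_PNG_FIGURE, _PNG_GROUND, _PNG_MASKED = 255, 0, 128


def _grid_to_png_array(grid: np.ndarray) -> np.ndarray:
    img = np.full(grid.shape, _PNG_MASKED, dtype=np.uint8)
    img[grid == 1] = _PNG_FIGURE
    img[grid == -1] = _PNG_GROUND
    return img


def _png_array_to_grid(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    grid = np.zeros(arr.shape, dtype=np.int8)
    grid[arr >= 192] = 1
    grid[arr <= 64] = -1
    return grid


def _majority_downsample(grid: np.ndarray, grid_size: int) -> np.ndarray:
    """Resample a {+1,-1,0} mask to grid_size x grid_size by per-cell majority vote.

    Each target cell votes over the source cells whose index block maps to it;
    the sign of the summed votes wins, exact ties going to figure.
    """
    src = grid.shape[0]
    if src == grid_size:
        return grid.copy()
    edges = np.linspace(0, src, grid_size + 1)
    out = np.zeros((grid_size, grid_size), dtype=np.int8)
    for r in range(grid_size):
        r0, r1 = int(np.floor(edges[r])), int(np.ceil(edges[r + 1]))
        for c in range(grid_size):
            c0, c1 = int(np.floor(edges[c])), int(np.ceil(edges[c + 1]))
            block = grid[r0:r1, c0:c1]
            s = int(block.sum())
            if s > 0:
                out[r, c] = 1
            elif s < 0:
                out[r, c] = -1
            elif (block != 0).any():
                out[r, c] = 1  # tie between figure and ground -> figure
    return out


def save_labels(labels: StimulusSet, path: str | Path) -> None:
    """Write a stimulus set as PNG masks plus a metadata.json table."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = []
    for lab in labels:
        fname = f"{lab.stimulus_id}.png"
        Image.fromarray(_grid_to_png_array(lab.grid)).save(path / fname)
        meta.append(
            {
                "stimulus_id": lab.stimulus_id,
                "file": fname,
                "stimulus_class": lab.stimulus_class,
                "mirror_partner": lab.mirror_partner,
                "contrast_partner": lab.contrast_partner,
            }
        )
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def load_labels(path: str | Path, grid_size: int) -> StimulusSet:
    """Load a stimulus set from a directory of mask images with metadata.json.

    Masks are thresholded to {+1, -1} (0 under a mid-gray mask) and resampled
    to ``grid_size`` by majority vote per target cell.
    """
    path = Path(path)
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json in {path}")
    meta = json.loads(meta_path.read_text())
    out: list[FGLabel] = []
    for entry in meta:
        img = Image.open(path / entry["file"]).convert("L")
        grid = _png_array_to_grid(np.array(img))
        grid = _majority_downsample(grid, grid_size)
        out.append(
            FGLabel(
                grid=grid,
                stimulus_id=entry["stimulus_id"],
                stimulus_class=entry.get("stimulus_class", "synthetic"),
                mirror_partner=entry.get("mirror_partner"),
                contrast_partner=entry.get("contrast_partner"),
            )
        )
    return StimulusSet(out)


def write_kernel(kernel: RFFG, path: str | Path, render: bool = False) -> None:
    """Write a kernel as a tab-delimited matrix plus a JSON sidecar.

    The sidecar records estimator provenance, significance and convergence.
    With ``render=True`` a signed-colormap PNG is emitted next to the matrix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, kernel.grid, delimiter="\t", fmt="%.17g")
    sidecar = {
        "estimator": kernel.estimator,
        "magnitude": kernel.magnitude,
        "p": kernel.p_perm,
        "convergence_ratio": kernel.convergence_ratio,
        "effective": kernel.effective,
        "eigenvalue": kernel.eigenvalue,
        "rank": kernel.rank,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vmax = float(np.abs(kernel.grid).max()) or 1.0
        plt.imsave(
            path.with_suffix(".png"),
            kernel.grid,
            cmap="RdBu_r",
            vmin=-vmax,
            vmax=vmax,
        )


def read_kernel(path: str | Path) -> RFFG:
    """Read a kernel matrix and its JSON sidecar written by :func:`write_kernel`."""
    path = Path(path)
    grid = np.loadtxt(path, delimiter="\t", ndmin=2)
    side = path.with_suffix(path.suffix + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return RFFG(
        grid=grid,
        estimator=meta.get("estimator", "STA"),
        p_perm=meta.get("p"),
        convergence_ratio=meta.get("convergence_ratio"),
        eigenvalue=meta.get("eigenvalue"),
        rank=meta.get("rank"),
    )
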