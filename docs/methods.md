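# Methods

## The estimation problem

A figure-ground (FG) label is a G × G grid with +1 on cells a human
observer assigns to the figure and −1 on ground cells (0 marks cells
outside an optional aperture). The ensembles considered here share two
structural constraints: the figure/ground boundary passes through the
patch center, and every boundary shape appears with both polarities
(figure on either side). Given per-stimulus spike counts, the goal is a
kernel on the label grid whose positive (negative) cells mark locations
where figure (ground) coverage increases the response — a *responsive
field with respect to figure and ground*, not a luminance receptive
field.

G = 25 throughout (all estimators share the grid so kernels are
comparable); the patch center is cell (12, 12); continuous positions are
in cell units, rows increasing downward.

## Bias-compensated spike-triggered average

```
K = Σ_i L_i s_i / Σ_i s_i − (1/N) Σ_i L_i
```

`s_i` is the per-stimulus total over trials; the estimator is invariant
to positive rescaling of the counts, so totals and means are
interchangeable. The ensemble-mean subtraction is the whitening
surrogate: labels cannot be whitened without destroying the very notion
of a figure region, but on an ensemble closed under figure/ground swap
the mean is exactly zero and a response-independent cell produces an
exactly zero kernel. Kernel values lie in [−1, +1].

*Significance.* The stimulus→count assignment is permuted (default
1000×) and the kernel magnitude `‖K‖²` compared with the permuted
magnitudes; `p = (1 + #{‖K*‖² ≥ ‖K‖²}) / (n_perm + 1)` (the add-one
estimator avoids p = 0). Degenerate all-equal counts give p = 1 by
construction. Permutation operates on stimulus-level totals, not trials:
the estimator only ever sees totals.

*Convergence.* Mean kernel magnitude is computed on random
without-replacement subsets at sizes step, 2·step, …, N (step 20,
100 repetitions by default; the subset's own ensemble mean is used for
compensation, since the bias term must match the ensemble actually
averaged). The curve is fitted with the saturating six-parameter family

```
y(x) = a · (1 − b·exp(−(x/c)^d) + b·e)^f
```

by bounded least squares with multi-start (b ∈ [0,1], e ∈ [0, 0.05] so
that a is the asymptote, d ∈ [0.3, 3], f ∈ [0.5, 2]). The convergence
ratio is y(N)/a; kernels need ratio ≥ 0.9 (and p < 0.05) to count as
effective. The ratio is insensitive to the exact family on
well-saturated curves; the family lives behind one function and can be
swapped.

*Ideal kernels.* An ideal FG cell fires one spike exactly when its
preferred side covers its CRF-center cell. Its kernel equals the mean of
the selected labels minus the ensemble mean; on a uniform half-plane
ensemble this has the closed form `M(x) = 1 − 2θ(x, p)/π` with θ the
angle between the cell position and the CRF-center direction — the
oracle used in tests. Its PR ratio is 0.5 (balanced antagonism).

## Adaptive filter (recursive least squares)

Exponentially weighted RLS over a randomized stream of (label, rate)
pairs, rate = single-trial count / 0.16 s stimulus window, one pair per
(stimulus, trial), the whole list duplicated to ≥ 4200 pairs and ordered
so no two consecutive pairs share a stimulus. Parameters: initial
inverse-correlation P(0) = δ⁻¹I with δ⁻¹ = 10⁻⁵, forgetting β = 0.99,
leakage μ = 0, re-regularization interval Q = 100.

The Q guard is load-bearing, not cosmetic: with β < 1 on a finite,
highly correlated ensemble, P inflates as δ⁻¹/βᵗ in weakly excited
directions and the effective window (≈ 1/(1−β) pairs) supports a
near-unregularized fit that amplifies noise — the estimated kernel
decorrelates from both truth and the STA. Resetting P to δ⁻¹I every Q
updates keeps the filter in a slow, strongly regularized regime whose
accumulated updates track the spike-label correlation; with the guard,
cos(AF, STA) ≈ 0.99 for synthetic rectified-linear cells at these
parameters. At β = 1 the guard is off and the final kernel equals the
ridge solution `(δI + ΣxxT)⁻¹Σxd` exactly (the batch oracle asserted in
tests at G = 5).

## Spike-triggered covariance

With normalized weights `w_i = s_i / mean(s)` (mean weight 1):

```
C = 1/(N−1) Σ_i (w_i − 1)(L_i − K_STA)(L_i − K_STA)ᵀ
```

i.e. spike-weighted minus baseline covariance of STA-centered labels.
The weighted reading (weights outside the outer product) is the default:
it preserves the null identity C ≡ 0 for uniform weights, which the
compensation logic requires. The literal alternative (counts multiplying
the labels inside the product) is available via `mode="literal"` for
comparison; the two are deliberately not reconciled.

The symmetric difference yields G² = 625 orthonormal eigenpairs. An
eigenvector is significant when (1) its rank-local eigenvalue gap (the
gap separating it from the spectrum interior) exceeds the mean + 1 SD of
the same gap across n_rand spike-shuffled null spectra (per-rank
statistics; the STA is recomputed per shuffle so the null mirrors the
full estimator), and (2) its neighbor in the more-extreme direction is
itself significant — chaining inward from ranks 1⁺ and 1⁻, so
significant sets are contiguous from each end.

## Response models

STA model: `r_i = max(0, w·⟨K_STA, L_i⟩)`, w ≥ 0 minimizing RMSE against
per-stimulus mean rates (closed form: a nonnegative projection
regression). STA+STC model: drive plus significant covariance kernels,
positive-eigenvalue projections added, negative subtracted, all weights
fitted jointly by L-BFGS-B initialized at the STA optimum with zero
covariance weights — so the combined RMSE can never exceed the STA
model's (enforced; the STA-only solution is returned on optimizer
failure). Model quality is the Pearson correlation between model and
neural per-stimulus rates.

The models have no intercept. A cell with an un-modeled positive
baseline drive is therefore *not* "linear" from the model's viewpoint:
covariance kernels legitimately absorb part of the intercept and the
model comparison shows Δr ≈ 0.03. The Δr ≈ 0 prediction holds for cells
whose only nonlinearity is the model's own half-wave rectification,
which is what the model-comparison tests simulate.

*Linearity diagnostic.* Stimuli are ranked by kernel projection and
split into equal-count bins (default 10); per bin, the ratio
P(stimulus|spike)/P(stimulus) is proportional to P(spike|stimulus). The
reported R² is from an ordinary regression of the ratio on bin rank. A
cell operating in its linear range gives R² near 1; a half-rectified
cell gives a flat-then-linear curve (R² ≈ 0.83 when half the stimuli sit
below threshold) — a structural property of rectification, not an
estimator failure; an energy cell gives a U-shaped, non-monotone curve.

## CRF estimation and screens

The CRF is an elliptical 2D Gaussian (center, two SDs, orientation,
amplitude, baseline) fitted by bounded least squares to the 5 × 5
grating-probe count map, multi-started from the peak cell; the 1-SD
ellipse is the CRF extent. Stimuli are classed figure-at-CRF or
ground-at-CRF by the label's sign at the cell nearest the CRF center
(sub-cell interpolation would imply label values the data model does not
define). Responsiveness compares pre-stimulus (100–0 ms) and
stimulus-window (40–200 ms) counts with Student's or Welch's t-test,
chosen by a two-sided variance F-test at α = 0.05 (the variance-screen
test and α are this package's choice). FG modulation is a one-way ANOVA
on per-stimulus mean counts grouped by class.

## Geometry metrics

Support = cells with |value| > ε·max|value|, ε = 0.05 by default (an
explicit knob: estimated kernels are noisy and have no natural support).
PR ratio = preferred-sign cells / support cells. Overlap ratio =
Jaccard |AND|/|OR| between the rasterized 1-SD CRF ellipse (cell centers
inside) and the preferred region. Alignment operators: translation of
the CRF center to the patch center, rotation about the patch center
taking the preferred subregion's |value|-weighted center of gravity to
the left (figure) or right (ground) axis, and isotropic scaling about
the CRF center to a common geometric-mean SD. Population means
max-normalize each kernel before aligning and averaging.

Resampling uses cubic splines (order 3) by default rather than bilinear:
on kernels whose features span only a few cells, bilinear loses 4–10 %
of the kernel maximum per pass and cannot keep inverse compositions of
the alignment operators under the intended 2 %; cubic does (≈ 0.1 % on
difference-of-Gaussians kernels). Bilinear remains selectable. The ideal
half-plane kernel is excluded from the 2 % round-trip claim: its cone
apex at the patch center (gradient ∼ 1/r) defeats any interpolation
order.

## Synthetic data: what it emulates and what it does not

Generators produce half-plane ensembles (uniformly spaced straight
boundaries through the center), curved ensembles (a straight line
perturbed by a random quadratic/cubic in the rotated frame — always a
function graph, hence always partitioning the grid into two simply
connected regions; amplitude set by `curvature_sd` in cells), exhaustive
±1 single-cell dot sets, translated copies (edge-filled), and
odd-symmetric difference-of-Gaussians truth kernels (two opposed
anisotropic lobes, unit norm). Every generated boundary shape appears
with both polarities, and the swapped partner is the *exact* negation of
its mate: this guarantees exact swap-closure (zero ensemble mean, exact
STA null, exact figure/ground ideal-kernel symmetry). For straight
boundaries the negation coincides with the geometric mirror-about-
tangent; for curved boundaries it replaces it — a deliberate choice of
algebraic closure over geometric mirroring. The deterministic tie-break
(boundary-centered cells to the figure side) is applied to the first
label of each pair; its partner, being the negation, carries those cells
on the ground side.

Virtual neurons: ideal FG cells (the definitional reference),
rectified-linear cells `gain·max(0, ⟨k, L⟩ + offset)` (offset shifts the
operating point; 0 by default), energy cells `gain·|⟨k, L⟩|`, and
constant-rate non-FG cells. Noise modes: `poisson` (Poisson counts at
the expected rate), `none` (expected count rounded to nearest integer,
keeping deterministic counts integer-valued like real data), and `exact`
(real-valued expected counts, used where analytic identities — e.g. the
exact dot-set recovery `max(x,0) − max(−x,0) = x` — are asserted; this
mode deliberately relaxes the integer-count invariant). Pre-stimulus
counts are Poisson at `baseline_rate` (default 0, so responsiveness
screens pass trivially unless a baseline is configured).

What the synthetic ensembles do *not* emulate: natural contour
statistics (convexity/closure/symmetry balancing is only approximated by
`curvature_sd`), luminance, color and texture, perceptual inconsistency
across observers, and inter-neuron correlations. Passing tests therefore
demonstrate the estimators' correctness and calibration under the
stimulus design's structural constraints, not population-level claims
about cortical neurons.

## Problem sizes and numerical choices

Test and acceptance runs use ensembles of 104–210 labels, 10 trials, 500–
1000 permutations, and 100–300 covariance randomizations — sizes chosen
to match the stimulus design while keeping a full suite run in tens of
seconds on one core. Optimizers: `scipy.optimize.least_squares` with
box constraints (CRF and convergence fits, tolerance 1e-8/1e-10,
multi-start, best-RSS winner regardless of the success flag — flat noisy
curves legitimately exhaust evaluation budgets near the optimum) and
L-BFGS-B (model weights). Eigendecompositions use `numpy.linalg.eigh`;
the covariance difference is symmetrized before decomposition. Seeds:
every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from a master seed via `SeedSequence.spawn`.

## Known limitations

- The convergence-curve family is one saturating form among several; only
  the ratio y(N)/a is consumed downstream.
- The RLS Q-interval is implemented as a periodic covariance reset; other
  re-regularization schemes (e.g. gradual shrinkage) would also tame the
  forgetting-driven inflation and may differ in transient behavior.
- Estimated kernels inherit the label ensemble's spatial correlation;
  comparisons against the ideal kernel (same ensemble, same correlation)
  are the intended reading, not absolute spatial accuracy (the dot-set
  validation quantifies the gap).
- The response models carry no intercept or output nonlinearity beyond
  half-wave rectification; cells with un-modeled baseline drive shift the
  model comparison (see above).
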