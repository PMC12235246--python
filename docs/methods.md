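# Methods

## The model

`pottsml` simulates a confluent two-dimensional cell layer with the
cellular Potts model (CPM) and asks whether a cell's *motility
phenotype* — high-motility ("active") versus low- or zero-motility
("passive") — can be read off a single static snapshot of the layer.

Cells are sets of same-labelled pixels on a periodic square lattice
(default 300×300, exactly tiled by 144 cells of target area
A_t = 625). Every pixel belongs to a cell (confluence; there is no
medium), and each cell's pixel set is forced to stay 4-connected.
Dynamics are Metropolis Monte Carlo pixel-copy attempts against

    H = Σ_{<i,j>} J · (1 − δ(σ_i, σ_j))          adhesion, J = 5
      + λ_A Σ_σ (A_σ − A_t)²                      area constraint, λ_A = 1
      + λ_P Σ_σ [P_σ > P_t] (P_σ − P_t)²          perimeter constraint

where P_σ is the number of boundary pixels (pixels with at least one
first-order neighbour in a different cell) and the perimeter term is
*one-sided*: it vanishes identically for P_σ ≤ P_t = 150 and grows
quadratically above, so it only suppresses pathologically ramified
shapes (λ_P = 1). Adhesion pairs and pixel-copy sources use the
4-neighbourhood by default (configurable to the 8-neighbourhood).

Motility enters as an energy bias added to ΔH of each proposed copy:

    ΔH_mot = − Σ_σ κ_σ (p̂_σ · ΔR⃗_σ)

summed over the two cells whose centre of mass (COM) moves — the
gainer and the loser each contribute with their own κ and polarity.
ΔR⃗_σ is that cell's own COM displacement under the proposal, computed
with the minimum-image convention. p̂_σ is a unit polarity vector that
performs rotational diffusion: once per Monte Carlo step (MCS,
defined as lattice_size² attempts) every θ_σ receives an independent
perturbation η ~ U(−π/36, π/36), giving a rotational diffusion
constant D_r = (π/36)²/6 per MCS and a persistence time of roughly
8·10² MCS. A proposed copy is accepted with probability
min(1, exp(−ΔH/T)) provided the losing cell stays connected and
non-empty. Polarities of all cells are updated every MCS regardless
of κ (for κ = 0 the angle has no energetic effect).

Two phenotype scenarios are studied: a pure active–passive mixture
(κ_p = 0, κ_a = 1500) and finite-contrast mixtures characterised by
the motility ratio γ = κ_p/κ_a with κ_p = 150 and κ_a between 375
and 1500 (γ = 0.4 … 0.1). N_a of the 144 cells are chosen active
uniformly at random.

### Temperature

T is the one Hamiltonian parameter without a prescribed value; it is
exposed in the configuration and echoed into every archive. The
default T = 5 was calibrated on simulation behaviour alone: passive
cells (κ = 0) show clearly visible boundary fluctuation (mean
boundary length ≈ 121 versus 96 for the initial square tiling)
without fragmentation, typical shapes stay below the perimeter
threshold so that the one-sided penalty remains inactive for healthy
cells, and at κ_a = 1500 active cells are strongly elongated and
displace an order of magnitude farther than passive ones
(≈ 220 px versus ≈ 27 px of COM travel per 2000 MCS). At T ≳ 50 the
mean boundary length exceeds P_t, i.e. the perimeter penalty would be
chronically active — outside the model's intended regime.

### Numerical implementation

The flip kernel is numba-compiled over flat arrays. Energy changes
are evaluated incrementally from the 13-pixel neighbourhood of the
proposed copy; areas, boundary-pixel counts and COMs are maintained
incrementally and are exactly consistent with from-scratch
recomputation (property-tested). Connectivity is checked with a
256-entry ring lookup first; ambiguous cases fall back to an exact
flood fill that exploits the fact that every fragment of a cell minus
one pixel must touch that pixel's 4-neighbourhood, so the fill can
stop as soon as all in-cell 4-neighbours are reached. Randomness
comes from one xorshift128+ stream per simulation, seeded from the
run configuration; identical configurations reproduce snapshot
archives bit for bit. COMs are stored wrapped into [0, L); unwrapped
trajectories are reconstructed per snapshot via minimum-image
increments (valid because per-interval displacements are far below
L/2).

## Features

From each snapshot the package extracts 145 per-cell features in four
groups (the registry in `pottsml.registry`):

* **local shape (23)** — pixel-count area, boundary length, fitted
  ellipse semi-axes and eccentricity e = √(1 − b²/a²), major-axis
  orientation, parallel/perpendicular alignment with the neighbours
  (mean |cos Δφ| and |sin Δφ| of major-axis angle differences —
  nematic-invariant), neighbour count, and standard region-geometry
  descriptors (aspect ratio, elongation, shape index P/√A,
  circularity, equivalent diameter, radius of gyration, central
  second-moment eigenvalues and anisotropy, bounding box, extent,
  compactness, perimeter-to-area ratio);
* **local structure (14)** — bond orientational order parameters
  ψ_n = |⟨e^{inθ_k}⟩|, n = 2…12, over minimum-image angles to
  neighbour COMs, plus the first moment, raw second moment and
  standard deviation of the neighbour COM distance;
* **non-local shape (66) and non-local structure (42)** — the
  neighbour mean, maximum and minimum of each local feature.
  Orientation is excluded from aggregation (a plain average of a
  circular quantity is ill-defined), which makes the four groups
  total exactly 145.

Cells are neighbours when they share at least one first-order pixel
contact (edge contact; corner contact does not count — the same
convention as the boundary-pixel definition). All COM-based geometry
uses the minimum image; the ellipse is a direct least-squares conic
fit to the cell's boundary pixels (centred first, which makes
congruent pixel sets give bit-identical fits), with a fallback to the
second-central-moment equivalent ellipse for degenerate fits, flagged
in the output. Near-circular cells (e < 0.01) get orientation 0 by
convention since a circle has no major axis.

## Classification

Phenotype inference is a binary classification with a single-hidden-
layer perceptron whose hidden width equals the number of input
features, trained with ADAM (scikit-learn `MLPClassifier`; ReLU,
learning rate 10⁻³, at most 300 epochs — networks that hit the epoch
cap are kept and reported with a warning). Features are standardised
with train-set statistics only. Each snapshot is balanced by keeping
all minority-class cells and an equal-size uniform subsample of the
majority; balanced snapshots are concatenated to the target dataset
size, split 80/20 with stratification, and an ensemble of
independently seeded networks is trained; the reported accuracy is
the ensemble mean on the held-out test split. Confusion counts follow
the convention FN = active cell called passive, FP = passive cell
called active.

Seven feature subsets are compared (all, shape, local shape,
non-local shape, structure, local structure, non-local structure).
Feature importance is assessed three ways: the manual subsets, an
interventional Shapley-value explainer (exact coalition enumeration
for small inputs; Shapley-kernel-weighted constrained regression on
sampled coalitions otherwise, so additivity holds by construction;
an accompanying permutation-importance ranking serves as a quick
fallback), and PCA on the standardised matrix with retraining on the
components covering 95% of the variance.

## Reduced-scale protocol

The full study uses 120 000 balanced cells per condition and
20-network ensembles. The package's experiment driver
(`pottsml.experiments`) runs the same pipeline at a reduced scale
chosen for a single CPU: 3 000 MCS of equilibration (the reference
energy is stationary well before that; the configuration default is
10⁴), snapshots every 1 000 MCS as in the full study, 8–30 snapshots
per condition (≈ 300–1 800 balanced cells), and 5-network ensembles.
At this scale the headline accuracies are stable to a few hundredths
and reproduce the qualitative structure of the full study: accuracy
near 1 for a single active cell, ≈ 0.74 at N_a = 60, successful
γ = 0.2 → 0.1 transfer, and breakdown of γ = 0.4 → 0.1 transfer at
N_a = 30. `scripts/acceptance.py` recomputes these headline numbers
from scratch; tests run the same protocol at a further 0.7× snapshot
scale.

## What the generator does and does not emulate

The simulator produces confluent monolayers whose only phenotypic
difference is the motility strength κ: shape differences between the
classes are *emergent*, not injected, which is exactly what makes the
classification question non-trivial. It does not model cell division
or death, chemotaxis, size or stiffness heterogeneity, nuclei, 3-D
effects, or imaging noise — so passing tests demonstrate that the
pipeline recovers motility from emergent morphology in this model
class, not that it would survive segmentation errors or biological
covariates in real histology.

## Numerical choices and edge cases

* Incremental ΔH equals global recomputation to < 10⁻⁹ (tested over
  ≥ 1 000 randomized moves), and bookkeeping (A, P, COM) matches
  from-scratch values exactly after arbitrary runs.
* Single-pixel cells cannot lose their last pixel (moves rejected);
  the loser's bias term is skipped at area 1 (no COM is defined for
  an emptied cell).
* The minimum-image unwrap of a cell's pixel set assumes the cell
  spans less than half the lattice per axis; the perimeter penalty
  keeps cells far below that.
* Ellipse fits are rejected (moment fallback) when collapsed or
  implausibly large relative to the cell size.
* Datasets must have an even target size; the last snapshot is
  trimmed class-pairwise so balance is exact.
* γ = 1 layers (κ_a = κ_p) are the null calibration: phenotype labels
  are exchangeable, and the classifier scores at chance within the
  99% binomial CI.

## Known limitations

Accuracies at the reduced scale carry sampling noise of roughly
±0.02; the γ = 0.4 → 0.1 transfer sits intentionally near the 0.7
boundary, as in the full study, and is the most seed-sensitive
number. The Shapley explainer subsamples coalitions for the
145-feature input, so individual ranks beyond the top group are
noisy (the retraining check uses only the top-20 set). Simulation
wall time is dominated by boundary activity and rises with κ and the
number of motile cells.
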