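# Methods

## Model

Connectivity is modeled bilinearly in gene expression.  For presynaptic
cell (or type) *i* with feature vector `x_i ∈ R^p` and postsynaptic *j*
with `y_j ∈ R^q`, the predicted connectivity is `ẑ_ij = (x_i A)(y_j B)ᵀ`
with transforms `A ∈ R^{p×d}`, `B ∈ R^{q×d}` into a shared latent space of
dimension d.  The model assumes connectivity is determined (up to noise) by
a low-dimensional interaction between pre- and post-synaptic expression;
each latent dimension acts as one connectivity motif, and `Ô = ABᵀ` is the
implied gene–gene rule matrix of rank ≤ d.

**Cellwise regime.**  When expression and connectivity are observed on the
same cells the loss is

```
L(A,B) = Σ_ij w_ij (z_ij − (x_i A)(y_j B)ᵀ)² + (λ_A/2)‖A‖² + (λ_B/2)‖B‖²
```

Each squared residual is weighted once: with type-balance weights
`w = 1/(nᵢ nⱼ)` the data term is the average squared residual per type
pair, so abundant types do not dominate; a binary contact mask instead
restricts the fit to physically plausible pairs (zero weight removes a
pair entirely — its value never influences loss or gradients).  The
analytic gradients are `2 Xᵀ(W⊙(Ẑ−Z))YB + λ_A A` and its transpose-mirrored
counterpart for B.

**Typewise regime.**  When transcriptomic and connectomic data come from
different sources, cells cannot be matched across them — only types can.
The model then assumes each cell's latent features and connectivity sit
near its type mean.  Inputs are variance-normalized type means
`x̂_im = x̄_im/σ̂_m`, where `σ̂²_m` is the pooled within-type variance of
feature m (sum over types of the population within-type variance), and the
loss penalizes the factor Gram matrices,

```
L(Â,B̂) = ‖Z̄ − X̂Â(ŶB̂)ᵀ‖² + (λ_A/2)‖ÂᵀÂ‖² + (λ_B/2)‖B̂ᵀB̂‖²
```

which is the penalized surrogate of constraining within-type latent
scatter; the constrained ϵ-form is never exposed as a runtime parameter.
The B̂-side data gradient uses the transposed residual (the only
dimensionally consistent form) and both penalty gradients carry the factor
2 of the true derivative, so analytic gradients match finite differences.

## Optimization

Both regimes are fit by alternating gradient descent: factors are
initialized from a seeded standard normal; per iteration the prediction
`Ẑ = XA(YB)ᵀ` is computed once, both gradients are evaluated there, and A
is updated before B.  The loop stops when the absolute loss change falls
below `tol` (default 1e-6) or at `max_iter` (default 1e6); a non-finite
loss raises an explicit divergence error.  The fit is a pure function of
(data, config): identical seeds give bitwise-identical trajectories.

**Step size.**  The loss is quartic in (A, B) jointly, and a fixed
learning rate is fragile: steps that converge on one problem scale diverge
or crawl on another (the typewise feature scale varies with 1/σ̂).  The
default step policy is therefore an exact line search per factor update:
with the other factor held fixed, the loss along `A − t·g_A` is a quadratic
in t (plus quartic terms from the Gram penalty), whose coefficients are
available in closed form and whose nonnegative minimizer is found from the
derivative's roots.  This preserves the update directions, their order, and
determinism, guarantees monotone descent, and removes the learning rate
from the list of quantities that must be tuned per dataset.  A fixed-rate
mode (`FitConfig(adaptive=False)`) retains the textbook update for studies
of the raw dynamics; it is the mode used by the monotone-descent test's
halving schedule.

Factors are identifiable only up to an invertible d×d transform (sign
flips and column permutations in particular), so recovery is always
assessed on predictions or on the product `ABᵀ`, and the run-consistency
score maximizes mean absolute cosine similarity over column pairings
(all d! pairings for d ≤ 4, greedy matching beyond).

## SCM baseline and rule comparison

The spatial connectome model predicts `X O Xᵀ` with a full gene–gene rule
matrix O, fit by ridge regression of observed connectivity on Kronecker
rows `x_i ⊗ x_j` over contacting pairs.  Gap junctions are undirected, so
O is constrained symmetric by averaging `(x_i⊗x_j + x_j⊗x_i)/2` and
counting each unordered pair once.  The normal equations are solved
directly for p² ≤ 2,500 and by LSQR (tolerance 1e-10) beyond; at λ = 0 a
rank-deficient system raises an error pointing to λ > 0.  With d = p and
vanishing ridge the bilinear model can represent any rule, and the two
fits coincide (this is tested numerically).  Rules are compared entrywise
with the discrepancy score `DS(ô,o) = |ô−o|/(|ô|+|o|) ∈ [0,1]`, defining
DS(0,0) = 0 as the no-discrepancy limit; entries are flagged when
DS ≥ 0.5 unless both magnitudes are below 0.1 (regularization shrinks
unimportant coefficients, making small-value disagreement uninformative).

## Preprocessing

Counts are scaled per cell to the median library size and log(1+x)
transformed (log1p handles the zeros of sparse counts).  Highly variable
genes are those whose standardized residual from a log-log regression of
CV² on mean expression exceeds a threshold (default z = 1).  PCA retains
the smallest number of components reaching 95% cumulative explained
variance.  Type means and the pooled within-type variance then give the
normalized type matrices.  The pooled variance uses the population divisor
nᵢ and sums across types, exactly as the type-level model's derivation
requires; a floor of 1e-8 guards zero-variance features.  Transcriptomic
and connectomic type names are aligned only through an explicit
user-supplied mapping table — never by fuzzy string matching.  Each
neuronal class (e.g. bipolar cells vs ganglion cells) runs through its own
pipeline instance.

## Connectivity construction

For retina-style data, a cell pair's connectivity proxy is the cosine
similarity of their stratification profiles (voxel-volume density vs
normalized IPL depth, resampled by linear interpolation onto a common
120-point grid on [0, 1]).  Cosine of nonnegative profiles lies in [0, 1],
so the cell matrix is standardized (mean 0, SD 1) to admit both signs and
then averaged within type pairs; this order — standardize, then average —
is fixed in the pipeline and exposed as a switch.  ON/OFF starburst
amacrine laminae (depths 0.28/0.62) and the outer/inner IPL boundary
(0.47) are reporting landmarks only.  For *C. elegans*-style data the
binary contact mask is used directly as the loss weight matrix.

## Cross-validation

Hyperparameters (λ, d) are chosen by five-fold cross-validation at the
level of observed connectivity entries: contact pairs in the cellwise
regime, all type pairs in the typewise regime.  Entries are shuffled by a
seed and partitioned; held-out entries get weight zero during fitting, and
the validation loss is the unregularized weighted data term on the held-out
entries (penalties are training-only).  The selected pair minimizes the
mean validation loss, ties broken toward smaller d then smaller λ.  Default
grids: λ ∈ {0.01, 0.1, 1, 10, 100}, d ∈ {1..5}.

## Synthetic data

`generate_bilinear_instance` draws type-mean features from a standard
normal, adds within-type Gaussian scatter to cells, draws true factors
A*, B* from a standard normal, sets `Z = XA*(YB*)ᵀ` plus Gaussian noise,
and produces either a Bernoulli contact mask or type-balance weights.  The
default scenario mirrors the retina problem's shape — 25 presynaptic × 12
postsynaptic types, 10 cells per type, 30 features per side, d_true = 2,
within-type and connectivity noise SD 0.05.  `generate_count_instance`
plants highly variable genes via per-type log-normal programs on a Poisson
background with uniform library-size variation; `generate_stratification_
profiles` emits Gaussian-bump museum-style JSON records with per-cell
center/width jitter.  All generators are pure functions of their seed.

Because the generated connectivity is already signed, the synthetic
type-level recovery harness averages cell connectivity by type without the
standardization step; standardizing would add a rank-one constant offset
that a rank-2 model cannot absorb and that real (cosine-valued) data
needs but synthetic data does not.

The cross-validated dimension-selection experiment uses within-type
expression scatter of SD 0.5, commensurate with the unit between-type
separation.  This is the regime real single-cell data occupies — within-
type dispersion comparable to type distances — and it keeps the
variance-normalized features at order one.  With near-zero scatter the
1/σ̂ normalization inflates features several-fold and the experiment
measures optimizer conditioning rather than model selection.

**What these experiments do not show.**  The generators draw i.i.d.
Gaussian features, so they exercise recovery, selection and equivalence
under the model's own assumptions; they do not emulate dropout curves,
ambient RNA, batch effects, correlated gene programs, or connectivity not
expressible bilinearly.  Passing synthetic recovery therefore validates
the machinery, not the biological adequacy of the bilinear hypothesis on
any particular dataset.

## Numerical choices and degenerate inputs

- Convergence is judged on absolute loss change; tol and max_iter are
  configurable (defaults 1e-6 and 1e6).
- λ_A = λ_B by default (a single consolidated λ), with both exposed for
  unequal regularization.
- ROC-AUC uses the rank equivalence AUC = P(s₊ > s₋) + ½P(s₊ = s₋); masked
  evaluation restricts to entries with positive weight, and single-class
  truth raises rather than returning a conventional value.
- Zero-variance inputs raise (standardization, Pearson) rather than
  silently producing NaN; zero-norm stratification profiles name the
  offending cell.
- Partner prediction requires new types to be processed through the
  training feature basis; a dimension mismatch raises a provenance error
  rather than silently projecting.
- Latent-coordinate "positive half" grouping assigns zero coordinates to
  the positive side.
- Top-gene tables default to 50 genes per (dimension, side, sign); partner
  predictions default to the top 3, ties broken by partner label order.

## Problem sizes

The test suite and the acceptance script run desk-scale problems: gradient
checks on ≤ 10-feature instances, recovery on the 25×12-type default
scenario, dimension selection on a 12×8-type scenario over a d ∈ {1..4}
grid with 10 repetitions, and SCM equivalence on 12 neurons × 4 genes.
These sizes were chosen so the full suite completes in minutes while every
matrix dimension (types vs cells vs features) is exercised asymmetrically.
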