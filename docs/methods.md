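# Methods

This note records the statistical model, the algorithmic and numerical
choices, and the limits of what the test suite demonstrates.

## Model and parametrization

Tip traits follow a stationary-root OU model on a rooted ultrametric tree
of depth T: covariance Σ_ij = σ² e^(−α d_ij)/(2α) for α > 0, and the
Brownian-motion limit Σ_ij = σ² t_ij at α = 0 (t_ij the shared time,
d_ij the patristic distance; on ultrametric trees d_ij = 2(T − t_ij)).
Optimum shifts Δθ_b at the start of branch b enter the tip means as
effects β_b = (1 − e^(−α t_start(b))) Δθ_b on the binary clade-incidence
design, so selection operates on β and never needs α-dependent columns.
The root state is folded into the intercept β₀; consequently a root-edge
shift is unidentifiable and the candidate set is the 2n − 2 non-root
branches. The root's two child branches remain individually valid
candidates but are jointly collinear with the intercept; the selection
criteria handle that (a model containing both is scored +∞).

Branch ids are assigned by postorder of the child-sorted tree (children
ordered by the smallest tip label in their clade), so rankings and
reports are reproducible across parsers and input rotations. Tip ages
are snapped to exactly zero after the ultrametricity check (default
tolerance 10⁻⁶ · T) so the d = 2(T − t) identity is exact.

## Identifiability and surrogates

Distinct branch sets can induce identical or nearly identical tip-mean
contrasts ("surrogates"): the root children are mutual surrogates modulo
the intercept, a branch and its only-sampled child differ by tips absent
from a subsample, and equal shifts on clades that tile all tips collapse
into an intercept change. Three consequences shape the package:

* TP/FP counting is exact on branch ids (no surrogate credit); the ARI on
  induced tip regimes and predictive log-likelihood are reported alongside
  because they do grant surrogates credit. `surrogate_branches` lists
  exact-duplicate incidence columns as a diagnostic.
* Stepwise selection *skips* non-improving candidates rather than stopping
  at the first one: a surrogate of an already-selected shift can never
  improve the score, and halting there would discard every lower-ranked
  true shift.
* The synthetic-scenario shift placer never returns clades covering all
  tips, which would be an undetectable pure-intercept configuration.

## Ensemble ranking

Defaults: 100 subsamples of fraction 0.5 of the taxa, sampled without
replacement (subsample sizes are not prescribed anywhere authoritative;
these are standard ensemble-selection values and are configurable).
Subsampling happens on taxa *before* whitening — whitened rows are not
exchangeable — and the covariance is subset and re-factorized per
subsample. Branch columns constant within a subsample are dropped there
and treated as never-entered. The LASSO path is computed by LARS
(scikit-learn `lars_path`) on the whitened design with the whitened
intercept projected out; entry penalties are reported on the
½‖r‖² + λ‖β‖₁ scale. A variable entering, leaving and re-entering gets
the maximum λ over its active intervals. Ranks use average-tie
convention (all never-entered variables share the worst average rank);
the aggregate is the linearly interpolated first quartile by default
(median, arithmetic and geometric mean available), with ties in the
aggregate broken by branch id.

## Selection criteria

BIC: −2 loglik + (2k + 3) log n, counting each shift's position and
magnitude plus (β₀, α, σ).

pBIC: −2 loglik + 2k log(2n − 3) + 2 log n + log det(X_Mᵀ v Σ⁻¹ X_M),
where X_M is the intercept plus the selected binary incidence columns and
v is the scalar sample variance of the observed traits, acting as the
prior scale of the magnitudes. Two deliberate readings of
under-specified elements:

* **v** is a scalar (the sample variance of Y), multiplying the Gram
  matrix — the literal reading of "observed trait variance".
* **Design columns are binary**, i.e. the determinant is the Fisher
  information of the tip-level effects β_b. The alternative α-scaled
  columns (1 − e^(−α t_start(b)), the information of Δθ_b) degenerate:
  for short external branches the scaled column tends to zero, the log
  determinant to −∞, and the criterion would *reward* adding junk
  tip-branch shifts without bound — the opposite of pBIC's intended
  conservatism. The scaled form is retained behind a `scaled_design`
  flag for diagnostic use only.
* At k = 0 the determinant term uses the intercept column alone.

Stepwise moves require strict score improvement; ties keep the smaller
model. During a stepwise pass (α, σ²) are held fixed with σ² profiled per
candidate from whitened residuals (ML: RSS/n); full (α, σ²) re-estimation
happens only between outer-loop rounds. The outer loop starts at α = 0,
re-selects at each refit α̂, stops when the selected set repeats or after
`max_iter` = 10 rounds, and returns the criterion-best iterate (the α
trajectory and a convergence flag are always reported; non-convergence
does occur, notably on mis-specified trees).

α̂ maximizes the profile likelihood by bounded scalar search on
log α ∈ [log 10⁻⁴, log 10²] (the same span as the mis-estimation grid)
with relative tolerance 10⁻⁴; boundary values are compared explicitly, so
degenerate data return a boundary α with a warning rather than failing.
This is a deliberately crude estimator (matching the methods it
emulates); on 100-taxon trees with the generating α = 1 the median α̂
over replicates falls within [0.5, 2] on pure-birth and balanced trees,
with a larger upward bias on coalescent trees, whose short deep
internodes carry little information about α.

## Numerical choices

* Whitening is by the inverse lower Cholesky factor — deterministic,
  O(n³/3); any valid inverse square root gives identical GLS/LASSO
  results (tested against the eigendecomposition whitener).
* For small α the factorization is computed on the unit-diagonal
  correlation e^(−α d) and rescaled by 1/√(2α) analytically; otherwise
  the 1/(2α) offset dwarfs entry differences and Cholesky fails. A tiny
  escalating relative ridge (≤ 10⁻⁸) guards the PD boundary (zero-length
  cherries). The BM branch always carries a 10⁻⁸·tr(Σ)/n ridge.
* Exact interpolation (RSS = 0) yields a degenerate density; the fit
  reports σ̂² = 0 and +∞ log-likelihood rather than crashing.
* Rank-deficient candidate designs are detected via least-squares rank
  and scored +∞ (library calls) or raised with the collinear pair named
  (direct `gls_fit` calls).

## Simulation machinery

Tree shapes, all rescaled to depth 1: complete balanced (equal level
lengths), caterpillar (internal nodes evenly spaced in age), pure-birth
(dendropy, unit birth rate) and Kingman coalescent (msprime, ploidy 1).
Only relative branch proportions matter after rescaling, so the unit
rates are immaterial. Scenario grids are module constants: shift
magnitudes {0.2, 1, 1.5, 2, 2.5, 3, 5, 7, 10} (one β shared by all
shifts in a scenario), shift counts {3, 7, 12}, α = 1 and σ² = 2 (so the
stationary variance is 1), variance-shift levels {2, 4, 6, 8, 11} against
baseline 1, branch-length perturbation scales {1/30, 1/10, 1/5}, and the
fixed-α̂ mis-estimation grid {10⁻⁴, …, 10²}. Default replicate counts are
200 training and 1000 test sets; per-replicate seeds derive from the
scenario seed via `SeedSequence(seed, spawn_key=(stream, index))`, making
any single replicate bitwise reproducible in isolation.

Mis-specification mechanisms:

* **Measurement error** — additive N(0, σ_e²) per tip; σ_e is free
  (`measurement_sd`), as no canonical grid exists.
* **Wrong branch lengths** — each internal branch redrawn in preorder
  from a gamma with mean equal to its original length (shape = ℓ/scale);
  a draw pushing the branch past the tree depth is redrawn, implemented
  exactly as inverse-CDF sampling of the truncated gamma so arbitrarily
  small admissible intervals cannot stall. External branches then restore
  the exact original depth. Note the depth cap necessarily biases deep
  internal branches' means downward; mean preservation holds where the
  cap rarely binds (root-adjacent branches), and the mean-preservation
  test is phrased accordingly.
* **Variance shift** — one branch and all its descendants switch to a
  local σ²; simulation is branch-by-branch with exact OU transition
  moments (mean decay e^(−αℓ), variance σ²_loc(1 − e^(−2αℓ))/(2α)), the
  root drawn from the stationary law of its regime. Requires α > 0; with
  the local variance equal to the global one it reproduces the
  closed-form covariance (tested by Monte Carlo).

The generator emulates OU-distributed tip traits under these mechanisms
only. It does not emulate topology error (no meaningful "true shift" on a
wrong topology), non-ultrametric or dated-tip trees, multivariate traits,
branch-specific α, or phylogenetic signal in measurement error — so green
tests certify behavior under the stated model family, not robustness on
arbitrary empirical data.

## Evaluation instruments

TP = |true ∩ detected|, FP = |detected \ true| on exact branch ids.
Regimes label each tip by the most tip-ward shift on its root path (root
regime otherwise); the ARI between regime partitions is the standard
Hubert–Arabie form (delegated to scikit-learn; the test suite carries an
independent O(n²) pair-counting oracle). Predictive log-likelihood refits
(β, α, σ²) on the training replicate given only the selected branch set
and reports the arithmetic mean of per-replicate log densities over the
test set; an alternative policy refits magnitudes on an error-free copy
of the training data for the measurement-error study. Refit failure
scores −∞ with a warning.

## Problem sizes used in the shipped checks

The distributed test suite and acceptance script run reduced designs
chosen to keep the full run in the tens of minutes on one core:
50 detection replicates (acceptance script) and 15 (suite) for the
7-shift β = 2 conservatism scenario on a synthetic 100-taxon pure-birth
stand-in tree; 10–15 replicates for null-specificity and
criterion-ordering comparisons; 30–50 replicates for α recovery;
2000-replicate Monte Carlo for covariance/Kingman checks. The stand-in
tree is synthetic: the empirical 100-taxon Anolis tree used by the
comparison literature is not redistributed here, and conclusions on it
are directional only.

## Known limitations

* pBIC's calibration here reflects the formula as printed plus the two
  documented readings; measured null specificity (≈ 65–77 % empty
  selections on 50-taxon null data at the true α, never more than 3
  branches) is the package's own property, and the pBIC ≤ BIC
  conservatism ordering is what the tests pin down.
* The crude outer α loop can oscillate (reported, not hidden); fixed-α
  runs are first-class for sensitivity analysis.
* Detection of variance shifts, Bayesian treatments, bootstrap support
  and multivariate traits are out of scope.
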