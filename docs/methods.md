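# Methods

## Model

Two blocks on the same N samples are decomposed as

```
X = T Wᵀ + T⊥ P⊥ᵀ + E,     Y = U Cᵀ + U⊥ Q⊥ᵀ + F,
U = T B_T + H,             T = U B_U + H̃,
```

with K joint components (scores `T`, `U`; unit-norm loadings `W`, `C`), Kx
X-orthogonal and Ky Y-orthogonal components (scores `T⊥`, `U⊥`; loadings
`P⊥`, `Q⊥`), and residuals `E`, `F`. "Orthogonal" means unrelated to the
other block, not geometrically orthogonal to the joint loadings. `B_T`,
`B_U` are diagonal: components are extracted sequentially and linked
pairwise by least squares, which keeps cross-block prediction well defined
for every K.

## Estimation

1. **Centering.** Columns of both blocks are mean-centered (optionally
   scaled to unit variance). Covariance maximisation is meaningless on
   uncentered data. Constants are stored for projecting new samples.
2. **Initial joint fit.** `K + max(Kx, Ky)` unpenalised NIPALS components
   are extracted from the centered data. The extra components are needed so
   the joint-score matrix has enough directions for the next step: with only
   K of them, the cross-product below would have rank K and could never
   yield more than K orthogonal components (the glycomics-style setting
   K = 1, Ky = 3 would be infeasible).
3. **Orthogonal estimation.** For the X side, `E₀ = X − T₀W₀ᵀ`; the
   orthogonal basis `Worth` is the first Kx left singular vectors of
   `E₀ᵀT₀` — directions of X-structure entangled with the joint scores that
   Y cannot explain. Scores `T⊥ = X·Worth`, loadings `P⊥` by regression of X
   on `T⊥`. Symmetrically for Y. Estimation happens once, up front, not
   interleaved per joint component: the iteration count stays deterministic
   and each step is independently testable. Orthogonal estimation is never
   penalised; sparsity is a property of the joint subspace only.
4. **Filtering.** `X̃ = (I − T⊥(T⊥ᵀT⊥)⁻¹T⊥ᵀ)X`, likewise `Ỹ`.
5. **Penalised joint fit.** For k = 1…K on the filtered, deflated blocks:
   one NIPALS pair with thresholding (below); the loading pair is then
   orthogonalised against the previous k−1 loadings restricted to its
   selected-variable support (if no previous loading touches the support,
   nothing happens); scores are recomputed; both blocks are deflated by
   regressing their score out. Deflation on scores guarantees mutually
   orthogonal score columns.
6. **Inner relation.** `B_T[k,k] = tₖᵀuₖ / tₖᵀtₖ`, and symmetrically.

### Penalised NIPALS

Each iteration updates `c ∝ thresh(Ỹᵀt)`, `u = Ỹc`, `w ∝ thresh(X̃ᵀu)`,
`t = X̃w`. The threshold is the identity (no penalty), the soft-thresholding
operator `S(a, λ) = sgn(a)(|a| − λ)₊` (L1), or the group-wise operator that
scales each group's sub-vector by `(1 − √p_j·λ/‖a^(j)‖₂)₊` and renormalises
(the Lagrange constant of the unit-norm constraint is absorbed by the
renormalisation). A group survives iff `‖a^(j)‖₂ > √p_j·λ`; the `√p_j`
adjustment stops large groups from being selected merely for being large.
The sparse mode is implemented as the all-singleton group mode, which makes
the sparse/group reduction identity exact by construction.

When the user requests a *count* `h` of groups instead of a penalty level,
λ is recomputed each iteration as the midpoint between the h-th and
(h+1)-th largest size-adjusted group norms, so exactly h groups survive at
convergence. Exact ties at the boundary keep all tied groups (logged) rather
than dropping one by floating-point accident.

### Numerical choices

* Convergence: max loading change below `tol = 1e-10` after sign alignment;
  `max_iter = 1000`. Non-convergence is a logged warning with the flag
  recorded per component, not an error — loadings, not iteration counts, are
  the reported quantities.
* Initialisation is deterministic (the Ỹ column with the largest variance)
  so repeated runs and CLI reruns are bit-identical; a seeded random
  initialisation is available.
* Sign convention: every loading vector is flipped so its largest-magnitude
  entry is positive. Power iterations determine loadings only up to sign;
  without the convention no two runs would be comparable. A consequence is
  that `B_T` entries may be negative.
* Scores satisfy `T = X̃ · W(PᵀW)⁻¹` exactly, where `P` collects the
  per-component regression loadings of the deflated blocks. `transform`
  applies this rotation (after filtering new data with the *training*
  orthogonal basis — test structure is never re-estimated), so transforming
  the training data reproduces the stored scores to machine precision.
  Applying `W` alone would not: deflation makes the k-th score a function of
  the deflated, not the original, filtered matrix. The two coincide at K = 1.
* If the cross-covariance is numerically exhausted before the requested
  number of components (exactly low-rank input), the initial fit stops early
  and the final fit raises — the data cannot support the requested K.
* Variance bookkeeping: with the definitions above the joint, orthogonal and
  residual sums of squares decompose the total exactly, so the reported
  fractions sum to one (asserted at 1e-8).

## Cross-validation

Folds are a seeded permutation cut into equal parts — a pure function of
(N, folds, seed). Three procedures:

* **Orthogonal counts (Kx, Ky)**, K fixed: per cell, the held-out error of
  predicting U from T and T from U through the fitted inner relation, each
  normalised by the held-out score variance (cells with different filtering
  otherwise live on different scales); minimised.
* **Joint count K**, (Kx, Ky) fixed: held-out MSE(X→Y) + MSE(Y→X);
  walked in increasing K with a two-increase patience rule (early stop
  logged; full grid on request).
* **Sparsity (h_x, h_y)**: the summed empirical covariance of held-out
  joint score pairs (training loadings, training orthogonal filter);
  maximised. Covariances are summed over components, not averaged, to keep
  the per-fold bookkeeping simple; any monotone variant selects identically.
  Whether to evaluate the covariance held-out or in-fold is a genuinely open
  choice; held-out is standard CV logic and is what is implemented.

All three report both the plain optimiser and the one-standard-error choice
(the sparsest / smallest model within one SE of the optimum). For component
counts the criterion surface is typically steep up to the true value and
then flat; the plain argmin walks into the flat region on sampling noise,
while the one-SE rule recovers the generating (K, Kx, Ky) reliably — the CV
tests select with it. Infeasible cells (rank constraints, over-penalisation)
are marked invalid, logged and excluded. A near-flat criterion across the
whole grid triggers a logged warning (spread below 1% of the mean — a
heuristic; structureless data does not always trigger it because
inner-relation coefficients overfit noise folds and move cell means apart).

## Synthetic designs

Both generators are deterministic in (design, seed); experiment replicate r
uses a sub-seed derived from (seed, r), so serial and parallel execution
agree.

**Design 1 — group selection with one joint component.** Defaults: N = 30,
p = 5000, q = 20. X carries five relevant groups of sizes 100/50/20/5/1 with
loading value 1, five "strong" groups of size 10 with value 5 (these make
the weak groups harder to find), remaining features with zero loadings in
filler groups of size 10. All Y features load equally (1/√q, a unit-norm
loading — the scale is irrelevant to every method under test). A single
standard-normal score drives both blocks (U = T, correlation one). Gaussian
noise is calibrated so Var(E)/Var(X) equals α in expectation (the
population signal variance per element is known in closed form, so the
calibration needs no simulation).

**Design 2 — the imbalanced case-control shape.** Defaults: p = 20000,
q = 10000, 1000 equal groups per block, K = 2, Kx = Ky = 1, N = 30. Per
joint component, 50 relevant groups (disjoint between components) carry
within-group-constant loadings 1…50; that is 1000 relevant X features and
500 relevant Y features per component. Scores are zero-mean normal with
σ²_T = 1; U = T + H with Var(H)/Var(U) = 0.2; orthogonal score variance is
`orth_ratio`·σ² of the corresponding joint scores. Joint loadings are used
as printed (not normalised); the noise calibration absorbs the overall
scale. The orthogonal loadings are *group-structured like the joint ones*
(a random set of 50 groups with shuffled values 1…50, scaled to the mean
joint column norm): block-specific variation in omics data — batch effects,
cell-type composition — hits feature modules, not isolated features. This
matters: with dense Gaussian orthogonal loadings a group penalty can evade
the contamination almost entirely and the flat penalised methods match their
orthogonal-aware counterparts, which is neither realistic nor the documented
behaviour of the family. All dimensions scale down for desk-size tests.

**Exact (noise-free) design.** For parameter-recovery checks,
`simulate_exact` builds data satisfying the decomposition *exactly*:
orthonormal loading columns, sample-orthogonal mean-zero scores (so
centering is a no-op and the cross-covariance SVD is unperturbed), distinct
score strengths (separated singular values make the loadings identifiable —
with equal strengths only the joint *subspace* is identified and no
estimator could return the individual vectors), and H = 0. A correct
implementation must recover W, C, T, U essentially to machine precision;
the tests require three nines.

What the generators do *not* emulate: non-Gaussian margins, heteroscedastic
platform noise, count-data mean-variance coupling, correlated noise within
groups, overlapping groups, and sample structure (batches, relatedness).
Passing tests therefore show correctness of the algorithms and their
documented comparative behaviour under the stated designs, not performance
guarantees on real omics data.

## Metrics

Fitted components are greedily matched to true components by largest
|cosine| of X-loadings and sign-aligned first. Joint-score accuracy is the
pooled R² of regressing the true scores on the estimates (`R²_T̂T`), and of
regressing Û on T̂ (`R²_T̂Û`); score scales are arbitrary per method, so the
regression form (equivalently, squared correlation) is the scale-free
reading of these quantities. TPR = TP/(TP+FN) over truly relevant features;
for dense methods (PLS, O2PLS) a selection rule is required, and the least
arbitrary is taking the top-m features by |loading| with m the true support
size. Loading accuracy is the per-component cosine `WᵀŴ`. Group importance
`‖X^(j)ᵀU‖₂/√p_j` is reported per group; it is exactly the quantity the
selection condition compares against λ, and it is invariant under
duplicating a group's features.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full pipelines at desk
scale, chosen so the whole suite completes in minutes on one core: design 1
at p = 500 with relevant sizes 50/25/10/5/1 and 200 replicates per noise
level; design 2 at p = 2000, q = 1000, 100 groups, 100 replicates, 200
held-out samples; CV recovery on 50 datasets at p = 600, q = 400, N = 100.
The qualitative findings these sizes reproduce — selection robustness
growing with group size, TPR(GO2PLS) ≥ TPR(SO2PLS), orthogonal-aware methods
beating flat ones when specific variation is strong, CV recovering the
generating component numbers — are size-stable; the full-size designs are
available through the same API and the `simulate` CLI.

## Known limitations

* Two blocks only; no outcome-supervised variant; no probabilistic version.
* Groups must partition the features (no overlap); unmapped features become
  singletons.
* The orthogonal-estimation recipe re-estimates the joint loadings once
  after filtering; no outer iteration between joint and orthogonal parts.
* Whether λ should differ per component is unsettled; per-component `keep`
  values are accepted, constant by default.
* Group-penalised solutions with `keep` may return more groups than
  requested under exact ties (logged, never silently resolved).
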