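# Methods

## Problem and model

A protein is represented by four feature views computed from its amino-acid
sequence and its PSI-BLAST profile (PSSM), each view is turned into a
Gaussian kernel, the kernels are combined by ideal-kernel alignment, and a
fuzzy kernel ridge regression (FKRR) separates DNA-binding (+1) from
non-binding (−1) proteins. The model is intercept-free: the decision value
of a test protein x is `k(x)ᵀα` with `α = (K* + (1/C)D⁻²)⁻¹ y`, and the
label is its sign (ties map to +1 for determinism).

## Feature extractors

**MCD** (882-d). Residues are mapped to seven physicochemical groups
({A,G,V}=1, {C}=2, {D,E}=3, {F,I,L,P}=4, {H,N,Q,W}=5, {K,R}=6,
{M,S,T,Y}=7 — the digit assignment is pinned by the descriptor's reference
encoding `AVDCALSK → 11321476`). The encoded sequence is split into 4
equal parts (remainder to the leftmost parts), and statistics are computed
on 14 regions: the 10 contiguous part spans
{1, 2, 3, 4, 12, 23, 34, 123, 234, 1234} plus the 4 discontinuous unions
{1∪3, 2∪4, 1∪4, 1∪2∪4} (`MCD_REGIONS`, a single named constant, so the
scheme can be swapped). Per region: 7 composition frequencies, 21
unordered adjacent-distinct-pair transition frequencies over (m−1), and
5 distribution quantiles (first, 25%, 50%, 75%, last occurrence position
as a fraction of region length; 0 when the group is absent) × 7 groups —
63 features, 63·14 = 882 total. Minimum sequence length 8 (two residues
per quarter keeps every transition denominator positive). The region
scheme is the one genuinely open design choice here: descriptions of this
descriptor disagree on "10 regions" versus the 882-width, and only a
14-region scheme is consistent with 63 features per region; we chose the
documented mixed continuous/discontinuous set and froze it.

**NMBAC** (6·lg-d, default lg=10 → 60). The six residue properties
(hydrophobicity, side-chain volume, polarity, polarizability, SASA, net
charge index; 20×6 table stored verbatim in `features.py`) are each
standardized to zero mean and unit population SD over the 20 amino acids —
the descriptor is *normalized* autocorrelation, and the raw property
scales differ by orders of magnitude. Entry (j, lag) is
`(1/(n−lag)) Σ_i X[i,j]·X[i+lag,j]`; ordering is property-major. lg=10 is
a conventional choice; any value < min sequence length works.

**PSSM-AB** (400-d). Profile rows are cut into 20 consecutive blocks,
block i covering rows ⌊(i−1)L/20⌋..⌊iL/20⌋−1 (equal blocks when 20 | L),
and each of the 20 columns is averaged per block; feature index
k = j + 20(i−1). Raw log-odds values are used — no squashing.

**PsePSSM** (20+20·lag_max-d, default lag_max=15 → 320). Each profile
*row* is standardized over its 20 entries (row-wise as the defining
formula prints it, although column-wise is the more common convention
elsewhere; rows with zero spread standardize to all-zeros, never NaN).
First 20 features: column means of the standardized profile; feature
20 + j + 20(lag−1): mean squared lag-difference of column j.

All four orderings (region-major, property-major, block-major, lag-major)
are frozen; changing them breaks serialized feature tables.

PSSM input is the *first* 20-column block of PSI-BLAST's ASCII output (the
log-odds scores, not the percentages), remapped to the canonical column
order `ARNDCQEGHILKMFPSTWYV`. Non-canonical residues (B, Z, X, U, O, J)
are rejected by default; an opt-in policy masks them to X and drops those
positions, since silently coercing them would corrupt group encodings and
property lookups.

## Kernels and multiple-kernel learning

Per view, `K_ij = exp(−γ‖x_i−x_j‖²)`. No per-view γ is prescribed by the
method itself, so the default is the median heuristic γ = 1/median of
pairwise squared distances (seeded subsample above 500 rows); features
enter as extracted, with standardization available as an option. Kernel
weights solve

    min_ω ‖Σ_h ω_h K_h − yyᵀ‖²_F + λ‖ω‖²,  ω on the simplex.

Expanding gives a QP with Gram matrix M_hk = ⟨K_h,K_k⟩_F and linear term
b_h = yᵀK_h y. With H = 4 the QP is solved *exactly* by enumerating the 15
support patterns, solving the equality-constrained KKT system on each and
keeping the feasible minimum — deterministic, no tolerance tuning, and
testably optimal against grid search. Kernels are not centered before
alignment. Since ⟨K_h,K_k⟩_F grows like N², the default λ=1 is interpreted
in those units (multiplied by mean_h⟨K_h,K_h⟩_F); `scale_lambda=False`
uses λ verbatim.

## Memberships and the fuzzy fit

Membership scores are computed once on the MKL-combined training kernel:
`score_t = (1/N²)(Σ_{same class} K*(t,i) − Σ_{other class} K*(t,i))`, the
self-term included in the same-class sum (the defining sum carries no
i≠t restriction). Memberships are the logistic `D_tt = 1/(1+e^{−score})`.
Because raw scores scale like O(1/N), memberships crowd toward 0.5 as N
grows; the default follows the formula verbatim, and an opt-in
`standardize_scores` switch z-scores before the sigmoid when spread
matters more than fidelity. `α` solves `(K* + (1/C)D⁻²)α = y` by a
symmetric factorization with a residual diagnostic (< 1e−6·‖y‖ enforced);
the matrix inverse in the closed form is never formed explicitly.

Defaults: C = 1 (the standard ridge default; no value is prescribed by the
method), λ = 1 as above. A per-fold hyperparameter search is deliberately
*not* the default: the evaluation protocol fixes hyperparameters before
the jackknife, and C, λ, per-view γ are all exposed in the library, the
CLI and the config file for explicit sweeps.

## Evaluation

ACC, SN, SP and MCC are written in class-total/error-count form
(N⁺, N⁻, N⁺⁻ false positives, N⁻⁺ false negatives); that MCC
parameterization is algebraically identical to the usual TP/TN/FP/FN
formula, verified exhaustively for all tables with class sizes ≤ 12.
Undefined metrics (zero denominators) are flagged by name, never silently
NaN. AUC uses the Mann–Whitney rank statistic with average ranks, so ties
contribute ½. The jackknife retrains *everything* per fold — bandwidths,
MKL weights, memberships, the fit — which is the leakage-free reading of
leave-one-out; per-fold cost is O(N³) at H=4, ~0.5 s for N=60 over all
folds.

## Synthetic data

The generator emulates the *shape* of real inputs, not their biology:
class +1 draws residues from a fixed 10-residue pool with probability
(1+shift)/20 each, class −1 from the complement; lengths are uniform on
[50, 120]; the profile row of an observed residue gets a base log-odds of
+5 at its own column plus rounded Gaussian noise (sd 2) everywhere, clipped
to [−10, 10] — magnitudes typical of real log-odds profiles. At shift=1
the residue pools are disjoint (maximal compositional separation); at
shift=0 the classes are exchangeable. All randomness flows through one
`numpy.random.Generator` seeded from the spec. What passing tests show:
the pipeline recovers a strong compositional signal and does not
hallucinate one from noise. What they do not show: performance on real
proteins, whose class signal is far subtler than a composition shift and
whose profiles carry homology structure the generator does not model.
Benchmark-scale accuracy claims therefore cannot be checked here; they
require the curated datasets and database-searched profiles themselves.

Fixture specs (n=30/class): easy shift=1.0 seed=11, medium shift=0.4
seed=12, null shift=0.0 seed=13 — fixed once at module creation and reused
everywhere, including the end-to-end tests.

## Known limitations

* **Leave-one-out anti-bias on null data.** The classifier has no
  intercept, so on signal-free data the decision value correlates with the
  training-label mean; under leave-one-out, holding out sample t makes t's
  class the training minority, biasing jackknife accuracy *below* chance
  (observed ≈0.23–0.55 across seeds at N=60, mean ≈0.39, vs the binomial
  chance band 0.5±0.19; heavier regularization strengthens the effect).
  This is a property of intercept-free ridge classification under
  leave-one-out, not of the implementation; it fades as 1/N at benchmark
  sizes. Unit tests on shuffled labels therefore check the leakage
  direction only (no *above*-chance accuracy).
* Membership spread vanishes at large N under the verbatim score scaling
  (see above); `standardize_scores` is the documented remedy.
* The exact-enumeration MKL solver is exponential in the number of views —
  exact and fast for H ≤ ~15, unsuitable beyond.
* The MCD region scheme follows this package's documented reconstruction;
  other implementations of the descriptor may partition differently while
  still matching the 882 width.
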