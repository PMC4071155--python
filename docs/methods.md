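# Methods

## Model and assumptions

Each sample is a vector of m coded SNP genotypes, x_j ∈ {0, 1, 2} counting
minor alleles. Within class k the genotypes are assumed independent across
loci with X_j ~ Binomial(2, θ_{k,j}) (Hardy–Weinberg equilibrium), and
θ_{k,j} ∈ (0.01, 0.5): above 0.01 so the variant is a polymorphism rather
than a mutation, below 0.5 by definition of the minor allele. The
independence assumption is what the Kendall-τ selection module is for:
from a dense correlated panel it retains a pairwise-independent subset,
and classification uses only that subset. A fraction ρ of the m SNPs is
allowed to carry a marginal effect; the optimal rule uses l = ⌊ρm⌋ SNPs
(ρ = 1 by default — how a sparser effect pattern should be allocated among
loci is not specified by the design, so we expose ρ but do not guess an
allocation).

## Classifiers

With known θ the posterior-argmax (Bayes) rule reduces to pairwise linear
score comparisons; the pairwise threshold is

    K_{k,k′} = log(π_{k′}/π_k) + Σ_{j≤l} 2 log[(1−θ_{k′,j})/(1−θ_{k,j})],

where the sum over j is required for the pairwise rule to coincide with
the posterior argmax — we verified the equivalence by exhaustive
enumeration of all 3^l genotype vectors (l ≤ 6, D ∈ {2, 3}, random
profiles and priors).

The trainable variant plugs in per-class maximum-likelihood MAFs
θ̂_{k,j} = Σ x / (2 n_k), clipped to [1/(4 n_k), 1 − 1/(4 n_k)] so
log-odds coefficients stay finite when a class shows no minor alleles
(a continuity-correction scale; the clip only binds in degenerate small
samples). SNP j enters the (k, k′) contrast only when the two-sample Wald
test on 2n alleles per class rejects equal MAFs at level α (default 0.1);
the pairwise thresholds restrict their Σ_j term to the same selected SNPs
so score and threshold stay on a common SNP set (using all m SNPs in the
threshold instead would miscalibrate every contrast by the unselected
residual).

Strict pairwise wins can be non-transitive in the plug-in rule, so samples
without a class that wins all D−1 comparisons are assigned by
argmax_k min_{k′} (score − threshold), residual exact ties by smallest
class index, and flagged. Exact ties have probability zero unless two
classes have identical parameters; the deterministic tie-break is chosen
over a randomized one to keep `predict` reproducible.

## Gaussian performance approximations

For class k the D−1 pairwise scores are sums of l independent bounded
terms, hence asymptotically jointly normal with mean Σ_j b·2θ_{k,j} and
covariance Σ_j b b′·2θ_{k,j}(1−θ_{k,j}) across contrasts (shared X_j).
ξ_k = P(scores > thresholds componentwise) is a (D−1)-dimensional normal
orthant probability and PCC = Σ π_k ξ_k.

The estimation-adjusted variant (PCC(n), VUS(n)) models the fitted rule's
score for a future sample: each SNP enters a contrast with probability
equal to the Wald power at its true MAF difference (inclusion treated as
independent across SNPs and contrasts), and the plug-in coefficient
carries the first-order (delta-method) variance
1/(2 n_k θ_{k,j}(1−θ_{k,j})) + 1/(2 n_{k′} θ_{k′,j}(1−θ_{k′,j})); the two
contrasts of a class share θ̂_k, contributing the shared term to their
covariance. Thresholds use the power-weighted plug-in form. The
construction converges entrywise to the known-θ variant as all n_k → ∞,
is monotone in n, and in simulation is conservative: Monte-Carlo rates of
actually-fitted classifiers run somewhat above it, because two effects it
deliberately ignores (selection inflates |coefficient| conditional on
inclusion, and the threshold shares estimation noise with the score in a
variance-cancelling way) both push true performance up. We keep the
simpler independent-inclusion form; tests assert the conservative
direction rather than exact agreement.

Two structural caveats. First, ξ counts only strict pairwise winners; the
tie rule assigns the cyclic-tournament residue, so for barely-separated
classes the orthant PCC sits below the true rate (at zero separation:
~1 − P(cycle) per class versus the exact 1/D by symmetry). This residue
vanishes with separation and is invisible at the design points the tests
target. Second, all PCC(n) statements are about the *population* of
training sets at size n, not any single fitted classifier.

## Orthant probabilities

Public path: scipy's numerical multivariate normal CDF (absolute
tolerance 1e-4), exact univariate tail for D = 2. Rank-deficient
covariances (identical-class designs) receive a diagonal jitter of
1e-10·tr(Σ)/(D−1) plus an absolute floor 1e-12, which turns degenerate
components into point-mass indicators. The VUS search needs tail
probabilities for thousands of threshold vectors against a fixed (μ, Σ);
scipy's ≥3-dimensional CDF costs ~1.5 ms/point, so the engine uses a
vectorized Genz separation-of-variables quasi-Monte-Carlo tail (512
fixed scrambled-Sobol nodes, deterministic across runs), which agrees
with scipy to ~1e-4 on well-conditioned inputs and is validated against
it and against 1e6-draw Monte Carlo in the tests.

## AUC and VUS

Operating points are generated by D−1 free per-class threshold offsets
(K_1, …, K_{D−1}, K_D ≡ 0), entering contrast (k, k′) as K_{k′} − K_k —
exactly the family swept by varying the class priors, matching the
dimension of the ROC hypersurface and reducing to the standard ROC for
D = 2. For D = 2 the AUC is integrated deterministically (trapezoid over
≥512 offsets spanning ±8 sd of both score distributions); a
one-dimensional threshold space needs no stochastic search.

For D ≥ 3 the search alternates two proposal steps over threshold space:
an ant-colony step perturbing retained thresholds with Gaussian noise
(scale 0.25 × the interquartile range of retained components unless set),
and a genetic step applying uniform crossover (rate 0.9) and mutation
(rate 0.1, resampling a coordinate uniformly over the box). The first
iteration evaluates a deterministic coarse tensor grid over the box plus
uniform draws, so coverage does not depend on the random stream. Points
with all-positive rates accumulate into a cloud; since any rate vector
dominated by an achievable one is achievable (degrade assignments at
random), the cloud is closed below by every axis-subset projection of
each point (the corners of its dominated box) together with the origin
and the D unit vectors, making the hull a full-dimensional body bounded
below by the unit simplex from the first iteration. The volume is the
qhull convex-hull volume (with a joggle retry for near-degenerate 4-d
inputs, perturbation ~1e-10); the cumulative cloud makes the volume
history nondecreasing, and iteration stops when one iteration adds less
than 0.001 (configurable) after a minimum number of iterations.
Per-iteration effort scales with dimension — (512 initial, 256/batch,
min 6 iterations) for D = 3 and (4096, 2048, 12) for D ≥ 4, where the
2-surface needs far denser coverage; with these defaults the search
agrees with brute-force 200×200 Riemann integration of the
threshold-to-rate Jacobian to <0.01 for D = 3, and with analytic values
(1/D! floor, unit cube, simplex) to the stated tolerances. An empirical
variant replaces orthant rates with correct rates on a labelled test set,
giving Monte-Carlo VUS estimates for fitted classifiers.

## Sample-size determination

f(n) = VUS(∞) − VUS(n) − γ is evaluated on integers and bisected:
midpoints replace whichever bracket end preserves f(n_S) > 0 > f(n_L),
stopping at n_L − n_S ≤ 1 with answer n_L (total D·n_L). The initial
bracket (10, 5000) auto-shrinks toward 1 and auto-expands geometrically
(×4, capped at 4·10^5) when it does not straddle the root. Because the
VUS search is stochastic, every evaluation reuses one seed (common random
numbers), without which search noise near the root breaks the bisection's
sign logic; VUS(∞) is computed once and cached. Because the criterion is a
*difference* of volumes under common random numbers, it is insensitive to
the hull's absolute coverage deficit (doubling the 4-d search effort moves
the D = 4 gap by <0.002 while quadrupling cost), so gap evaluations in
four classes default to about half the effort of an absolute-VUS search
(2048 initial points, 1024 per batch, minimum 8 iterations). The returned root is
re-verified with a tightened search (3× initial points, tolerance 5e-4)
at n and n−1 and locally adjusted if the refined sign flips. Learning
curves share one gap cache across the γ grid (f is a γ-shift of a single
curve), so a curve costs little more than one search; required n is
nonincreasing in γ. For D = 2 the deterministic AUC gap is used and no
seed policy is needed. Per-class sizes are equal across classes;
unequal allocation is out of scope.

## SNP selection

Kendall's τ-b (tie-corrected — 0/1/2 data is massively tied, plain τ-a is
degenerate here) screens pairs for independence. The greedy loop seeds
the kept set with the first SNP in scan order (input order by default,
optionally MAF-descending) and adds a candidate only if |τ| < cutoff
against every kept SNP, recording for each rejected SNP the first
conflicting member; it stops when no candidate can be added, so the kept
set is maximal for the scan order. The default cutoff 0.05 is a
*statistic* threshold: reading it as a p-value cutoff would reject
independence for nearly all large-sample pairs, inverting the intended
screen. A p-value mode (keep when the τ test fails to reject at the
cutoff level) is provided for users who want a size-calibrated screen;
note the null dispersion of τ-b shrinks like n^{-1/2} (~0.02 at n = 800),
so a statistic cutoff only separates signal from noise when the sample is
large enough that the null mass lies well inside it.

## Synthetic designs

`table1_design` draws θ_{1,j} ~ U(0.4, 0.49) and shifts each subsequent
class down by h_{k,j} ~ U(h−0.002, h+0.002), extending the same recursion
for D = 4; priors are uniform and per-class sample sizes equal, matching
the symmetric simulation setting. Designs that would push any frequency
to the 0.01 floor fail fast with the offending locus named — clipping
would silently change the effect size h. The generator emulates
independent HWE loci with a common shift scale; it does not emulate
linkage disequilibrium, missing genotypes, genotyping error, unequal
class sizes, or MAF spectra skewed toward rare variants, so passing tests
certify the method under its stated model, not robustness to real-data
violations (the `correlated_fixture` generator covers correlated panels
only for the selection module, via duplicated columns with optional
resampling noise).

## Numerical choices and limitations

- MVN CDF tolerance 1e-4; Genz nodes 512; covariance jitter as above.
- Hull stopping tolerance 0.001 on the volume increment; the hull
  estimator approaches the true volume from below, so defaults were sized
  (dimension-scaled, above) to bring the residual deficit inside ~0.01
  for D = 3 and ~0.005 for D = 4 on the tested designs.
- Simulation studies default to 5 design draws × 5 datasets (the full
  20 × 20 replication is a flag) and Monte-Carlo test sets of 400 per
  class; acceptance runs use 5 design draws per cell.
- The bisection treats a stochastic f as deterministic between the CRN
  evaluations; the verification pass bounds, but cannot eliminate,
  root shifts of ±1–2 near flat gap curves.
- Estimation-adjusted performance is conservative (see above); sample
  sizes derived from it are correspondingly on the safe (large) side
  relative to Monte-Carlo truth, and quantities derived from other, more
  pessimistic adjustment conventions can be larger still.
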