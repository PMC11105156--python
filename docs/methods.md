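# Methods

This note documents the models and procedures implemented in `refree`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable construction exists.

## The ordinal model and its coding

Activation of each protein/response-element (RE) complex is an ordered
three-class outcome, Null < Weak < Strong. The model is a forward-cumulative
logit with the proportional-odds assumption: one coefficient vector governs
both class boundaries, and two thresholds θ_NW and θ_WS separate them. We
orient the link so that a larger genetic score increases the odds of higher
classes:

    P(class ≥ Weak)  = logistic((y − θ_NW) / s)
    P(class = Strong) = logistic((y − θ_WS) / s)

with `s` a link scale (1.0 until rescaling; see below). At y = θ_WS the
probability of being at most Weak is exactly ½. Predicted classes are the
argmax of the three class probabilities with ties broken toward the lower
class. Note the argmax boundaries coincide with the thresholds only when the
thresholds are well separated; Weak is never the modal class unless
θ_WS − θ_NW > 2·ln 2 ≈ 1.39, a geometric fact of the three-class logistic
that matters when choosing synthetic thresholds.

Indicator coding: each complex activates exactly
2·(1 + n_sites + C(n_sites,2) + C(n_sites,3)) indicators at third order — 30
in the default 4-site space — one β (binding) and one σ (specificity)
indicator per contained state/combination plus the global intercept β₀ and
the RE main effect σ₀. β indicators are 1; σ indicators carry the RE sign
(+1 ERE, −1 SRE). Fourth-order terms are not modeled: each would be
estimated from a single observation and is indistinguishable from
measurement error.

## Fitting

The cumulative model is fit through its two-binary recoding (Null=00,
Weak=10, Strong=11): two Bernoulli observations per complex sharing the
coefficient vector, each with its own unpenalized intercept. This is exactly
the proportional-odds likelihood. The penalized objective is

    (1/n) Σ NLL + (λ/2)·‖w‖²

with the thresholds and the two order-0 terms excluded from the penalty
(penalizing intercept-like terms would distort class base rates). β₀ is
dropped from the fitted design entirely — a column of ones is collinear with
the two thresholds — and is reintroduced by the post-hoc recentering, which
leaves scores and likelihood unchanged.

Optimization is L-BFGS with an analytic gradient on a CSR sparse design
(9.6M non-zeros at full scale), warm-started along the decreasing λ path.
Convergence tolerance 1e−8 (relative objective), max 500 iterations; a
non-converged final fit raises with diagnostics rather than returning
silently.

λ is selected by repeated k-fold cross-validation minimizing the mean
cost-weighted misclassification rate: prediction errors count the number of
class boundaries crossed (adjacent classes 1, Null↔Strong 2). Folds are
uniform random partitions of complexes; a partition whose training folds do
not contain all three classes is redrawn. Ties in the CV minimum resolve to
the larger λ (more regularization). Defaults follow the study design (900
λ values from 1e−1 to 1e−8 on a log₁₀ grid, 10×10-fold); the `reduced`
configuration (20 λ values, 3-fold, 1 repeat) is the desk-scale setting used
by the acceptance checks, where a full-scale fit takes ~5 minutes on one
CPU.

A diagnostic (`check_proportional_odds`) fits the two binary collapses
separately with a small ridge and reports the paired coefficient estimates
and their correlation; proportional-odds data give near-identical estimates.

## Reference-free coefficients and recentering

Reference-free effects are deviations from the global mean rather than from
a wild-type: the main effect of state q at site i is the mean score of all
variants carrying it minus the global mean; a pairwise effect is the subset
mean minus the sum of its lower-order expectations, and so on; σ₀ is half
the ERE-minus-SRE mean difference. These subset-mean definitions are exactly
the ANOVA (Möbius/inclusion-exclusion) projection of the score tensor, which
is how `reffree_coefficients_from_scores` computes them; it is exact
whenever the scores contain no interaction above the requested order and
serves as the independent oracle for both the regression and the recentering.

Because the regularized fit is unconstrained, its coefficients are
recentered post hoc: for each site subset V, the recentered coefficient
collects from every stored subset U ⊇ V the inclusion-exclusion combination
of marginal averages of the unconstrained U-coefficients, and the intercepts
absorb all grand means. After recentering every coefficient set and every
marginal subset (fixing any sub-combination of states) averages to zero to
~1e−15, and no complex's score changes. Recentering is idempotent and
agrees with the score-side oracle to ~1e−15; in practice L2 regularization
already brings most set means close to zero.

## Score rescaling

For reporting, scores are affinely rescaled so the global mean is 0 and the
strong-activator threshold θ_WS is 1. A pure affine map would change
logistic probabilities, so the coefficient table carries a `link_scale` that
the link divides by; the rescaling multiplies it by the same factor, making
every class probability (hence every predicted class, network, and catalog)
exactly invariant. FVar is invariant under the rescaling as well since
numerator and denominator scale together. Rescaling is idempotent and
undefined when θ_WS equals the global mean.

## Variance partition

Total genetic variance is the population variance of the score over all
2·A^n complexes. For a recentered table it equals Σ θ²/A^O over all terms
(σ₀ has O = 0; β₀ carries no variance), and the two routes agree to ~1e−12
relative — this dual-route identity is asserted in the tests rather than
assumed. FVar_θ = θ²/(A^O·Var); the "99% set" is the minimal FVar-ranked
prefix reaching 99% of the variance. The partition requires a recentered
table and raises otherwise, since the decomposition is invalid for
uncentered coefficients.

Epistasis-type classification: for a pair term c with constituent main
effects βᵢ, βⱼ, we compare sign(β + c) with sign(β) for each state. One flip
is sign epistasis, two flips reciprocal sign; no flip is magnitude
epistasis, split by the interaction's direction — negative interactions are
counted as diminishing returns (which subsumes amplifying costs), positive
ones as diminishing costs (subsuming amplifying returns). A net effect of
exactly zero does not count as a flip (ties go to magnitude). Third-order
terms are classified by fixing each of their three states in turn — which
conditions the remaining two main effects (β_qᵢ + β_qᵢqₖ) and their
interaction (β_qᵢqⱼ + β_qᵢqⱼqₖ) on the fixed state — and contributing one
third of the term's FVar per fixing, so the four categories always sum to
the total interaction FVar. The comparison algebra is this package's
operationalization of the named categories; binding and specificity terms
are classified separately.

## Mutation effects

A mutation at one site replaces one main effect, three pairwise and three
third-order interactions for each effect type; the 14 coefficient
differences sum exactly to the score change and are antisymmetric under
reversal. Direction profiles count, over all A³ backgrounds, the fraction in
which a mutation type raises or lowers the score by more than 5% of the
mean-to-strong-threshold gap (0.05 in rescaled units); smaller changes count
toward neither side. Epistasis is *necessary* for a class promotion when the
main-effect change alone leaves the score below the new class's threshold,
and *sufficient* when the interaction changes alone cross it; third-order
versus lower-order calls are made the same way. Specificity switches are
single-step moves from an ERE-specific to an SRE-specific genotype under the
configured adjacency rule, with necessity/sufficiency assessed separately
for losing ERE, gaining SRE, and both, via θ_WS threshold arithmetic. For
the switch catalog a serine-split rule is collapsed to the union of the two
groups' adjacencies (the catalog is a statement about amino-acid sequences);
split-resolved connectivity lives in the network module.

## Networks and path statistics

Functional networks contain genotypes predicted active under a fitted model.
Two passages of the source analysis differ on "functional"; the default is
Strong on ≥ 1 RE, with `weak-or-strong` available as a flag, and the
phenotype labels (ERE-specific / SRE-specific / promiscuous) use the same
binding predicate. Adjacency is hamming or genetic-code (any codon pair at
nucleotide distance 1; stop codons excluded, so no path through a stop
intermediate). With the genetic-code rule the two serine codon groups are
split into S (TCN) and Z (AGY) nodes — mutually non-adjacent — so a sequence
with n serines occupies 2ⁿ network positions; a collapse helper merges them
for reporting.

Shortest-path counts use layered BFS dynamic programming (a node is on a
shortest path iff its distances to the two endpoints sum to d(a,b); an edge
iff it advances one layer). Path distinctiveness follows the printed
formulas verbatim: with S genotypes along one shortest path, G_u unique
genotypes and E unique edges over all shortest paths,
P_g = (G_u−2)/(S−1), P_e = E/S, D = P_g²/P_e. Note that fully distinct paths
give P_g = P_e only asymptotically in S (the diamond gives 1 vs 4/3); the
formulas are applied as printed, not adjusted. Direct edges (S = 2) are
reported with a degenerate flag.

## Evolutionary walks

Walks start from ERE-specific nodes and end at the first SRE-specific node,
moving only among functional variants. Neutral mode steps uniformly over
neighbors. Selection mode computes each neighbor's selection coefficient as
c·Δ(specificity), specificity being y(g|SRE) − y(g|ERE), and steps with
probability proportional to Kimura's fixation probability. We use the
diploid form π = (1 − e^(−2s))/(1 − e^(−4Ns)) with initial frequency 1/(2N)
(the haploid variant is a constant-factor change; the choice is isolated
behind `fixation_probability`), evaluated with expm1 for small-s stability
and an exact 1/(2N) branch below |s| = 1e−12. The scale c = 0.01 per
rescaled score unit makes one non-binder→strong-binder unit of specificity
correspond to Ns = 1 at N = 100. Zero selection scale reproduces the
neutral walk exactly (same RNG stream), which the tests assert.

Selection walks can cycle between two high-specificity genotypes with no
SRE-specific exit; walks exceeding 20 steps (configurable) are censored and
excluded from path-length means, with the censored fraction reported.
Neutral walks carry a 10,000-step guard for toy networks with unreachable
targets. Exact expected absorption times for validation come from the
absorbing-Markov-chain linear system (I − Q)t = 1.

## Synthetic landscapes

The generator draws i.i.d. normal coefficients per order, zeroes a
configurable sparsity fraction, and recenters exactly, so the stored table
is simultaneously the ground truth and a valid reference-free architecture.
Defaults emulate the statistical shape reported for the motivating DMS:
20 states × 4 sites; per-order scales (β: 1.0/0.5/0.1, σ: 0.5/0.3/0.05)
decaying so main and pairwise effects dominate and third-order variance is a
few percent; σ₀ = 0.25; thresholds θ_NW = 3.0, θ_WS = 6.0 placed in the
upper tail of the resulting score distribution (SD ≈ 2.6) so strong
activators are ~1% of complexes and weak ~10%, mirroring the real library's
strong class minority while keeping all classes populated at desk scale.
Labels are the argmax class (deterministic mode) or, with probability
`label_noise`, a draw from the ordinal class probabilities.

What the generator does *not* emulate: replicate/read-count structure of the
sort-seq assay, technical misclassification correlated across REs,
fourth-order interactions, or any particular amino-acid chemistry (effects
are exchangeable across states). Passing recovery tests on these landscapes
therefore demonstrates correctness of the estimator and pipeline under the
model's own assumptions — identifiability from ordinal data, exactness of
the algebraic identities — not robustness to assay-specific artifacts.

The ΔG calibration (`calibrate_ddg`) is an ordinary least-squares line from
genetic score to measured binding free energy — both accrue additively, so a
linear relationship is expected — and is exercised on synthetic lines only.

## Problem sizes and tolerances

Acceptance-level checks run at the full default scale: recentering verified
on 100 random third-order 20-state tables (zero sums ≤ 1e−9, score drift
≤ 1e−9, score preservation spot-checked on every 10th table to bound
runtime); the averaging oracle to 1e−10 on a complete noiseless landscape;
FVar conservation to 1e−9. Fit recovery uses the reduced CV configuration on
argmax labels and checks first-order rank correlation > 0.9 and ≥ 99% class
agreement (measured: ≈ 0.99 and 99.9%). Walk calibration uses 10,000
replicates against the exact absorption time within three Monte-Carlo
standard errors. Unit tests use smaller alphabets (2–8 states, 1–3 sites)
where brute-force enumeration is feasible.

## Known limitations

* The proportional-odds assumption is diagnosed but not relaxed; strongly
  non-proportional data would need per-threshold coefficients.
* Near-separable data (noiseless labels at tiny λ) push coefficient
  magnitudes up with the link slope; only score *rankings* and class
  boundaries are then meaningful, which is why recovery is asserted by rank
  correlation up to the link's affine calibration.
* Genetic-code adjacency is defined at the amino-acid level; nucleotide
  genotypes are not tracked and codon usage is not weighted.
* The class-transition and switch catalogs are single-step only; multi-step
  (double-mutant) transitions are out of scope.
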