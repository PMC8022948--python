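# Methods

## The model

An individual's trait is split into a population mean, a self-QTL effect,
a neighbor-QTL effect, and noise:

    y_i = ȳ + g_i + Σ_{<i,j>} g_i g_j(s) / L_i + e_i

Self effects take the classical values `g ∈ {a1, d1, -a1}` for AA, AB, BB.
Neighbor effects act through the *genotypic identity* of the focal
individual with each neighbor within Euclidean distance `s`: the nine
ordered genotype combinations score `a2²` (identical homozygotes),
`-a2²` (opposite homozygotes), `±a2·d2` (homozygote–heterozygote), and
`d2²` (both heterozygous).  The construction is an inverse Ising problem:
genotypes are two (or three) "spin" states, the identity sum plays the role
of the interaction energy, and the fitted coefficient of the identity is
the interaction strength.  The sign is interpretable: positive means the
trait rises when neighbors carry the same alleles.

Every quantity is computed on conditional genotype *probabilities* rather
than hard calls, which is what makes the method an interval-mapping method:
positions between markers are evaluated through the probabilities the
marker data imply there.

## Conditional genotype probabilities

A hidden Markov chain per chromosome with states AA/AB/BB (F2), AA/AB
(backcross), or AA/BB (selfed RIL).  Transition probabilities come from
inter-position distances through a map function — Haldane
`r = (1 - e^{-d/50})/2` by default, Kosambi selectable; the selfed-RIL
chain uses the RIL-expanded fraction `R = 2r/(1+2r)`, the standard
accumulation of recombination over repeated selfing.  Emissions allow a
genotyping error rate (default `1e-4`; `0` supported for exact tests);
missing calls and pseudomarkers emit uniformly.  Posteriors come from the
forward–backward algorithm, checked in the tests against exhaustive
hidden-path enumeration to 1e-10.

Pseudomarkers are inserted so that no grid gap exceeds a chosen step;
the genome scans can also run at observed markers only (step `None`), the
configuration used throughout the simulation benchmark.

Two-point map estimation maximizes the exact two-marker likelihood of each
adjacent pair (cross-specific chain, RIL expansion inverted for selfed
lines) and caps the estimate at r = 0.49 before cM conversion so unlinked
pairs yield a finite, flagged distance.

## Neighbor identity and codings

    z_i(s) = (1/L_i) Σ_{j: 0 < d_ij <= s} Σ_v Σ_w p_{i,v} p_{j,w} C[v,w]

The neighborhood is a closed ball excluding self; `L_i` is the focal
individual's own neighbor count (counts differ at arena edges; the range of
`L_i` is worth inspecting on real layouts — a "global L" variant is exposed
as config).  A scale at which some individual has no neighbors is rejected
with a diagnostic rather than silently scored zero, since zeros would bias
the regression; dropping the isolated individuals is available as an
option.

Codings:

| name | table | use |
|---|---|---|
| quadratic | 1, ±0.25, 0, ∓0.25 (het pairs), ±1 | F2 genome scan |
| additive-polygenic | products of (-1, 0, 1) | genome-wide K2 kernel |
| inbred-linear | products of {AA, BB} = (1, -1) | selfed-RIL scan |
| backcross-linear | products of {AA, AB} = (-1, +1) | backcross scan and kernel |

The backcross coding deserves a note.  For two-genotype crosses the
identity is a product of symmetric ±1 codes, so identical pairs score +1
and mixed pairs -1 regardless of which two genotypes the design carries;
the inbred and backcross codings are therefore the same model on relabeled
data, and the test suite asserts their LOD curves coincide.  An asymmetric
0/-1 coding would zero every pair involving the heterozygote and discard
the identity contrast for half of a backcross; in our benchmark it costs
most of the long-range power, which is why the symmetric form is used both
in the scan and in the neighbor kernel.

## Stepwise genome scans

At each grid position, for a gaussian trait:

1. regress y on the expected additive score (codes -1, 0, 1) and, for F2,
   the expected dominance score (codes 0, 1, 0), plus covariates;
   `LOD_self = (n/2) log10(RSS_null / RSS_self)`;
2. form the fitted self effect from the step-1 coefficients and carry it as
   a *single constructed covariate* — the self effect is fixed before the
   neighbor term is tested, because self and neighbor components are
   intrinsically correlated (the focal genotype appears in both) and a
   joint fit would over-credit the neighbor term;
3. regress on the identity `z` (plus `z²` for F2);
   `LOD_nei = (n/2) log10(RSS_self / RSS_nei)`.

Because the constructed covariate spans the genotype-score fit, the
"self" likelihood is identical whether the covariate or the original two
scores are used, and the three models are nested — both LODs are
non-negative by construction for gaussian traits.  Binary traits replace
least squares with logistic IRLS (deviance-based LODs, ridge fallback with
a warning under separation), so tiny negative binomial LODs can occur at
convergence tolerance.

Reported effects follow the homozygote-difference convention:
`2a1` is the fitted AA-minus-BB difference (AA minus AB for a backcross),
`d1` the heterozygote deviation; `2a2²` is twice the linear identity
coefficient — the effect of identical-homozygote neighbors over opposite
ones, signed — and `d2²` the quadratic coefficient.  Since the model
writes the quadratic coefficient as a square, a negative fit is floored at
zero and flagged (`d2sq_clipped`) rather than hidden.  The regression is
run on the raw identity; per-position standardization of `z` spans the
same model space (an affine map plus its square), so LODs are unchanged
and the raw-scale coefficients stay interpretable.

Permutation thresholds shuffle trait and covariate rows jointly against
the fixed genotype/spatial structure, re-run both scans (the self fit is
re-estimated per permutation), and take nearest-rank percentiles of the
genome-wide max LOD — self and neighbor separately; defaults are 999
permutations with 0.05/0.10 as significant/suggestive levels.  The type-I
error of the neighbor threshold is verified by Monte-Carlo calibration in
the tests.

Epistasis: for a focal position, every other position is tested by adding
the product of the two identities to their additive-joint model; positions
within 1 cM on the focal chromosome are reported but flagged as linked.

## Variance components and the effective distance

    y = Xβ + u1 + u2 + e,  Var(u1) = σ1² K1,  Var(u2) = σ2² K2

`K1 = P1ᵀP1/(q-1)` from expected additive genotype values over all q grid
positions, `K2` analogously from neighbor identities at scale s.  Columns
of P1/P2 are centered and standardized to unit variance before the
cross-product (both toggles exposed).  Standardization matters: identity
columns shrink roughly as 1/L with the neighbor count, so without it the
neighbor kernel's overall scale collapses as s grows and PVE_nei values
are not comparable across scales — the quantity the ΔPVE rule differences.
With it both kernels have unit-scale diagonals and
`PVE_nei = σ2²/(σ1²+σ2²+σe²)` is a genuine variance share.

Fitting is average-information REML: AI steps with step-halving on the
restricted likelihood, EM fallback when an AI step fails, non-negativity
by projection, convergence at gradient ∞-norm < 1e-6 within 200
iterations (non-convergence is flagged, never silent).  The optimum is
checked in the tests against a dense grid search over variance proportions
with the total variance profiled out.  Binary traits use penalized
quasi-likelihood on the logistic scale: the working-response REML carries a
fixed diagonal residual kernel `W⁻¹`, there is no free σe², and the
neighbor contribution is reported as the ratio `RVE_nei = σ2²/σ1²`.

Marker heritability `h²` is the single-kernel fit (σ2² and s at zero);
`(PVE_self + PVE_nei) − h²` is the net contribution of polygenic neighbor
effects.

**ΔPVE rule.**  Candidate scales are the percentiles (default every 10th)
of the pairwise-distance distribution, deduplicated keeping the smallest
scale on ties.  The model is fitted at each scale (warm-started from the
previous one), `ΔPVE(s_k) = PVE_nei(s_k) − PVE_nei(s_{k−1})` with the first
usable scale differenced against zero, and `ŝ = argmax ΔPVE`, smaller scale
on ties.  Two kinds of scale are skipped as carrying no spatial contrast:

- scales leaving any individual without neighbors (small end), and
- scales whose neighborhood graph is complete (large end — typically the
  100th percentile, which is the maximum pairwise distance).  With every
  individual neighboring every other, the identity degenerates into a
  function of the focal genotype alone (its additive value times a constant
  plus a heterozygosity term), K2 is no longer separable from K1, and the
  REML split between the kernels becomes arbitrary; empirically it
  produces a spurious ΔPVE spike at the top scale in a fifth to a third of
  replicates.  Skipping such scales restored clean distance recovery
  (medians at the true percentile) and is the package's own design choice,
  symmetric to the isolated-individual rule.

## The synthetic benchmark generator

The generator reproduces the study conditions the method was validated
under, and doubles as the test fixture factory:

- **map/cross**: default 5 chromosomes × 5 markers at 15 cM spacing
  (compact but multi-chromosome; marker count only sets kernel resolution);
  genotypes from the cross-appropriate Markov chain with Haldane
  transitions; default n = 200.
- **space**: x, y ~ Unif(1, 100), a continuous two-dimensional arena.
- **self phenotype**: one major marker with additive deviation
  `max_a1` — defaults 0.56 for F2 and 0.28 for backcross, realistic
  major-QTL deviations on a standardized trait for the two designs (a
  backcross exposes half the allelic contrast of an intercross) — plus
  `1e-3 · max_a1` effects at all other markers
  (polygenic background) and unit normal noise, then standardized to
  mean 0 / variance 1.
- **neighbor component**: the nine-combination table at the true scale
  (a percentile of the realized pairwise distances), with scenario
  coefficients additive (a2, 0.25·a2), dominant (a2, a2), overdominant
  (a2, 1.25·a2), backcross (a2, −a2), plus a `null` scenario (0, 0).
  The component is rescaled per replicate so that its share of the final
  trait variance is exactly the requested value (default 50%), solving the
  quadratic that accounts for the self–neighbor covariance; the realized
  share is recorded.
- **neighbor-phenotype scenario**: the component is instead the scaled
  mean of neighbor *self-phenotypes* — phenotype spillover with no
  genotype-identity signal, used to confirm the genotype model does not
  misattribute it (the quantity `scripts/acceptance.py` reports).

What the generator does *not* emulate: real arenas are lattices with edge
effects rather than uniform scatters; residuals can be non-gaussian
(counts, zero inflation); neighbor effects can be anisotropic or
asymmetric in distance; and environmental spatial autocorrelation — which
can mimic neighbor identity when genotypes are spatially clustered — is
absent, since cross designs randomize genotypes over positions.  Passing
benchmarks therefore demonstrate correctness of the machinery under the
stated generating model, not robustness to confounded field layouts.

## Problem sizes and runtime choices

The bundled benchmark tests run n = 200 individuals, 25 markers, distance
percentiles 10–50: 30 replicates per distance class for the F2 power and
distance-recovery checks (enough for stable medians) and 10 for the
backcross; the acceptance script uses 25 replicates per scenario
for the spillover guard.  A full five-scenario table at these sizes takes
a few minutes on one core; `neiqtl benchmark --reps` scales it in either
direction.

## Known limitations

- Autosomes only; sex chromosomes would need their own degrees of freedom.
- Single-QTL scans (plus pairwise epistasis); no multi-QTL model search.
- PQL variance components for binary traits carry the usual PQL bias for
  rare outcomes; RVE_nei is a ratio, not a variance share.
- PVE_nei is a selection statistic for ŝ, not a measure of model
  improvement over the self-only model — use `(PVE_self+PVE_nei) − h²`
  and the stepwise LOD_nei for that.
- The quadratic approximation assumes equal variance across the nine
  genotype combinations; purely additive F2 traits are fitted more
  efficiently by the linear two-genotype model, and long-range effects in
  F2 designs lose power as the self/neighbor correlation grows.
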