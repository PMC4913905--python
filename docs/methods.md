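# Methods

This note records the models implemented in `gsacc`, the choices made
where the design was genuinely open, and what the simulation benchmark
does and does not establish.

## Causal model and accuracy definitions

The trait follows `Y = Qθ + e` with fixed QTL effects θ, centered causal
genotypes `Q`, and `e ~ N(0, σe² I)`. All genotype matrices (markers and
QTLs) are centered; by default the column means are taken over the
pooled training+test sample (`ExperimentConfig.centering="pooled"`,
with `"trn"` as the alternative), and phenotypes are centered by their
pooled mean. Two accuracies are tracked: the phenotypic accuracy ρ
(correlation of predictions with phenotypes) and the genotypic accuracy
ρ̃ (correlation with breeding values q′θ); they satisfy ρ = h·ρ̃. When
QTL positions and effects are known, the best predictor is q′θ itself
and the accuracies are ρ_oracle = h, ρ̃_oracle = 1.

Heritability is estimated as `Var̂(q′θ)/(Var̂(q′θ)+σe²)` with the
unbiased (n−1) empirical variance over the pooled training+test sample;
σe² is taken at its known value (1 in all simulations). The
maximum-likelihood (n) denominator would change results by O(1/n).

## Ridge-regression BLUP

Marker effects are `β̂ = (X′X+λI)⁻¹X′Y`, computed in the dual form
`β̂ = X′V⁻¹Y` with `V = XX′+λI` (Cholesky solve of an nTRN×nTRN system,
so cost is governed by the training size even at 10,000 markers; the
primal and dual forms are verified to agree to 1e−8 relative in tests).
λ = σε²/σβ² comes from one of three routes:

- **REML** (default for benchmark runs): the one-random-effect model
  `y = μ + Xβ + ε`, `β ~ N(0, σβ² I)`, is reduced via the spectral
  decomposition of `K = XX′` to a 1-D profiled restricted likelihood in
  λ, minimized by bounded scalar search on log λ (bounds 1e−8…1e8,
  xatol 1e−8). The kinship is the unscaled `XX′`, so σβ² is a per-marker
  variance and λ is directly σε²/σβ². A single fixed intercept is
  absorbed by GLS even though phenotypes are pre-centered — this is true
  REML (n−1 residual degrees of freedom), matching standard mixed-model
  software behaviour; with centered data the intercept estimate is ≈0
  and the choice is immaterial in practice.
- **Heritability**: λ_h² = (1−h²)/(nTRN h²)·ΣᵢⱼXᵢⱼ², which assumes the
  genetic variance is spread uniformly over the filtered markers. A
  misspecified variant multiplies the estimated h² by 0.9 before this
  formula only (the accuracy formulas keep the true quantities).
- **Fixed**: a user-supplied λ.

If σβ² collapses to the boundary (null trait), λ is set to the cap
1e8·tr(XX′)/nTRN with a warning, keeping the (≈0) predictor defined.

## Theoretical accuracy and its plug-in estimators

The closed-form accuracy conditions on the realized `X` and `Q` and
takes expectations over the joint distribution of a test individual's
markers x and causal genotype q. Four plug-in estimators replace those
expectations by averages over the realized test sample: the mean of
‖xᵢ′X′V⁻¹‖², the cross-moment θ′[(1/nTST)Σ qᵢxᵢ′]X′V⁻¹Qθ, the uncentered
second-moment matrix (1/nTST)X_tst′X_tst for Var(x), and the
mean-subtracted (1/nTST) variance of qᵢ′θ for σG². The last two follow
the reference estimators literally — Var(x) uncentered, σG² centered —
even though the asymmetry looks odd; with centered genotypes the
difference is O(1/nTST). σe² enters at its known value. At λ=0 the
weights X′V⁻¹ are computed through the primal form (X′X)⁻¹X′, which
requires full column rank and reproduces the least-squares limit used
by the independent-loci closed form.

## Proxies

- **Effective dimension**: nTRN·Ê‖x′X′V⁻¹‖². Substituting it for the
  locus count in the independent-loci form and multiplying by h gives
  the QTL-free proxy exactly (an algebraic identity tested to 1e−12).
- **Imperfect LD**: with a constant LD r² between each QTL and its
  marker, ρ = r²h·√[(h²/(1−h²)) / (Ê‖x′X′V⁻¹‖² + r²h²/(1−h²))]; r²=1
  recovers the perfect-LD proxy and the value decreases with r².
- **Me-based proxies**: Ne is fitted by nonlinear least squares of all
  pairwise marker r² (training sample, filtered markers; pairs
  subsampled above `max_ld_pairs`=100,000) against the Hill–Weir (1988)
  drift expectation E[r²] = (10+C)/((2+C)(11+C)) + 1/n with C = 4·Ne·c
  and c the map distance in Morgans. The Sved-type curve 1/(a+b·Ne·c)+1/n
  and the rate constant b (4 = standard/diploid convention, 2 =
  haploid-rate) are config-exposed; the Hill–Weir curve with b=4 is the
  default because it reproduces the reference Me values on these
  simulated populations, where the haploid-rate Sved fit does not.
  Then Me1 = 2NeL/ln(4Ne·l), Me2 = 2NeL/ln(2Ne·l), Me3 = 2NeL/ln(Ne·l)
  (natural logs; L genome length, l average chromosome length), each
  substituted for the locus count and multiplied by h (proxies are
  compared on the phenotypic scale).
- **Li & Ji count**: eigenvalues λᵢ of the marker correlation matrix
  over the pooled training+test genotypes give
  Meff = Σ[1(λᵢ≥1) + (λᵢ−⌊λᵢ⌋)]; eigenvalues below 1e−10 are zeroed.
  Because the rule needs p < n, dense panels are split into equal-width
  position intervals (2 parts at 1,000 nominal SNPs, 3 parts at ≥5,000)
  and the per-interval counts summed.
- Proxies are scored by the mean squared error between per-architecture
  proxy means and empirical-accuracy means.

## The simulator

One chromosome of length 1 Morgan; n ∈ {100, 1000, 5000, 10000} markers
on a left-aligned grid at spacing 1/n Morgan, which makes every
whole-centimorgan point an exact marker position at all four densities
(so cM-placed QTLs always coincide with markers). Two completely
divergent haploid founders (all-0 / all-1) are crossed; generation 1
consists of pop_size gametes of that pair; thereafter each generation is
pop_size offspring, each one meiotic gamete of two distinct parents
drawn uniformly at random (no selfing, no overlapping generations, no
mutation, no selection). Meiosis draws a Poisson(L) number of crossovers
placed uniformly — Haldane's model, no interference; the two-locus
recombination fraction is verified against (1−e^(−2d))/2 in tests. In
the final generation a random pair produces pop_size/4 full sibs that
join the training set (nTRN = pop_size + pop_size/4 ∈ {500, 1000}); the
100 test individuals are extra offspring of the penultimate generation,
so they belong to the final generation without duplicating training
rows. The test branch can instead evolve extra generations from that
checkpoint (training fixed at its generation) to study prediction decay
over time. Markers that are monomorphic in the training sample, or
column-identical to an earlier marker, are removed (first occurrence
kept); the kept set defines the panel for both training and test. In
the "QTL removed" (imperfect LD) mode the causal columns are deleted
from the marker panel only — `Q` and the phenotypes are untouched.

QTL scenarios (σe²=1 throughout): 2 QTLs at 3/80 cM with effects +1/−2;
100 QTLs every centimorgan with effect +0.15; and three mixtures of two
major QTLs at 3/80 cM (+0.5/−0.6, +1/−0.7, +2/−2) plus 98 small QTLs
(+0.07, +0.1, +0.1) on the remaining centimorgan points.

Reproducibility: one master seed; the stream for (architecture a,
replicate r) is `SeedSequence(master_seed, spawn_key=(a, r))`, so
replicates are independent, never collide across architectures, and
every simulated object is bit-reproducible.

## What the benchmark shows — and does not

The simulated populations are haploid, single-chromosome, biparental
and neutral; they mimic evolving recombinant-inbred/doubled-haploid
material with maximal starting LD that decays by recombination and
drift. Passing benchmarks here demonstrates that the closed-form
accuracy and the proxies behave as derived **under the model's own
assumptions** (known σe², QTLs on markers unless removed, random-mating
LD structure). They do not demonstrate performance on outbred diploids,
multi-chromosome genomes, structured populations, or traits with
dominance/epistasis — on real data the proxy should be read as an upper
bound, with the r²-adjusted variant when marker density is limiting.

Two reference quantities are systematically sensitive to simulator
details that the available description does not pin down: the number of
distinct marker columns after filtering on dense panels (ours run
~15–20% below the reference means, consistent with somewhat fewer
accumulated recombination junctions) and, downstream of it, the Li&Ji
count on dense panels. Heritabilities, accuracies, the effective
dimension and the Me estimates all reproduce the reference values at
matched configurations.

## Problem sizes and numerics

Benchmark checks run 20 replicates per architecture (the reference
design used 100) and compare means within 3 Monte-Carlo standard
errors; the proxy-comparison grid is reduced to 16 architectures (all
four densities, both QTL scenarios, 30/50 generations, nTRN = 500) at 8
replicates. Full 100-replicate, 48-architecture runs are available via
`ExperimentConfig`/`run_grid`. All V-solves use Cholesky
factorizations; explicit inverses appear only in test oracles. Failed
replicates are excluded from summaries and the run aborts if more than
5% fail.
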