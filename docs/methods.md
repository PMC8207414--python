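# Methods

## Model overview

`plastisim` simulates a geographically closed, panmictic population of a
sexual species with non-overlapping generations (one generation per time
unit) adapting to a moving phenotypic optimum. Adaptation can proceed
through genetic change (selection on standing variation plus new
mutations) and/or through one of five phenotype-development rules. The
model deliberately excludes migration, age structure, the evolution of
plasticity itself, costs of plasticity, and cue-reliability models:
sensing is perfect, and the question is what the *shape and limits* of the
plastic response do to population fate.

One generation executes in a fixed order: develop phenotypes of all
adults → evaluate the degree of adaptation → compute density-dependent
fecundity → record cohort statistics → mate and produce offspring
(inheritance + mutation) → all adults die → advance the environment.
Statistics are therefore always measured on developed, pre-reproduction
adults, which makes Var(a) and Var(z) comparable across development rules.

## Environment

The optimum is θ_t = θ₀ + η·t + φ_t with AR(1) noise
φ_t = α·φ_{t−1} + β·ξ_t, ξ_t ~ N(0,1), and innovation scale
β = σ√(1−α²). The β scaling holds the stationary variance of φ at σ² for
every admissible α, so noise color can be varied without changing noise
magnitude — the property the stationarity tests verify to within 3
Monte-Carlo standard errors. φ₀ is initialized as a single scaled draw
β·ξ₀ so the very first generation already experiences stochasticity and
the process starts at its stationary distribution. A deterministic
environment (σ² = 0) consumes no random draws, so seeded runs with and
without noise share their demographic randomness.

Generation g (1-based) experiences the environment at time t = g − 1;
under a deterministic trend its optimum is θ₀ + η(g−1). This indexing
places the first crossing of the plasticity limit π/2 at generation 80
for η = 0.02 (0.02·79 = 1.58).

When the carrying capacity is stochastic, K_t is redrawn independently
each generation from Normal(K, (sd·K)²) and floored at 1.0: K_t enters
only as a divisor in the Ricker exponent, and the floor keeps fecundity
defined while leaving catastrophic draws effectively lethal.

## Development rules

z = a + e, where a is the additive genetic component and e is set at
development time:

- **none** — e = 0; all phenotypic variance is genetic.
- **random** — e ~ N(0, V_E), redrawn independently for every individual
  every generation (a labile, nonadaptive trait). Default V_E = σ² = 1.
- **linear** — e = b·θ_cue with default slope b = 0.5: adaptive but
  imperfect; b = 1 gives perfect plasticity.
- **saturating / sinusoidal** — a developmentally flexible response
  e = sin(|ΔE|)·ΔE toward the optimum, where ΔE = θ_cue − a is the shift
  development must produce. The saturating rule clamps ΔE to ±π/2 beyond
  the limit (maximum response magnitude π/2, clamped symmetrically for
  negative shifts to keep the response adaptive); the sinusoidal rule
  decays past π/2 and fails entirely (e = 0) for |ΔE| > π. Phenotypic
  units map 1:1 onto radians inside the sine, which puts the limit at a
  mismatch of ≈1.5708 phenotypic units.

The two limited rules make many genotypes develop the same phenotype near
the optimum, producing developmental canalization at the population level
(Var(z) ≪ Var(a)) and, once the optimum passes the limit, exposing that
hidden variation as phenotypic (cryptic genetic variation) while mean
fitness drops.

The development cue is configurable: `current` (labile traits develop on
the optimum they are selected on) or `previous` (constant characters whose
sensitive period closed one generation earlier; the first generation uses
θ₀). Development results are recomputed from scratch every generation and
e is never inherited.

## Selection, demography, reproduction

Degree of adaptation w = exp(−(z−θ_t)²/(2γ²)) with γ = 2.2 (moderate
selection). Fecundity w′ = w·e^{ψ(1−N/K_t)} uses the adult count N before
reproduction and the realized K_t of the generation; there is no hard
ceiling at K, so high density compensation (ψ = 2.5) produces the
overshoot–oscillation dynamics of the classic Ricker map while ψ = 0.5
approaches K monotonically. Each female mates once with a uniformly drawn
male (with replacement across females: lottery polygyny) and the couple's
offspring number is one Poisson draw with mean w′_i + w′_j. Offspring sex
is Bernoulli(1/2). A population is extinct when it is empty or single-sex
(no pair can ever form again); a replicate that completes its horizon
persists.

## Genetics

L diploid additive loci (default 1); a = sum of allelic values. The
founding population of N = K adults is locally adapted: alleles ~
Normal(θ₀, V_G/2), so Var(a) = V_G initially. With θ₀ ≠ 0 this literal
rule makes the mean genotype 2Lθ₀; the package warns in that case (all
canonical scenarios use θ₀ = 0). Inheritance is Mendelian per locus with
free assortment; mutation hits each haplotype-locus independently with
probability μ and *adds* a Normal(0, M_V) effect to the allelic value
(continuum of alleles). Defaults μ = 10⁻³, M_V = 0.2.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| K | 1000 | mean carrying capacity (individuals) |
| γ | 2.2 | width of the Gaussian fitness function (trait units) |
| σ² | 1 | stationary environmental variance (trait units²) |
| θ₀ | 0 | initial optimum |
| η | 0 – 0.04 | rate of directional change (trait units/generation) |
| α | −0.8 – 0.8 | noise autocorrelation (color) |
| ψ | 0.5 – 2.5 | density compensation (life-history strategy) |
| b | 0.5 | linear reaction-norm slope |
| V_G | 0.2 | initial genetic variance |
| L | 1 | loci per trait |
| μ | 10⁻³ / 10⁻⁴ | mutation rate per haplotype per locus |
| M_V | 0.2 | mutation effect variance |
| t | 100 / 250 | generations per replicate |
| sd | 0.1K / 0.2K | stochastic-K standard deviation |

## Reproducibility and seeding

Each replicate owns one `numpy` Generator seeded base_seed +
replicate_index and consumed in a fixed order (environment
initialization, population initialization, then per-generation draws), so
whole replicates are bit-reproducible. Grid cells are seeded
base_seed + 10⁶·cell_index + replicate_index, making cell results
independent of execution order and safe to parallelize externally.

## Statistics

Persistence probability is n_persisted/n_reps with the plain binomial
(Wald) standard error √(p(1−p)/n); a Wilson interval is available for
p near the boundaries. Cohort variances use the unbiased (ddof = 1)
estimator; cohorts of fewer than two individuals report NaN, and
variance-ratio diagnostics flag degenerate denominators instead of
propagating infinities.

## Problem sizes and what the tests show

The test suite runs replicate batches at a desk scale chosen once: 20
replicates per scenario, 40–250 generations, K = 1000 — enough for the
qualitative phenomena (canalization ratios, variance maintenance
orderings, persistence contrasts) to be stable across seeds, while a full
100-replicate sweep of the published scenario grids remains available via
`run_grid` / the `plastisim grid --paper-scale` command. Monte-Carlo unit
checks use 10⁵–10⁶ draws and 3-standard-error tolerances.

The synthetic populations the generator produces are idealized: exactly
Gaussian initial allele values, exact Bernoulli sex ratios, no linkage,
observation-free census. Passing tests therefore validates the simulator's
internal consistency and its agreement with the model's analytic limits
(AR(1) stationarity, Ricker skeleton, Mendelian and Poisson moments), not
the model's fidelity to any real species.

## Known limitations

- Persistence probabilities in the hardest corners are sharp thresholds:
  under strong red noise with ψ = 1.8 at η = 0.02, long replicates
  occasionally go extinct late (measured p ≈ 0.98 per cell), so "all
  treatments persist" holds only approximately there.
- Under rapid change (η = 0.04) with weak density compensation, the
  saturating rule delays extinction by roughly 50 generations relative to
  genetic determinism but rarely converts that delay into 250-generation
  persistence: past saturation its adaptation rate is mutation-limited,
  and the mutational variance input (2μM_V = 4·10⁻⁴ per generation)
  cannot sustain the required response. Rescue under these conditions is
  carried almost entirely by the linear rule.
- The "slightly deleterious mutations" effect-size variant is exposed only
  as a hook (`MutationModel` is the single implemented effect model).
- Var(a) ≈ 0 cohorts (e.g. V_G = 0 scenarios) make ratio diagnostics
  undefined by construction; they are flagged, not imputed.
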