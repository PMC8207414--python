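# plastisim

An individual-based eco-evolutionary simulator for studying how phenotypic
plasticity, genetic adaptation, and life-history strategy jointly determine
whether a closed, sexual population persists under directional, stochastic
environmental change.

It is aimed at evolutionary ecologists and modellers who want to compare
*types* of plasticity — not just its presence — under realistic assumptions:
reaction norms with physiological limits, many-to-one genotype–phenotype
maps, colored (temporally autocorrelated) climate noise, and density
regulation spanning slow vertebrate-like to fast boom-bust life histories.

## The model

A panmictic population with non-overlapping generations tracks a phenotypic
optimum

&nbsp;&nbsp;θ*t* = θ*t*\* + φ*t*,&nbsp;&nbsp; θ*t*\* = θ₀ + η·*t*,&nbsp;&nbsp;
φ*t* = α·φ*t*₋₁ + β·ξ*t*,&nbsp;&nbsp; β = σ√(1−α²),

i.e. a linear trend of rate η with AR(1) noise whose stationary variance is
σ² for every autocorrelation α (blue α<0, white α=0, red α>0). Each
individual's trait is z = a + e: an additive diploid genetic component a
(L loci, alleles initialized Normal(θ₀, V_G/2)) plus an environmental
component e set by one of five development rules:

| mode | e | limits |
|---|---|---|
| `none` | 0 | — (genetic determinism, h² = 1) |
| `random` | ~ Normal(0, V_E) | nonadaptive, redrawn each generation |
| `linear` | b·θ | none (b = 1 is perfect plasticity) |
| `saturating` | sin(\|ΔE\|)·ΔE | response magnitude caps at π/2 |
| `sinusoidal` | sin(\|ΔE\|)·ΔE | decays past π/2; e = 0 beyond \|ΔE\| > π |

with ΔE = θ − a the shift development must compensate. Fitness is the
Gaussian degree of adaptation w = exp(−(z−θ)²/2γ²); fecundity follows a
Ricker form w′ = w·e^{ψ(1−N/K)} where ψ is the density-compensation
strength; each female mates with a uniformly drawn male (lottery polygyny)
and the couple produces Poisson(w′ᵢ + w′ⱼ) offspring. Haplotypes mutate at
rate μ per locus with Normal(0, M_V) additive effects. The carrying
capacity can itself fluctuate, K_t ~ Normal(K, (sd·K)²).

## Worked example

```python
import plastisim as ps

cfg = ps.SimulationConfig.from_values(
    K=1000, psi=1.0, eta=0.02, sigma2=0.0,   # deterministic slow change
    plasticity="sinusoidal", t_max=250, seed=1,
)
records = ps.run_scenario(cfg, 20)
summary = ps.persistence_summary(records)
print(f"p = {summary.p:.2f} +/- {summary.se:.2f}")

diag = ps.variance_diagnostics(records[0])
print(f"early Var(z)/Var(a) = {diag['ratio_var'][:40].median():.2f}")
print(f"late  Var(z)/Var(a) = {diag['ratio_var'][150:].median():.2f}")
print(f"late  mean w        = {diag['mean_w'][150:].mean():.2f}")
```

prints

```
p = 1.00 +/- 0.00
early Var(z)/Var(a) = 0.12
late  Var(z)/Var(a) = 4.56
late  mean w        = 0.84
```

Read: all 20 replicates of this population survive 250 generations of
slow, steady warming. Early on, the limited sinusoidal
reaction norm develops nearly identical phenotypes from different
genotypes, so phenotypic variance is ~9× smaller than genetic variance
(developmental canalization). Once the optimum drifts past the plasticity
limit (≈ generation 80 at η = 0.02, where θ = 1.58 ≈ π/2), that hidden
genetic variation becomes phenotypically visible — the ratio rises past 1
(cryptic variation exposed) and mean fitness sags, after which genetic
change must carry adaptation.

The same scenarios are scriptable from the shell:

```bash
plastisim simulate --eta 0.02 --psi 1.8 --plasticity sinusoidal --reps 20 --seed 1 --out series.csv
plastisim grid --eta 0 --eta 0.04 --psi 0.5 --plasticity none --plasticity linear \
    --reps 20 --seed 1 --out grid.csv
```

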