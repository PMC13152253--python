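# mrmediate

Two-sample Mendelian randomisation (MR) of maternal exposures on pregnancy
outcomes, with maternal-specific genetic-effect partitioning, a
pleiotropy-robust estimator panel, and two-step MR mediation through
intermediate traits — built for the question of whether maternal BMI
causally affects birth weight, placental weight, gestational duration and
pre-eclampsia risk, and whether immune-related blood counts (basophil,
eosinophil, lymphocyte, monocyte, neutrophil, platelet) mediate those
effects.

The package is aimed at genetic epidemiologists working from GWAS summary
statistics. It takes tab-separated per-SNP association tables, prepares
instruments (genome-wide significance filtering, greedy LD clumping, allele
harmonization with palindromic-SNP handling), and estimates causal effects.

## Models

**Per-SNP Wald ratio.** For SNP *j* with exposure association β̂ˣⱼ and
outcome association β̂ʸⱼ, the ratio estimate is β̂ʸⱼ/β̂ˣⱼ with first-order
SE σʸⱼ/|β̂ˣⱼ|.

**IVW with multiplicative random effects** (the headline estimator): with
weights wⱼ = 1/σʸⱼ²,

    θ̂ = Σ wⱼ β̂ˣⱼ β̂ʸⱼ / Σ wⱼ (β̂ˣⱼ)²,

the slope of the zero-intercept weighted regression of β̂ʸ on β̂ˣ. The
fixed-effects SE is inflated by √(Q/(n−1)) when Cochran's Q exceeds its
degrees of freedom. The sensitivity panel adds MR-Egger (free intercept;
the intercept tests directional pleiotropy), the weighted median, and
simple/weighted mode estimators, each with different validity assumptions
under horizontal pleiotropy.

**Maternal-specific effects (WLM).** Unadjusted maternal/fetal duo GWAS
effects are transformed by the weighted linear model
β̂ᴹᵃᵗᵉʳⁿᵃˡᴬᵈʲ = (4/3)β̂ᴹᵃᵗᵉʳⁿᵃˡ − (2/3)β̂ᶠᵉᵗᵃˡ, which inverts the ½
allele-sharing contamination between the two genomes exactly.

**Two-step MR mediation.** With step-wise IVW estimates â (exposure →
mediator), b̂ (mediator → outcome, using the mediator's own instruments)
and the total effect, the indirect effect is âb̂ with delta-method SE
√(b̂²SE²ₐ + â²SE²ᵦ + SE²ₐSE²ᵦ); the direct effect is total − indirect with
SE √(SE²ₜₒₜₐₗ + SE²ᵢₙ𝒹ᵢᵣₑ𝒸ₜ). Mediation is assessed only when all three
step effects are nominally causal (p < 0.05).

A synthetic-data module generates GWAS summary statistics with known causal
structure (instrument effects, sampling noise scaled by allele frequency and
sample size, balanced/directional pleiotropy, allele-coding quirks,
mother–child allele sharing), so every pipeline stage is testable without
external data.

## Worked example

```python
from mrmediate import SimulationConfig, simulate_mediation_study, run_two_step

cfg = SimulationConfig(n_snps=120, n_mediator_snps=120,
                       theta_direct=0.2, a_effect=0.3, b_effect=0.5, seed=11)
exposure, mediator, outcome, truth = simulate_mediation_study(cfg)
res = run_two_step(exposure, mediator, outcome)
print(f"a = {res.steps.a:.3f}, b = {res.steps.b:.3f}, total = {res.steps.total:.3f}")
print(f"indirect = {res.indirect:.3f}, direct = {res.direct:.3f}")
```

prints

```
a = 0.295, b = 0.516, total = 0.342
indirect = 0.152, direct = 0.190
```

The generating truth is a = 0.3, b = 0.5, total = 0.2 + 0.3×0.5 = 0.35:
the two-step pipeline recovers the indirect effect (0.152 ≈ 0.15) and the
direct effect (0.190 ≈ 0.20) from summary statistics alone.

The same study can be run from the shell:

```sh
mrmediate simulate --out fix --seed 11 --n-snps 120 --n-mediator-snps 120 \
    --theta-direct 0.2 --a-effect 0.3 --b-effect 0.5
mrmediate mediate --exposure fix/exposure.tsv --mediator fix/mediator.tsv \
    --outcome fix/outcome.tsv --out mediation.json
mrmediate run --config run.yaml     # full analysis graph from YAML
```

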