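# mrpath

Two-sample Mendelian randomization (MR) for gut-microbiome → plasma-metabolite →
disease pathways, built around the design of MR studies that link microbial taxa
and circulating metabolites to myeloproliferative neoplasm (MPN) risk using only
GWAS summary statistics. It is aimed at genetic epidemiologists who want the
full pipeline — instrument selection, univariable and bidirectional MR,
sensitivity statistics, two-step mediation with the proportion mediated,
multivariable MR, and Bayesian colocalization — as tested, composable library
code, together with a summary-statistics simulator that knows its own ground
truth.

## The statistics

For SNP *j* with exposure association β̂<sub>xj</sub> (SE σ<sub>xj</sub>) and
outcome association β̂<sub>yj</sub> (SE σ<sub>yj</sub>):

* **Wald ratio** (1 SNP): β = β̂<sub>y</sub>/β̂<sub>x</sub>, SE σ<sub>y</sub>/|β̂<sub>x</sub>|.
* **IVW** (≥ 2 SNPs): β = Σw<sub>j</sub>β̂<sub>xj</sub>β̂<sub>yj</sub> / Σw<sub>j</sub>β̂²<sub>xj</sub>
  with w<sub>j</sub> = σ<sub>yj</sub><sup>−2</sup> — weighted least squares through the
  origin; the SE is inflated by √(Q/(J−1)) when Cochran's Q exceeds its degrees
  of freedom (multiplicative random effects, floored at the fixed-effect SE).
* **MR-Egger** (≥ 3 SNPs): the same regression with a free intercept; a non-zero
  intercept signals directional horizontal pleiotropy.
* **Two-step mediation**: with total effect β<sub>EO</sub>, exposure→mediator
  β<sub>EM</sub> and mediator→outcome β<sub>MO</sub>, the indirect effect is
  β<sub>EM</sub>·β<sub>MO</sub> and the proportion mediated is
  β<sub>M</sub> = β<sub>EM</sub>·β<sub>MO</sub>/β<sub>EO</sub>.
* **MVMR**: weighted regression of outcome betas on several exposures' beta
  columns (no intercept) for direct, mutually adjusted effects.
* **Colocalization**: per-SNP Wakefield log approximate Bayes factors
  0.5·[log(V/(V+W)) + z²W/(V+W)] combined under the five-hypothesis model
  (H0–H4); PPH4 > 0.75 flags a shared causal variant.

Binary outcomes are handled on the log-odds scale throughout; every estimate is
reported as beta, SE, p, OR = e<sup>β</sup> and 95% CI.

## Worked example

The package ships the published worked-example constants for the
*Eubacterium xylanophilum* group → {succinylcarnitine, lysine} → MPN pathway
(total-effect OR 0.49; taxon→metabolite IVW betas 0.046 and −0.029;
metabolite→MPN betas −2.244 and 6.868):

```python
from mrpath import make_mpn_fixture, two_step_mediation

fx = make_mpn_fixture()
res = two_step_mediation(fx.est_EO, fx.est_EM_succinylcarnitine,
                         fx.est_MO_succinylcarnitine)
print(f"total beta_EO = {res.beta_EO:.4f}, indirect = {res.indirect:.4f}, "
      f"direct = {res.direct:.4f}, proportion mediated = {res.proportion_pct:.1f}%")
```

```
total beta_EO = -0.7133, indirect = -0.1032, direct = -0.6101, proportion mediated = 14.5%
```

The lysine leg of the same fixture yields 27.9%. The same machinery runs on
simulated data with known causal structure:

```python
from mrpath import SimConfig, PipelineConfig, simulate, run_screen, run_mediation_chain

sim = simulate(SimConfig(seed=1, beta_EM_true=0.3, beta_MO_true=0.5,
                         beta_direct_true=0.35, gamma_sd=0.15, delta_sd=0.15))
config = PipelineConfig(exposures=[sim.exposure], mediators=[sim.mediator],
                        outcome=sim.outcome)
print(run_screen(config)[["method", "n_snp", "beta", "se", "pvalue"]].to_string(index=False))
chain = run_mediation_chain(config, sim.exposure, sim.mediator)
print(f"recovered proportion mediated: {chain.proportion_pct:.1f}% "
      f"(truth: {sim.truth.proportion_mediated:.0%})")
```

```
method  n_snp     beta       se       pvalue
   ivw     11 0.561646 0.114229 8.795737e-07
recovered proportion mediated: 45.9% (truth: 30%)
```

A single replicate of the proportion is noisy (the outcome emulates a rare
disease with ~0.27% case fraction); averaged over 200 replicates it recovers
the truth within a few percentage points — that check is part of the test
suite. A `mrpath` console script exposes the same steps as `simulate`,
`screen`, `mediate`, `mvmr`, `coloc` and `report` subcommands.

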