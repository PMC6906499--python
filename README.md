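# targetodds

Probabilistic models of drug-target identification and development success.

## The problem

Most drug development programmes fail in clinical phases for lack of
efficacy — an expensive demonstration that the wrong protein target was
paired with the disease. `targetodds` implements a compact probabilistic
framework for reasoning about why: it models every target-disease
hypothesis as a cell in a matrix of `N_G = 20,000` protein-coding genes ×
`N_D = 10,000` common diseases, with independent *causal* and *druggable*
labels (`C̄ = 100` causal genes per disease, `N_T = 4,000` druggable genes).
The prior probability that a randomly chosen pairing is a true, druggable
target is then a simple ratio, and Bayes' rule converts that prior plus an
experiment's error rates into the false discovery rate of a declared
preclinical success:

    FDR = α(1−γ) / [(1−β)γ + α(1−γ)]

With the orthodox preclinical convention (α = 0.05, power 0.8) and a prior
of γ = 0.005 the FDR is **92.6%** — close to the observed ~96% failure rate
of drug development. Swapping preclinical studies for genome-wide
association studies (α = 5×10⁻⁸, every target interrogated at once)
reverses the discovery odds. The package provides, as composable library
functions and a CLI:

- the confusion-table machinery and sample-space priors (`core`),
- the two-stage preclinical→clinical pipeline, forward
  (`S_o = S_pc·S_c`, clinical prior `γ_c = TDR_pc`) and inverse
  (back-calculating the priors implied by observed success rates)
  (`two_stage`),
- parallel-programme sizing and hypergeometric target-selection sampling
  (`portfolio`),
- repurposing arithmetic: diseases per target, shared causal genes,
  diseases needed (`repurposing`),
- binomial rediscovery and prospective target yield of GWAS (`gwas`),
- a seeded Monte-Carlo simulator of the whole sample space that replays
  every closed form as a random experiment (`simulate`).

It is aimed at anyone doing quantitative triage of target-identification
strategy: how many programmes to run, what a preclinical "success" is worth
as evidence, and what a well-powered GWAS should deliver.

## Worked example

```python
from targetodds import (
    SampleSpace, TestParams, StageParams,
    fdr, forward, back_calculate, n_programmes_needed,
)

# prior for a random pick from the druggable genome
space = SampleSpace()                     # 20,000 genes, 10,000 diseases
print(fdr(alpha=0.05, beta=0.2, gamma=0.005))   # 0.9255813953488371

# two-stage pipeline at the whole-genome prior
res = forward(StageParams(preclinical=TestParams(0.05, 0.2, 0.001)))
print(res.preclinical.tdr)                # 0.015763546798029555
print(res.s_o)                            # 0.0031375

# what do observed success rates (40% preclinical, 10% clinical) imply?
bc = back_calculate(s_pc=0.4, s_c=0.1)
print(bc.gamma_c, bc.alpha_pc)            # 0.06666666666666667 0.38620689655172413

# programmes needed for a 90% chance of one success at 2% per programme
print(n_programmes_needed(0.02, 0.9))     # 114
```

Only ~1.6% of preclinical "successes" at the whole-genome prior are true
(TDR 0.016), the overall success rate composes to 0.003, and the observed
industry success rates imply that preclinical pipelines are only ~7-fold
enriched over a random pick — with an effective false-positive rate of 0.39.

The same numbers from the shell:

```console
$ targetodds fdr --alpha 0.05 --beta 0.2 --gamma 0.005 --human
FDR = 92.6%
{
  "tp": 0.004,
  "fp": 0.04975,
  ...
  "fdr": 0.9255813953488371
}
$ targetodds portfolio --ps 0.02 --confidence 0.9
{
  "n_programmes_needed": 114,
  ...
}
```

Other subcommands: `two-stage`, `backcalc`, `table4` (the 12-scenario
orthodox-vs-genomic sweep, JSON or CSV), `repurposing`, `gwas`, and
`simulate` (Monte-Carlo replay with `--seed`, `--replicates`, `--mode`).
Scenario defaults can be overridden with a YAML/JSON config (see
`targetodds.config`).

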