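# Methods

## The sample space

All calculations live on a matrix of unique gene–disease pairings: rows are
the `N_G = 20,000` protein-coding genes, columns the `N_D = 10,000` common
human diseases of the "disease-ome". A pairing is *causal* if perturbing the
gene's protein alters the disease, and involves a *druggable* gene if the
protein can be engaged pharmacologically (`N_T = 4,000` such genes). With an
average of `C̄ = 100` causal genes per disease, the prior probability that a
random pairing is causal is

    P_C = C̄ / N_G = 0.005,

independent of `N_D`. Causality and druggability are modelled as independent
labels, so `P_CT = P_C · N_T/N_G = 0.001` over the whole genome, rising to
`P_C = 0.005` when the sampling frame is restricted to the druggable genome.
For a single disease with `C` causal genes the genome partitions into
`C·N_T/N_G` causal-and-druggable genes (20 at the base case), `C` minus that
causal-only, `(N_G−C)·N_T/N_G` druggable-only, and the rest.

Model assumptions worth keeping in mind: one gene, one protein, one
function; causal assignments independent across diseases; druggability
independent of causality; and (for the pipeline model) incorrect target
selection as the only cause of clinical failure. These are deliberate
simplifications that make the arithmetic exact.

## Discovery as a Bayes-rule confusion table

A discovery experiment tests each pairing with false-positive rate `α` and
power `1−β` against a prior truth fraction `γ`. The population rates of the
four outcomes are `TP = γ(1−β)`, `FP = α(1−γ)`, `FN = γβ`,
`TN = (1−α)(1−γ)`, and the false discovery rate among declared successes is

    FDR = α(1−γ) / [(1−β)γ + α(1−γ)].

At `γ = 0.005`, `α = 0.05`, `1−β = 0.8` this gives 92.6%; at `γ = 0.001`,
98.4%. When `α = 0` and `γ(1−β) = 0` the TDR/FDR are 0/0 and the code raises
`UndefinedRateError` rather than returning a sentinel.

## The two-stage pipeline

Preclinical (stage 1) feeds clinical (stage 2): every declared stage-1
success enters the clinic, so the clinical prior is the preclinical TDR,
`γ_c = TDR_pc`. Success rates compose as `S_o = S_pc · S_c`, and the clinical
TDR admits the odds factorisation

    TDR_c = 1 / [1 + (α_c/(1−β_c)) (α_pc/(1−β_pc)) ((1−γ_pc)/γ_pc)],

whose equivalence with composing two confusion tables is verified
numerically to 1e−12 across randomised parameters (the algebraic derivation
is straightforward but the identity is asserted rather than assumed).

The inverse problem — observed `S_pc`, `S_c` to implied `γ_c`, `γ_pc`,
`α_pc` — is linear in `γ` and solved in closed form, which makes the
feasibility region explicit: `S_c < α_c` or `1−β_c ≤ α_c` admit no valid
prior and raise `InfeasibleScenarioError` naming the violated inequality;
nothing is silently clipped. The default scenario sweep evaluates twelve
labelled scenarios: whole-genome and druggable-genome priors, `C̄ ∈ {10,
100, 1000}`, orthodox (`α = 0.05`) and genome-wide-significance
(`α = 5×10⁻⁸`) screening, with power 0.8 and `α_c = 0.05` throughout.

## Portfolios and target selection

With per-programme success probability `p_s`, the number of independent
programmes needed for at least one success solves `1−(1−p_s)^N ≥ c`. Two
integerisations are offered: `rule="ceil"` (default) returns the smallest N
meeting the threshold — the guarantee semantics — while `rule="round"`
rounds the real-valued crossing point, the "on average" reading under which
an evens chance at `p_s = 0.02` is conventionally quoted as 34 programmes
(the strict guarantee is 35; `0.98³⁴ = 0.503`).

Drawing `N` targets without replacement from a frame of `F` candidates
containing `C` causal ones gives a hypergeometric count of causal targets,
with mean `N·C/F` and the finite-population SD; pmfs are evaluated through
scipy's log-space implementation, so frames of thousands of genes are safe.
The development-success scenario model assumes each drawn causal target
tests positive with probability `1−β`, each non-causal with `α`, one
nominal positive chosen uniformly advances, and success means it was causal:

    P(success) = E[ T / (T+F) ],  0 when no positives,

computed by exact summation over the joint
(causal-drawn) × (true-positive) × (false-positive) distribution. The
uniform tie-break is a modelling choice (recorded as such) and the exact sum
is validated against an independent draw–test–advance simulation across a
grid of scenarios at 3 Monte-Carlo standard errors.

## Repurposing

The number of diseases influenced by one target is binomial over the
disease-ome: mean `P_C · N_D = 50`, SD `√(P_C(1−P_C)N_D) ≈ 7.05`. The 95%
interval is reported two ways: the normal approximation mean ± 1.96 SD
rounded to integers ([36, 64], the conventional presentation) and the exact
binomial equal-tail interval ([37, 64]). Tail probabilities are likewise
reported from both the exact binomial and the normal approximation; at the
base case both round to "1 in 1000" for 28 or fewer diseases.

The probability that `k` randomly constituted diseases share no causal gene
is the chained product of hypergeometric avoidance terms
`∏_{j=1}^{k−1} C(N_G − jC̄, C̄)/C(N_G, C̄)`, evaluated as sums of
log-binomial coefficients. Conditioning each new disease on exactly `jC̄`
distinct accumulated genes is a sequential approximation (it assumes the
earlier diseases did not overlap within the conditioning event), accurate
when `C̄ ≪ N_G`; it is implemented exactly in this form, and the simulator's
exchangeable draw agrees with it within Monte-Carlo error for small `k`.

## GWAS rediscovery and yield

Per-locus detection is Bernoulli with homogeneous power `1−β` (a
heterogeneous-powers variant uses the Poisson-binomial mean and variance).
Rediscovery of `n` licensed targets is binomial; across `K` studied diseases
with `n̄` targets each, `E_T = K(1−β)n̄` with `SD = √(β(1−β)n̄K)`. The
identity inverts to estimate average historical power:
`1−β = E_T/(n̄K)`, rejecting (not clipping) observed counts that imply
power above 1. Prospective yield for one disease uses the
causal-and-druggable gene count from the therapeutic partition as the
binomial size.

## The simulator

`generate_world` materialises the assumed structure directly: fixed-count
mode draws exactly `C` causal genes per disease uniformly without
replacement (the way the worked examples reason); Bernoulli mode makes every
cell independently causal at rate `C̄/N_G`. Both modes share analytic
expectations at matched `C̄`. Druggable genes are a uniform `N_T`-subset,
independent of causality. Discovery, the two-stage pipeline, disease overlap
and portfolio selection are then replayed as literal random experiments and
summarised with binomial standard errors; the package's core stochastic
property is that every replay lands within 3 SE of its closed form.

Randomness derives from one root seed; each operation consumes a child
stream keyed by a fixed operation code, so changing one experiment's
replicate count does not reshuffle another's draws, and identical
configurations are bit-identical.

Default simulated worlds use 100 diseases (2×10⁶ pairings) rather than the
full 10,000: every quantity the simulator validates is provably invariant to
the disease count, and that invariance is itself asserted in the tests.
Replicate counts in the validation suite range from 2×10⁴ (unit tests) to
10⁵–10⁶ (end-to-end agreement checks), sized so the full suite runs in well
under a minute of simulation time on one core.

### What the generator does and does not emulate

It reproduces the model's own statistical world — independent causal
assignment, independent druggability, per-test Bernoulli detection — and
nothing more. Real genomes violate essentially every simplification:
pleiotropy is correlated across related diseases, causal-gene counts vary by
disease, druggability clusters in protein families, GWAS detections at
linked loci are not independent, and power varies per locus with allele
frequency and effect size. Passing tests therefore certify that the closed
forms correctly describe the stated model, not that the model describes
biology; the numbers are order-of-magnitude reasoning tools.

## Numerical choices

- All internal computation at full double precision; presentation rounding
  (92.6%, 0.016, …) happens only in the reporting layer via per-column
  precision maps.
- `C̄` may be non-integer in analytic formulas (it is an average); the
  simulator and pmf operations require integer counts and round or reject as
  documented.
- Hypergeometric and binomial-coefficient arithmetic in log space
  (scipy / gammaln).
- 0/0 discovery rates and infeasible back-calculations raise typed errors;
  no sentinels, no clipping.
- The back-calculated `γ_pc` is kept at full precision (1/30 at the
  reference inputs); quoting it as 0.03335 reflects rounding `γ_c` to
  0.0667 first, which the reporting layer reproduces but the library does
  not propagate.

## Known limitations

- The shared-gene chain is the sequential approximation described above,
  not the exact exchangeable-model probability.
- The development-success scenario model's uniform-choice tie-break is one
  of several defensible rules; alternatives can be compared against the
  simulator, which is the only oracle for this quantity.
- Scenario sweeps beyond the twelve default rows and the in-text anchor
  cells are unvalidated extrapolations of the same closed forms.
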