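"""Monte-Carlo engine: synthesise the gene x disease causal world and replay
every closed-form calculation stochastically.

The generator materialises the assumed statistical structure of the sample
space — a binary causal incidence matrix with either exactly C causal genes
per disease (fixed-count mode, the way the worked examples reason) or
independent Bernoulli(C_bar/N_G) cells, plus an independent druggable label
per gene — and then re-enacts discovery, the two-stage pipeline, disease
overlap and portfolio selection as random experiments.  Each estimate carries
a Monte-Carlo standard error so agreement with the analytic value can be
judged on the 3-SE scale.

Randomness derives from a single root seed: each operation draws from a
child stream keyed by a fixed per-operation code, so changing the replicate
count of one experiment does not reshuffle another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import SampleSpace, TestParams
from .portfolio import PortfolioSpec
from .two_stage import StageParams

__all__ = [
    "SimulationConfig",
    "CausalMatrix",
    "EmpiricalRate",
    "EmpiricalConfusion",
    "EmpiricalTwoStage",
    "generate_world",
    "simulate_discovery",
    "simulate_two_stage",
    "simulate_shared_targets",
    "simulate_portfolio",
]

# fixed per-operation stream codes (keep stable: they define reproducibility)
_STREAM_WORLD = 1
_STREAM_DISCOVERY = 2
_STREAM_TWO_STAGE = 3
_STREAM_SHARED = 4
_STREAM_PORTFOLIO = 5


@dataclass(frozen=True)
class SimulationConfig:
    replicates: int = 1
    seed: int = 0
    mode: str = "fixed-count"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in ("fixed-count", "bernoulli"):
            raise ValueError("mode must be 'fixed-count' or 'bernoulli'")

    def stream(self, opcode: int) -> np.random.Generator:
        """Child random stream for one operation, derived from the root seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, opcode]))


@dataclass(frozen=True)
class EmpiricalRate:
    """A Monte-Carlo frequency with its binomial standard error."""

    value: float
    se: float
    n: int

    def within(self, analytic: float, n_se: float = 3.0) -> bool:
        return abs(self.value - analytic) <= n_se * max(self.se, 1e-300)


def _rate(successes: float, trials: int) -> EmpiricalRate:
    if trials == 0:
        return EmpiricalRate(value=math.nan, se=math.nan, n=0)
    p = successes / trials
    return EmpiricalRate(value=p, se=math.sqrt(max(p * (1.0 - p), 0.0) / trials), n=trials)


@dataclass(frozen=True)
class CausalMatrix:
    """A realised world: causal incidence (genes x diseases) and druggable labels."""

    causal: np.ndarray
    druggable: np.ndarray
    space: SampleSpace
    seed: int

    @property
    def gamma(self) -> float:
        """Realised fraction of causal gene-disease pairings."""
        return float(self.causal.mean())

    @property
    def gamma_causal_druggable(self) -> float:
        """Realised fraction of pairings that are causal and druggable."""
        return float(self.causal[self.druggable].sum() / self.causal.size)


def generate_world(space: SampleSpace, config: SimulationConfig) -> CausalMatrix:
    """Draw one causal world.

    Fixed-count mode assigns exactly ``round(causal_per_disease)`` causal
    genes per disease, uniformly without replacement; Bernoulli mode makes
    every cell causal independently with probability
    ``causal_per_disease / n_genes``.  Druggable genes are a uniform
    ``n_druggable``-subset, drawn independently of causality.
    """
    rng = config.stream(_STREAM_WORLD)
    n_g, n_d = space.n_genes, space.n_diseases
    causal = np.zeros((n_g, n_d), dtype=bool)
    if config.mode == "fixed-count":
        c = int(round(space.causal_per_disease))
        if c > n_g:
            raise ValueError("causal count per disease exceeds the genome")
        for d in range(n_d):
            causal[rng.choice(n_g, size=c, replace=False), d] = True
    else:
        causal = rng.random((n_g, n_d)) < (space.causal_per_disease / n_g)
    druggable = np.zeros(n_g, dtype=bool)
    druggable[rng.choice(n_g, size=space.n_druggable, replace=False)] = True
    return CausalMatrix(causal=causal, druggable=druggable, space=space, seed=config.seed)


@dataclass(frozen=True)
class EmpiricalConfusion:
    """Stochastic replay of the confusion table with standard errors."""

    tp: float
    fp: float
    tn: float
    fn: float
    declared_success: EmpiricalRate
    tdr: EmpiricalRate
    fdr: EmpiricalRate
    n_pairs: int


def simulate_discovery(
    world: CausalMatrix, params: TestParams, config: SimulationConfig
) -> EmpiricalConfusion:
    """Test every gene-disease pair once per replicate and tabulate outcomes.

    A causal pair is declared positive with probability ``1 - beta``, a
    non-causal pair with probability ``alpha``; ``params.gamma`` is ignored
    because the truth fraction is whatever the world realises.
    """
    rng = config.stream(_STREAM_DISCOVERY)
    causal = world.causal.ravel()
    n = causal.size
    n_causal = int(causal.sum())
    tp = fp = 0
    for _ in range(config.replicates):
        u = rng.random(n)
        positive = np.where(causal, u < 1.0 - params.beta, u < params.alpha)
        tp += int(np.count_nonzero(positive & causal))
        fp += int(np.count_nonzero(positive & ~causal))
    total = n * config.replicates
    total_causal = n_causal * config.replicates
    fn = total_causal - tp
    tn = (total - total_causal) - fp
    n_pos = tp + fp
    return EmpiricalConfusion(
        tp=tp / total,
        fp=fp / total,
        tn=tn / total,
        fn=fn / total,
        declared_success=_rate(n_pos, total),
        tdr=_rate(tp, n_pos),
        fdr=_rate(fp, n_pos),
        n_pairs=total,
    )


@dataclass(frozen=True)
class EmpiricalTwoStage:
    """Stochastic replay of the two-stage pipeline."""

    s_pc: EmpiricalRate
    s_c: EmpiricalRate
    s_o: EmpiricalRate
    gamma_c: EmpiricalRate


def simulate_two_stage(
    world: CausalMatrix, stage: StageParams, config: SimulationConfig
) -> EmpiricalTwoStage:
    """Replay preclinical discovery then clinical evaluation of its positives.

    Stage 2 is applied only to pairs declared positive in stage 1; the
    empirical ``gamma_c`` is the causal fraction among stage-1 positives.
    """
    rng = config.stream(_STREAM_TWO_STAGE)
    causal = world.causal.ravel()
    n = causal.size
    pre = stage.preclinical
    n1 = n2 = 0
    n1_causal = 0
    for _ in range(config.replicates):
        u1 = rng.random(n)
        pos1 = np.where(causal, u1 < 1.0 - pre.beta, u1 < pre.alpha)
        causal_pos1 = causal[pos1]
        u2 = rng.random(causal_pos1.size)
        pos2 = np.where(
            causal_pos1, u2 < 1.0 - stage.clinical_beta, u2 < stage.clinical_alpha
        )
        n1 += int(causal_pos1.size)
        n1_causal += int(causal_pos1.sum())
        n2 += int(np.count_nonzero(pos2))
    total = n * config.replicates
    return EmpiricalTwoStage(
        s_pc=_rate(n1, total),
        s_c=_rate(n2, n1),
        s_o=_rate(n2, total),
        gamma_c=_rate(n1_causal, n1),
    )


def simulate_shared_targets(
    space: SampleSpace, k: int, config: SimulationConfig
) -> EmpiricalRate:
    """Empirical probability that k independent diseases share no causal gene.

    Each replicate draws k independent C-subsets of the genome and records
    whether their union has k*C distinct members.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return EmpiricalRate(value=1.0, se=0.0, n=config.replicates)
    rng = config.stream(_STREAM_SHARED)
    c = int(round(space.causal_per_disease))
    n_g = space.n_genes
    disjoint = 0
    for _ in range(config.replicates):
        genes = np.concatenate([rng.choice(n_g, size=c, replace=False) for _ in range(k)])
        if np.unique(genes).size == k * c:
            disjoint += 1
    return _rate(disjoint, config.replicates)


def simulate_portfolio(
    spec: PortfolioSpec, alpha: float, beta: float, config: SimulationConfig
) -> EmpiricalRate:
    """Empirical probability that the advanced target is truly causal.

    Vectorised draw-test-advance replay: a hypergeometric number of causal
    targets enters each replicate's portfolio, true and false positives are
    binomial, one positive is chosen uniformly, and the replicate scores a
    success when that choice is causal (replicates with no positives score a
    failure).
    """
    rng = config.stream(_STREAM_PORTFOLIO)
    reps = config.replicates
    n, c, f = spec.n_programmes, spec.n_causal_in_frame, spec.frame_size
    a = rng.hypergeometric(c, f - c, n, size=reps)
    t = rng.binomial(a, 1.0 - beta)
    fpos = rng.binomial(n - a, alpha)
    total_pos = t + fpos
    any_pos = total_pos > 0
    # uniform choice among positives: success probability t / (t + f)
    u = rng.random(reps)
    success = any_pos & (u * total_pos < t)
    return _rate(int(success.sum()), reps)
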