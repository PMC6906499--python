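"""Repurposing probabilities: how widely a target's effects spread across diseases.

Three calculations under the independence model of the gene x disease sample
space:

- how many diseases a single target is expected to influence (binomial over
  the disease-ome),
- the probability that a set of k randomly constituted diseases shares no
  causal gene (a chained hypergeometric product), and
- how many diseases must be examined to find, with given confidence, at least
  one affected by a particular target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from scipy.special import gammaln

from .core import SampleSpace, p_causal
from .portfolio import n_programmes_needed

__all__ = [
    "DiseasesPerTarget",
    "diseases_per_target",
    "prob_no_shared_gene_chain",
    "diseases_needed",
]


@dataclass(frozen=True)
class DiseasesPerTarget:
    """Distribution summary of the number of diseases influenced by one target.

    ``interval_95`` is the normal-approximation central 95% interval
    (mean +/- 1.96 SD, rounded to integers); ``interval_95_exact`` the exact
    binomial equal-tail interval, reported alongside for transparency.
    """

    mean: float
    sd: float
    interval_95: tuple[int, int]
    interval_95_exact: tuple[int, int]
    n_diseases: int
    p_affected: float

    def tail_prob(self, count: int) -> tuple[float, float]:
        """P(X <= count): exact binomial and normal-approximation values."""
        exact = float(stats.binom.cdf(count, self.n_diseases, self.p_affected))
        if self.sd > 0:
            normal = float(stats.norm.cdf(count, loc=self.mean, scale=self.sd))
        else:
            normal = float(count >= self.mean)
        return exact, normal


def diseases_per_target(space: SampleSpace) -> DiseasesPerTarget:
    """Number of diseases influenced by perturbing one target.

    Each of the ``n_diseases`` columns is causally linked to the target
    independently with probability ``p_causal``, so the count is binomial
    with mean ``p n_d`` and SD ``sqrt(p (1-p) n_d)``.  At the base case
    (p = 0.005, 10,000 diseases) the mean is 50 with SD ~7, and the 95%
    interval is [36, 64]: even a perfectly specific medicine is expected to
    influence dozens of conditions.
    """
    p = p_causal(space)
    n_d = space.n_diseases
    mean = p * n_d
    sd = math.sqrt(p * (1.0 - p) * n_d)
    lo = int(round(mean - 1.96 * sd))
    hi = int(round(mean + 1.96 * sd))
    if p in (0.0, 1.0):
        exact = (int(mean), int(mean))
    else:
        lo_e, hi_e = stats.binom.interval(0.95, n_d, p)
        exact = (int(lo_e), int(hi_e))
    return DiseasesPerTarget(
        mean=mean,
        sd=sd,
        interval_95=(lo, hi),
        interval_95_exact=exact,
        n_diseases=n_d,
        p_affected=p,
    )


def _log_binom(n: float, k: float) -> float:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def prob_no_shared_gene_chain(space: SampleSpace, k: int) -> float:
    """Probability that k randomly constituted diseases share no causal gene.

    Disease j+1's C causal genes must avoid the j*C genes accumulated by the
    previous diseases, an event with hypergeometric probability
    ``C(N_G - j*C, C) / C(N_G, C)``; the chain multiplies these over
    j = 1..k-1.  Conditioning on exactly ``j*C`` distinct prior genes (i.e.
    on the earlier diseases themselves not overlapping) makes this the
    standard sequential approximation rather than the exact exchangeable
    probability; the two agree closely when C << N_G.  Evaluated as a sum of
    log binomial coefficients for stability.  Once the accumulated genes
    exhaust the genome the probability is 0 by pigeonhole.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    c = space.causal_per_disease
    n_g = space.n_genes
    log_p = 0.0
    log_denom = _log_binom(n_g, c)
    for j in range(1, k):
        remaining = n_g - j * c
        if remaining < c:
            return 0.0
        log_p += _log_binom(remaining, c) - log_denom
    return math.exp(log_p)


def diseases_needed(p_affected: float, confidence: float = 0.9) -> int:
    """Diseases to study for a given chance of finding one affected by a target.

    The smallest k with ``1 - (1 - p_affected)**k >= confidence``; the same
    at-least-one-success kernel as parallel-programme sizing.  At
    p = 0.005 and 90% confidence, 460 diseases.
    """
    return n_programmes_needed(p_affected, confidence, rule="ceil")
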