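"""Parallel development programmes and target-selection sampling.

Two questions about running many programmes at once:

1. If each independent programme succeeds with probability ``p_s``, how many
   must run in parallel for a given chance of at least one success?
2. If ``n_programmes`` targets are drawn without replacement from a candidate
   frame containing a handful of causal targets, how many causal targets land
   in the drawn set (hypergeometric), and what is the chance that the single
   nominally-positive target advanced to the clinic is actually causal?
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PortfolioSpec",
    "n_programmes_exact",
    "n_programmes_needed",
    "causal_in_sample_pmf",
    "expected_causal_in_sample",
    "development_success_prob",
    "expected_true_vs_false_positives",
    "tp_fp_breakeven_frame",
]


@dataclass(frozen=True)
class PortfolioSpec:
    """A portfolio of parallel programmes drawn from a candidate target frame.

    ``frame_size`` is the candidate pool (e.g. the 4,000-gene druggable
    genome or a curated subset), ``n_causal_in_frame`` how many of those are
    truly causal for the disease, and ``n_programmes`` how many distinct
    targets are taken into development.
    """

    frame_size: int
    n_causal_in_frame: int
    n_programmes: int
    per_programme_success: float = 0.02

    def __post_init__(self) -> None:
        if self.frame_size <= 0:
            raise ValueError("frame_size must be positive")
        if not 0 <= self.n_causal_in_frame <= self.frame_size:
            raise ValueError("n_causal_in_frame must lie in [0, frame_size]")
        if not 1 <= self.n_programmes <= self.frame_size:
            raise ValueError("n_programmes must lie in [1, frame_size]")
        if not 0.0 <= self.per_programme_success <= 1.0:
            raise ValueError("per_programme_success must lie in [0, 1]")


def n_programmes_exact(p_s: float, confidence: float) -> float:
    """Real-valued solution N* of ``1 - (1 - p_s)**N = confidence``."""
    if not 0.0 < p_s < 1.0:
        raise ValueError("p_s must lie strictly in (0, 1); confidence is unattainable at p_s=0")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly in (0, 1)")
    return math.log(1.0 - confidence) / math.log(1.0 - p_s)


def n_programmes_needed(p_s: float, confidence: float, *, rule: str = "ceil") -> int:
    """Number of independent programmes for at least one success.

    With per-programme success probability ``p_s``, the probability that all
    ``N`` programmes fail is ``(1 - p_s)**N``.  ``rule='ceil'`` (default)
    returns the smallest integer N with ``1 - (1 - p_s)**N >= confidence``,
    i.e. a guarantee.  ``rule='round'`` rounds the real-valued crossing point
    to the nearest integer — the 'on average' reading, which for an evens
    chance at p_s = 0.02 reports 34 rather than the strict 35.
    """
    n_star = n_programmes_exact(p_s, confidence)
    if rule == "ceil":
        n = math.ceil(n_star)
        # guard against log round-off just above an exact integer crossing
        if n > 1 and 1.0 - (1.0 - p_s) ** (n - 1) >= confidence:
            n -= 1
        return max(n, 1)
    if rule == "round":
        return max(round(n_star), 1)
    raise ValueError(f"rule must be 'ceil' or 'round', got {rule!r}")


def causal_in_sample_pmf(spec: PortfolioSpec, a: int | np.ndarray) -> float | np.ndarray:
    """P(exactly ``a`` causal targets among the drawn programmes).

    Hypergeometric with population ``frame_size``, ``n_causal_in_frame``
    successes and ``n_programmes`` draws; evaluated in log space (scipy) so
    frames of thousands of genes do not overflow.  Out-of-support ``a``
    returns 0.
    """
    return stats.hypergeom.pmf(
        a, spec.frame_size, spec.n_causal_in_frame, spec.n_programmes
    )


def expected_causal_in_sample(spec: PortfolioSpec) -> tuple[float, float]:
    """Mean and SD of the number of causal targets in the drawn set.

    ``E(A) = N * C / frame`` with the finite-population SD
    ``sqrt(N C (frame - C)(frame - N) / (frame**2 (frame - 1)))``.
    """
    n, c, f = spec.n_programmes, spec.n_causal_in_frame, spec.frame_size
    mean = n * c / f
    if f == 1:
        return mean, 0.0
    var = n * c * (f - c) * (f - n) / (f**2 * (f - 1))
    return mean, math.sqrt(var)


def development_success_prob(spec: PortfolioSpec, alpha: float, beta: float) -> float:
    """Probability that the single advanced target is truly causal.

    Scenario model: draw ``n_programmes`` targets without replacement from
    the frame; each causal target in the draw tests positive with probability
    ``1 - beta`` and each non-causal one with probability ``alpha``; one
    nominal positive, chosen uniformly among the positives, advances to
    clinical development; development succeeds iff that target is causal.
    Computed by exact summation over the joint distribution of (causal drawn,
    true positives, false positives):

        P(success) = E[ T / (T + F) ]  with  P(success | no positives) = 0.
    """
    n, c, f = spec.n_programmes, spec.n_causal_in_frame, spec.frame_size
    a_vals = np.arange(max(0, n - (f - c)), min(c, n) + 1)
    p_a = stats.hypergeom.pmf(a_vals, f, c, n)
    total = 0.0
    for a, pa in zip(a_vals, p_a):
        if pa == 0.0:
            continue
        t_vals = np.arange(0, a + 1)
        p_t = stats.binom.pmf(t_vals, a, 1.0 - beta)
        f_vals = np.arange(0, n - a + 1)
        p_f = stats.binom.pmf(f_vals, n - a, alpha)
        # E[T/(T+F)] over the product distribution; the (t=0, f=0) cell is a miss
        tt, ff = np.meshgrid(t_vals, f_vals, indexing="ij")
        with np.errstate(invalid="ignore"):
            frac = np.where(tt + ff > 0, tt / np.maximum(tt + ff, 1), 0.0)
        total += pa * float(p_t @ frac @ p_f)
    return total


def expected_true_vs_false_positives(
    spec: PortfolioSpec, alpha: float, beta: float
) -> tuple[float, float]:
    """Expected true and false positives among the tested programmes.

    ``E[TP] = (1-beta) N C / frame`` and ``E[FP] = alpha N (1 - C/frame)``.
    """
    n, c, f = spec.n_programmes, spec.n_causal_in_frame, spec.frame_size
    p_causal_in_frame = c / f
    return (1.0 - beta) * n * p_causal_in_frame, alpha * n * (1.0 - p_causal_in_frame)


def tp_fp_breakeven_frame(n_causal: int, alpha: float, beta: float) -> float:
    """Frame size below which expected true positives exceed false positives.

    Solves ``(1-beta) C / F = alpha (1 - C/F)`` for F, giving
    ``F = C (1 - beta + alpha) / alpha``.  With C = 20 causal targets,
    alpha = 0.05 and power 0.8 the break-even frame is 340 targets — hence
    true positives dominate only in frames of a few hundred candidates.
    """
    if alpha <= 0.0:
        raise ValueError("alpha must be > 0 for a finite break-even frame")
    return n_causal * (1.0 - beta + alpha) / alpha
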