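"""Rediscovery of licensed drug targets by GWAS and prospective druggable yield.

A GWAS is abstracted as a battery of independent per-locus detection trials:
a truly causal locus is detected with power ``1 - beta``, so the number of
licensed targets a study rediscovers — and the number of new causal,
druggable targets it identifies — follows a binomial distribution.  Summing
over many diseases gives expected total rediscoveries, and the identity can
be inverted to estimate the average power of the GWAS literature from the
observed rediscovery count.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SampleSpace, therapeutic_partition

__all__ = [
    "RediscoverySpec",
    "rediscovery_pmf",
    "expected_rediscoveries",
    "expected_rediscoveries_hetero",
    "multi_disease_rediscoveries",
    "backcalc_power",
    "DruggableYield",
    "druggable_yield",
    "rediscovery_grid",
]


def _check_beta(beta: float) -> None:
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")


def _check_count(name: str, n: int) -> None:
    if not isinstance(n, (int, np.integer)):
        raise TypeError(f"{name} must be an integer count, got {n!r}")
    if n < 0:
        raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RediscoverySpec:
    """Inputs for rediscovery arithmetic across one or many GWAS.

    ``n_targets`` is the number of licensed targets available in one disease;
    ``n_gwas`` the number of diseases with a GWAS; ``mean_targets_per_disease``
    the average licensed-target count per studied disease (may be
    non-integer); ``total_rediscoveries`` an observed total, used when
    inverting for power.
    """

    n_targets: int = 3
    beta: float = 0.2
    n_gwas: int = 1
    mean_targets_per_disease: float = 3.0
    total_rediscoveries: int = 0

    def __post_init__(self) -> None:
        _check_count("n_targets", self.n_targets)
        _check_beta(self.beta)
        if self.n_gwas < 1:
            raise ValueError("n_gwas must be >= 1")
        if self.mean_targets_per_disease < 0:
            raise ValueError("mean_targets_per_disease must be non-negative")
        _check_count("total_rediscoveries", self.total_rediscoveries)


def rediscovery_pmf(n: int, beta: float) -> tuple[np.ndarray, float]:
    """Distribution of the number of detected targets among ``n`` true ones.

    Returns the binomial pmf over 0..n with per-locus success probability
    ``1 - beta``, plus P(at least one detection) = ``1 - beta**n``.
    """
    _check_count("n", n)
    _check_beta(beta)
    pmf = stats.binom.pmf(np.arange(n + 1), n, 1.0 - beta)
    return pmf, 1.0 - beta**n if n > 0 else 0.0


def expected_rediscoveries(n: int, beta: float) -> tuple[float, float]:
    """Mean ``n (1-beta)`` and SD ``sqrt(n beta (1-beta))`` of detections."""
    _check_count("n", n)
    _check_beta(beta)
    return n * (1.0 - beta), math.sqrt(n * beta * (1.0 - beta))


def expected_rediscoveries_hetero(betas: Sequence[float]) -> tuple[float, float]:
    """Mean and SD of detections with locus-specific powers (Poisson binomial).

    Per-locus type-2 errors may differ before collapsing to a common beta;
    the detection count is then Poisson-binomial with mean ``sum(1-beta_i)``
    and variance ``sum(beta_i (1-beta_i))``.
    """
    b = np.asarray(betas, dtype=float)
    if b.size and (b.min() < 0 or b.max() > 1):
        raise ValueError("all betas must lie in [0, 1]")
    return float((1.0 - b).sum()), float(np.sqrt((b * (1.0 - b)).sum()))


def multi_disease_rediscoveries(
    n_gwas: int, mean_targets: float, beta: float
) -> tuple[float, float]:
    """Expected total rediscoveries across ``n_gwas`` diseases.

    ``E_T = K (1-beta) n_bar`` and ``SD_T = sqrt(beta (1-beta) n_bar K)``,
    by summing independent per-disease binomials with ``N_K = K n_bar``
    targets in total.
    """
    if n_gwas < 1:
        raise ValueError("n_gwas must be >= 1")
    if mean_targets < 0:
        raise ValueError("mean_targets must be non-negative")
    _check_beta(beta)
    total = n_gwas * mean_targets
    return total * (1.0 - beta), math.sqrt(beta * (1.0 - beta) * total)


def backcalc_power(
    observed_rediscoveries: int, n_gwas: int, mean_targets: float
) -> float:
    """Average per-locus power implied by an observed rediscovery total.

    Inverts ``E_T = K (1-beta) n_bar`` to ``1 - beta = E_T / (n_bar K)``.
    With 74 rediscoveries over 315 disease terms and one target per disease
    on average, the implied power is ~0.23.

    Raises
    ------
    ValueError
        If the implied power exceeds 1 (more rediscoveries than targets),
        which signals inconsistent inputs rather than a clippable estimate.
    """
    _check_count("observed_rediscoveries", observed_rediscoveries)
    total = n_gwas * mean_targets
    if total <= 0:
        raise ValueError("n_gwas * mean_targets must be > 0")
    power = observed_rediscoveries / total
    if power > 1.0:
        raise ValueError(
            f"implied power {power} > 1: observed rediscoveries exceed available targets"
        )
    return power


@dataclass(frozen=True)
class DruggableYield:
    """Prospective yield of causal, druggable targets from one well-powered GWAS."""

    n_causal_druggable: float
    mean: float
    sd: float
    pmf: np.ndarray

    def prob_fewer_than(self, threshold: int) -> float:
        """P(X < threshold) from the exact binomial."""
        return float(self.pmf[: max(threshold, 0)].sum())


def druggable_yield(space: SampleSpace, beta: float) -> DruggableYield:
    """Causal, druggable targets a single GWAS of one disease should identify.

    The disease has ``C * N_T / N_G`` causal, druggable genes (the causal &
    druggable cell of the therapeutic-genome partition); each is detected
    independently with power ``1 - beta``, giving a binomial yield.  At the
    base case (C = 100, 4,000 druggable of 20,000 genes, power 0.8): 20
    available targets, 16 expected discoveries, SD 1.8.
    """
    _check_beta(beta)
    n_ct_real = therapeutic_partition(space)[0]
    n_ct = int(round(n_ct_real))
    pmf = stats.binom.pmf(np.arange(n_ct + 1), n_ct, 1.0 - beta)
    return DruggableYield(
        n_causal_druggable=n_ct_real,
        mean=n_ct * (1.0 - beta),
        sd=math.sqrt(n_ct * beta * (1.0 - beta)),
        pmf=pmf,
    )


def rediscovery_grid(
    n_gwas: int = 200,
    betas: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    mean_targets: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> pd.DataFrame:
    """Expected total rediscoveries over a beta x mean-targets grid.

    One row per (beta, n_bar) pair with columns ``beta``, ``mean_targets``,
    ``e_total`` and ``sd_total``, for a fixed number of GWAS.
    """
    rows = []
    for b in betas:
        for nbar in mean_targets:
            e, sd = multi_disease_rediscoveries(n_gwas, nbar, b)
            rows.append(
                {"beta": b, "mean_targets": nbar, "e_total": e, "sd_total": sd}
            )
    return pd.DataFrame(rows)
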