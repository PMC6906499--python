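"""Sample-space probabilities and Bayes-rule confusion machinery.

The model pictures all drug-development hypotheses as cells of a matrix whose
rows are the protein-coding genes of the genome and whose columns are common
human diseases.  A cell is *causal* if perturbing that gene's protein alters
the course of that disease, and *druggable* if the protein can be engaged by a
small molecule, peptide or antibody.  Under independence of the causal and
druggable labels, a handful of ratios fix the prior probability that a
randomly chosen gene-disease pairing is a viable drug target, and Bayes' rule
turns that prior plus a discovery experiment's error rates into the false
discovery rate (FDR) of a declared success.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SampleSpace",
    "TestParams",
    "ConfusionSummary",
    "UndefinedRateError",
    "p_causal",
    "p_druggable",
    "p_causal_druggable",
    "therapeutic_partition",
    "confusion",
    "fdr",
    "tdr",
]


class UndefinedRateError(ZeroDivisionError):
    """Raised when a discovery rate is 0/0 (no hypotheses declared positive)."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SampleSpace:
    """The structural parameters of the gene x disease hypothesis space.

    Parameters
    ----------
    n_genes
        Number of protein-coding genes (rows), default 20,000.
    n_diseases
        Number of common human diseases (columns), default 10,000.
    n_druggable
        Number of genes encoding druggable proteins, default 4,000.
    causal_per_disease
        Average number of causal genes per disease.  May be non-integer
        (it is an average); a per-disease count C reuses the same slot.
    """

    n_genes: int = 20_000
    n_diseases: int = 10_000
    n_druggable: int = 4_000
    causal_per_disease: float = 100.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_diseases <= 0 or self.n_druggable <= 0:
            raise ValueError("n_genes, n_diseases and n_druggable must be positive")
        if self.causal_per_disease < 0:
            raise ValueError("causal_per_disease must be non-negative")
        if self.n_druggable > self.n_genes:
            raise ValueError("n_druggable cannot exceed n_genes")
        if self.causal_per_disease > self.n_genes:
            raise ValueError("causal_per_disease cannot exceed n_genes")


@dataclass(frozen=True)
class TestParams:
    """Error rates of a discovery experiment plus the prior truth fraction.

    ``alpha`` is the per-hypothesis false-positive rate, ``beta`` the
    false-negative rate (power is ``1 - beta``), and ``gamma`` the prior
    fraction of tested hypotheses that are actually true.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        _check_prob("alpha", self.alpha)
        _check_prob("beta", self.beta)
        _check_prob("gamma", self.gamma)

    @property
    def power(self) -> float:
        return 1.0 - self.beta


@dataclass(frozen=True)
class ConfusionSummary:
    """Population rates of the four test outcomes plus derived discovery rates.

    All cells are rates over the tested hypothesis population, so
    ``tp + fp + tn + fn == 1``.  ``declared_success`` is the marginal rate of
    positive calls, ``tdr`` the true discovery rate (positive predictive
    value) and ``fdr = 1 - tdr`` the false discovery rate.
    """

    tp: float
    fp: float
    tn: float
    fn: float
    declared_success: float
    tdr: float
    fdr: float


def p_causal(space: SampleSpace) -> float:
    """Probability that a random gene-disease pairing is causal.

    Equals ``causal_per_disease / n_genes``; identically the ratio of causal
    pairings to all pairings, and therefore independent of ``n_diseases``.
    """
    return space.causal_per_disease / space.n_genes


def p_druggable(space: SampleSpace) -> float:
    """Probability that a random gene-disease pairing involves a druggable gene."""
    return space.n_druggable / space.n_genes


def p_causal_druggable(space: SampleSpace, *, restrict_to_druggable: bool = False) -> float:
    """Probability that a random pairing is both causal and druggable.

    With independent causal and druggable labels this is the product
    ``p_causal * p_druggable``.  If the sampling frame is restricted to the
    druggable genome (``restrict_to_druggable=True``) every selected gene is
    druggable by construction and the probability collapses to ``p_causal``.
    """
    if restrict_to_druggable:
        return p_causal(space)
    return p_causal(space) * p_druggable(space)


def therapeutic_partition(space: SampleSpace) -> tuple[float, float, float, float]:
    """Partition the genome of one disease by causal and druggable status.

    Returns expected gene counts ``(causal & druggable, causal & not
    druggable, druggable & not causal, neither)``, which sum to ``n_genes``.
    With C = 100 causal genes, 4,000 druggable among 20,000, the partition is
    (20, 80, 3980, 15920).
    """
    c = space.causal_per_disease
    frac_druggable = space.n_druggable / space.n_genes
    causal_druggable = c * frac_druggable
    causal_only = c - causal_druggable
    druggable_only = (space.n_genes - c) * frac_druggable
    neither = space.n_genes - c - druggable_only
    return (causal_druggable, causal_only, druggable_only, neither)


def confusion(params: TestParams) -> ConfusionSummary:
    """Population confusion rates of a discovery experiment, via Bayes' rule.

    The four cells are ``tp = gamma (1 - beta)``, ``fp = alpha (1 - gamma)``,
    ``fn = gamma beta`` and ``tn = (1 - alpha)(1 - gamma)``.  The false
    discovery rate among declared positives is

        fdr = alpha (1 - gamma) / [(1 - beta) gamma + alpha (1 - gamma)]

    Raises
    ------
    UndefinedRateError
        If no hypothesis is ever declared positive (``declared_success == 0``),
        in which case TDR and FDR are 0/0.
    """
    g, a, b = params.gamma, params.alpha, params.beta
    tp = g * (1.0 - b)
    fp = a * (1.0 - g)
    fn = g * b
    tn = (1.0 - a) * (1.0 - g)
    s = tp + fp
    if s == 0.0:
        raise UndefinedRateError(
            "declared-success rate is zero (alpha = 0 and gamma*(1-beta) = 0); "
            "TDR/FDR are undefined"
        )
    tdr_ = tp / s
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn, declared_success=s, tdr=tdr_, fdr=fp / s)


def fdr(alpha: float, beta: float, gamma: float) -> float:
    """False discovery rate for error rates (alpha, beta) and prior gamma."""
    return confusion(TestParams(alpha=alpha, beta=beta, gamma=gamma)).fdr


def tdr(alpha: float, beta: float, gamma: float) -> float:
    """True discovery rate (positive predictive value); complement of :func:`fdr`."""
    return confusion(TestParams(alpha=alpha, beta=beta, gamma=gamma)).tdr
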