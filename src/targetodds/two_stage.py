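"""Two-stage (preclinical then clinical) drug-development pipeline model.

Drug development is reduced to two linked screening stages.  Stage 1
(preclinical) tests target-disease hypotheses with error rates
``(alpha_pc, beta_pc)`` against a prior truth fraction ``gamma_pc``.  Every
declared preclinical success enters stage 2 (clinical), so the prior for the
clinical stage is the preclinical true discovery rate: ``gamma_c = TDR_pc``.
Observed success rates then decompose as ``S_o = S_pc * S_c``, and the whole
pipeline can be run forward (from priors and error rates to success rates) or
backward (from observed success rates to the implied priors and preclinical
false-positive rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfusionSummary, TestParams, confusion

__all__ = [
    "StageParams",
    "TwoStageResult",
    "BackCalcResult",
    "InfeasibleScenarioError",
    "forward",
    "tdr_clinical_closed_form",
    "back_calculate",
    "power_sweep",
    "enrichment_factor",
    "table4_sweep",
    "default_table4_scenarios",
    "TABLE4_COLUMNS",
]


class InfeasibleScenarioError(ValueError):
    """Raised when observed success rates are incompatible with the model."""


@dataclass(frozen=True)
class StageParams:
    """Error rates for both stages plus the preclinical prior.

    ``preclinical`` carries (alpha_pc, beta_pc, gamma_pc); the clinical prior
    is not free — it is determined by the preclinical true discovery rate —
    so only the clinical error rates are specified here.
    """

    preclinical: TestParams
    clinical_alpha: float = 0.05
    clinical_beta: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.clinical_alpha <= 1.0:
            raise ValueError("clinical_alpha must lie in [0, 1]")
        if not 0.0 <= self.clinical_beta <= 1.0:
            raise ValueError("clinical_beta must lie in [0, 1]")


@dataclass(frozen=True)
class TwoStageResult:
    """Linked confusion summaries of the two stages.

    ``gamma_c`` equals ``preclinical.tdr`` and ``s_o = s_pc * s_c``.
    """

    preclinical: ConfusionSummary
    clinical: ConfusionSummary
    gamma_c: float
    s_pc: float
    s_c: float
    s_o: float


@dataclass(frozen=True)
class BackCalcResult:
    """Priors and preclinical false-positive rate implied by observed success rates."""

    gamma_c: float
    gamma_pc: float
    alpha_pc: float
    fdr_pc: float


def forward(stage: StageParams) -> TwoStageResult:
    """Run the pipeline forward from priors and error rates to success rates.

    Stage-1 confusion rates come from ``(gamma_pc, alpha_pc, beta_pc)``; the
    clinical prior is set to the preclinical TDR and stage 2 is evaluated
    with ``(gamma_c, alpha_c, beta_c)``.
    """
    pre = confusion(stage.preclinical)
    gamma_c = pre.tdr
    clin = confusion(
        TestParams(alpha=stage.clinical_alpha, beta=stage.clinical_beta, gamma=gamma_c)
    )
    return TwoStageResult(
        preclinical=pre,
        clinical=clin,
        gamma_c=gamma_c,
        s_pc=pre.declared_success,
        s_c=clin.declared_success,
        s_o=pre.declared_success * clin.declared_success,
    )


def tdr_clinical_closed_form(
    gamma_pc: float, alpha_pc: float, beta_pc: float, alpha_c: float, beta_c: float
) -> float:
    """Clinical-stage TDR as a single odds expression.

    The clinical TDR factorises into the prior odds of a true relationship
    and the Bayes factors contributed by each stage::

        TDR_c = 1 / (1 + (alpha_c/(1-beta_c)) (alpha_pc/(1-beta_pc))
                         ((1-gamma_pc)/gamma_pc))

    Agrees with composing two confusion tables (``forward``) to machine
    precision; the factorised form makes explicit how stage stringency
    (alpha over power) and the prior odds each multiply into the result.
    """
    if gamma_pc <= 0.0:
        raise InfeasibleScenarioError("gamma_pc must be > 0 for the prior odds to exist")
    if beta_pc >= 1.0 or beta_c >= 1.0:
        raise InfeasibleScenarioError("stage powers must be > 0")
    odds = (
        (alpha_c / (1.0 - beta_c))
        * (alpha_pc / (1.0 - beta_pc))
        * ((1.0 - gamma_pc) / gamma_pc)
    )
    return 1.0 / (1.0 + odds)


def back_calculate(
    s_pc: float,
    s_c: float,
    alpha_c: float = 0.05,
    beta_c: float = 0.2,
    beta_pc: float = 0.2,
) -> BackCalcResult:
    """Infer the priors behind observed preclinical and clinical success rates.

    Solves the stage-2 success-rate identity ``S_c = gamma_c (1-beta_c) +
    alpha_c (1-gamma_c)`` for ``gamma_c``, then unwinds stage 1:

    - ``gamma_c  = (S_c - alpha_c) / ((1-beta_c) - alpha_c)``
    - ``gamma_pc = gamma_c * S_pc / (1 - beta_pc)``  (since gamma_c = TP_pc/S_pc)
    - ``alpha_pc = (S_pc - gamma_pc (1-beta_pc)) / (1 - gamma_pc)``
    - ``FDR_pc   = alpha_pc (1 - gamma_pc) / S_pc``

    The solution is exact (the system is linear in gamma), which also makes
    the feasibility region explicit: an observed ``S_c`` at or below
    ``alpha_c`` leaves no room for any true relationships.

    Raises
    ------
    InfeasibleScenarioError
        If ``S_c < alpha_c`` (success fully explained by false positives
        would need a negative prior) or ``1 - beta_c <= alpha_c`` (the
        clinical test is uninformative).
    """
    if not 0.0 < s_pc <= 1.0:
        raise InfeasibleScenarioError("s_pc must lie in (0, 1]")
    if 1.0 - beta_c <= alpha_c:
        raise InfeasibleScenarioError(
            f"clinical power must exceed alpha_c: 1-beta_c={1 - beta_c} <= alpha_c={alpha_c}"
        )
    if s_c < alpha_c:
        raise InfeasibleScenarioError(
            f"observed s_c={s_c} < alpha_c={alpha_c}: no non-negative gamma_c exists"
        )
    gamma_c = (s_c - alpha_c) / ((1.0 - beta_c) - alpha_c)
    gamma_pc = gamma_c * s_pc / (1.0 - beta_pc)
    if gamma_pc >= 1.0:
        raise InfeasibleScenarioError(
            f"implied gamma_pc={gamma_pc} >= 1: inputs inconsistent with the model"
        )
    alpha_pc = (s_pc - gamma_pc * (1.0 - beta_pc)) / (1.0 - gamma_pc)
    if not 0.0 <= alpha_pc <= 1.0:
        raise InfeasibleScenarioError(
            f"implied alpha_pc={alpha_pc} outside [0, 1]: inputs inconsistent with the model"
        )
    fdr_pc = alpha_pc * (1.0 - gamma_pc) / s_pc
    return BackCalcResult(gamma_c=gamma_c, gamma_pc=gamma_pc, alpha_pc=alpha_pc, fdr_pc=fdr_pc)


def power_sweep(
    s_pc: float = 0.4,
    s_c: float = 0.1,
    alpha_c: float = 0.05,
    beta_c: float = 0.2,
    powers: np.ndarray | None = None,
    step: float = 0.05,
) -> pd.DataFrame:
    """Back-calculated (gamma_pc, alpha_pc) across a range of preclinical powers.

    Sweeps preclinical power 1-beta_pc from 0.2 to 0.8 (inclusive) by
    ``step`` unless an explicit grid is supplied; columns are ``power``,
    ``gamma_pc``, ``alpha_pc`` and ``fdr_pc``.
    """
    if powers is None:
        powers = np.arange(0.2, 0.8 + step / 2, step)
    rows = []
    for p in np.asarray(powers, dtype=float):
        res = back_calculate(s_pc, s_c, alpha_c=alpha_c, beta_c=beta_c, beta_pc=1.0 - p)
        rows.append(
            {"power": p, "gamma_pc": res.gamma_pc, "alpha_pc": res.alpha_pc, "fdr_pc": res.fdr_pc}
        )
    return pd.DataFrame(rows)


def enrichment_factor(gamma_pc: float, baseline_gamma: float) -> float:
    """Fold-enrichment of an inferred prior over a random-pick baseline."""
    if baseline_gamma <= 0.0:
        raise ValueError("baseline_gamma must be > 0")
    return gamma_pc / baseline_gamma


TABLE4_COLUMNS = [
    "panel",
    "approach",
    "c_bar",
    "gamma_pc",
    "alpha_pc",
    "beta_pc",
    "fdr_pc",
    "s_pc",
    "tdr_pc",
    "alpha_c",
    "beta_c",
    "fdr_c",
    "tdr_c",
    "s_c",
    "s_o",
]

GWAS_ALPHA = 5e-8


def default_table4_scenarios(
    n_genes: int = 20_000, n_druggable: int = 4_000
) -> list[dict]:
    """The 12 standard a-priori scenarios contrasting orthodox and genomic screens.

    Panel ``a`` draws targets from the whole genome, so the prior is
    ``(c_bar/n_genes)(n_druggable/n_genes)``; panel ``b`` restricts the frame
    to the druggable genome, so the prior is ``c_bar/n_genes``.  Within each
    panel, c_bar in {10, 100, 1000} is crossed with the orthodox false-positive
    rate (0.05) and the genome-wide-significance rate (5e-8), power 0.8 at
    both stages and alpha_c = 0.05 throughout.
    """
    scenarios = []
    for panel in ("a", "b"):
        for alpha_pc, approach in ((0.05, "orthodox"), (GWAS_ALPHA, "genomic")):
            for c_bar in (10.0, 100.0, 1000.0):
                frac = c_bar / n_genes
                gamma_pc = frac * (n_druggable / n_genes) if panel == "a" else frac
                scenarios.append(
                    {
                        "panel": panel,
                        "approach": approach,
                        "c_bar": c_bar,
                        "params": StageParams(
                            preclinical=TestParams(alpha=alpha_pc, beta=0.2, gamma=gamma_pc),
                            clinical_alpha=0.05,
                            clinical_beta=0.2,
                        ),
                    }
                )
    return scenarios


def table4_sweep(scenarios: list[dict] | None = None) -> pd.DataFrame:
    """Evaluate the forward pipeline over a list of labelled scenarios.

    Each scenario is a dict with keys ``panel``, ``approach``, ``c_bar`` and
    ``params`` (a :class:`StageParams`).  Defaults to the 12 standard
    scenarios of :func:`default_table4_scenarios`.  Per-row failures are
    recorded in an ``error`` column rather than aborting the sweep.
    """
    if scenarios is None:
        scenarios = default_table4_scenarios()
    rows = []
    for sc in scenarios:
        sp: StageParams = sc["params"]
        row = {
            "panel": sc.get("panel", ""),
            "approach": sc.get("approach", ""),
            "c_bar": sc.get("c_bar", float("nan")),
            "gamma_pc": sp.preclinical.gamma,
            "alpha_pc": sp.preclinical.alpha,
            "beta_pc": sp.preclinical.beta,
            "alpha_c": sp.clinical_alpha,
            "beta_c": sp.clinical_beta,
        }
        try:
            res = forward(sp)
        except Exception as exc:  # collected, not fatal
            row.update({c: float("nan") for c in TABLE4_COLUMNS if c not in row})
            row["error"] = str(exc)
        else:
            row.update(
                fdr_pc=res.preclinical.fdr,
                s_pc=res.s_pc,
                tdr_pc=res.preclinical.tdr,
                fdr_c=res.clinical.fdr,
                tdr_c=res.clinical.tdr,
                s_c=res.s_c,
                s_o=res.s_o,
                error="",
            )
        rows.append(row)
    return pd.DataFrame(rows)[TABLE4_COLUMNS + ["error"]]
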