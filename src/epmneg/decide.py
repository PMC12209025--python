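"""Phenotype and anxiety-like-behaviour (ALB) grading from fitted evidence.

The classifier maps three pieces of upstream evidence to a behavioural
phenotype label and an ordinal ALB grade:

* the selected phase structure of the total-maze NEG (single vs dual phase),
* the arm-type (open - closed) contrast decision series within the cohort,
* the end-of-test exploration depth of each arm type.

Heuristics: no appreciable open-arm exploration is avoidant (maximal ALB);
open-arm exploration confined to a second phase after a closed-arm plateau
is delayed (moderately-low to moderately-high ALB by depth gap); open-arm
exploration present in the first phase is exploratory (low ALB when both
arm types are deeply and similarly explored, higher as the open arms lag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import ChangePointFit, ModelComparison
from .effects import DecisionSeries

__all__ = ["ALB_GRADES", "PhenotypeCall", "classify"]

#: Ordered ALB grades, lowest anxiety first.
ALB_GRADES = ("low", "moderately-low", "moderately-high", "high", "maximal")


@dataclass(frozen=True)
class PhenotypeCall:
    """Classifier output with the evidence that produced it."""

    label: str  # exploratory | delayed | avoidant | undecided
    alb_grade: str | None
    evidence: dict = field(default_factory=dict)


def _grade_from_gap(gap: float, grades: tuple[str, ...], cutpoints=(25.0, 50.0, 75.0)) -> str:
    """Grade by the end-of-test closed-minus-open NEG gap (percent points)."""
    idx = int(np.searchsorted(cutpoints, gap, side="right"))
    return grades[min(idx, len(grades) - 1)]


def classify(
    comparison: ModelComparison,
    arm_decisions: DecisionSeries,
    open_final: float,
    closed_final: float,
    total_fit: ChangePointFit | None = None,
    open_floor: float = 5.0,
    cutpoints: tuple[float, float, float] = (25.0, 50.0, 75.0),
) -> PhenotypeCall:
    """Classify one subject or cohort into a phenotype and ALB grade.

    Parameters
    ----------
    comparison : ModelComparison
        Phase-model selection for the total-maze NEG.
    arm_decisions : DecisionSeries
        SeXiT decisions for the open-minus-closed arm contrast over time.
    open_final, closed_final : float
        End-of-test NEG (percent) per arm type.
    total_fit : ChangePointFit, optional
        The selected total-maze fit; when it is a dual-phase fit, used to
        check that open exploration falls in the second phase.
    open_floor : float
        Open-arm NEG (percent) below which exploration counts as absent.
    cutpoints : tuple
        Depth-gap boundaries (percent points) between successive ALB grades.
    """
    gap = closed_final - open_final
    dual_selected = "2" in comparison.selected or "dual" in comparison.selected.lower()
    lm_states = arm_decisions.decision
    ever_not_equiv = bool(np.any(lm_states == "not-equivalent"))
    # Arm contrast equivalent from the start = arm-agnostic first phase.
    first_state = str(lm_states[0]) if lm_states.size else "equivalent"
    evidence = {
        "selected_model": comparison.selected,
        "dual_phase": dual_selected,
        "open_final": float(open_final),
        "closed_final": float(closed_final),
        "depth_gap": float(gap),
        "arm_contrast_ever_not_equivalent": ever_not_equiv,
        "arm_contrast_first_state": first_state,
    }

    if open_final <= open_floor:
        return PhenotypeCall("avoidant", "maximal", evidence)

    if dual_selected:
        # Open exploration should fall in the later phase: with a dual-phase
        # total fit, the arm contrast must have left equivalence in between.
        if not ever_not_equiv:
            return PhenotypeCall("undecided", None, evidence)
        grade = _grade_from_gap(
            min(max(gap, 0.0), cutpoints[-1] - 1e-9),
            ("moderately-low", "moderately-low", "moderately-high", "moderately-high"),
            cutpoints,
        )
        if total_fit is not None and total_fit.spec.n_phases == 2:
            infl = np.median(total_fit.inflexions(), axis=0)
            evidence["phase_inflexions"] = [float(v) for v in infl]
        return PhenotypeCall("delayed", grade, evidence)

    # Single-phase total growth: exploratory when the open arms took part in
    # the (only) phase; a persistently one-sided arm contrast with shallow
    # open depth contradicts that.
    grade = _grade_from_gap(max(gap, 0.0), ("low", "moderately-low", "moderately-high", "high"), cutpoints)
    return PhenotypeCall("exploratory", grade, evidence)
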