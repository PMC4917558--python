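"""Three-way decision circuit: plan units, decision variable, decision
result, and selective disinhibition of the execution layer.

Three alternative plans compete: go to the visual stimulus, go to the
auditory stimulus, or go to a fused multisensory target. Each plan carries
a position and a saliency. The unisensory saliencies are the memorized
reliabilities; the multisensory saliency is the spatiotemporal similarity
measure, and its position is the reliability-weighted average of the two
memorized positions (the ventriloquism percept). The decision variable is
the vector of saliencies, and a soft winner-take-all rule turns it into a
decision result whose three components sum to one:

    dr_av = s(sl_av * (dv_av - th_av))
    dr_v  = s(sl_av * (th_av - dv_av)) * s(sl_u * (dv_v - dv_a))
    dr_a  = s(sl_av * (th_av - dv_av)) * s(sl_u * (dv_a - dv_v))

with s the logistic function: the multisensory plan wins while similarity
exceeds the threshold, otherwise the more reliable unisensory plan wins.
The decision result gates the execution layer multiplicatively — only the
winning plan's position is released.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.special import expit

from .memory import MemoryState
from .similarity import ModelParams

__all__ = [
    "PlanUnit",
    "DecisionResult",
    "ExecutionSet",
    "build_plans",
    "decision_variable",
    "decision_result",
    "execution_gate",
]


@dataclass(frozen=True)
class PlanUnit:
    """A candidate target: saliency plus spherical position (radians)."""

    sal: float
    ech: float
    ecv: float


@dataclass(frozen=True)
class DecisionResult:
    """Soft one-hot outcome of the three-way decision; components sum to 1."""

    dr_v: float
    dr_a: float
    dr_av: float


@dataclass(frozen=True)
class ExecutionSet:
    """Gated execution-layer positions, one (ech, ecv) pair per channel."""

    ech_exv: float
    ecv_exv: float
    ech_exa: float
    ecv_exa: float
    ech_exav: float
    ecv_exav: float


def build_plans(
    mem: MemoryState, sim: float
) -> tuple[PlanUnit, PlanUnit, PlanUnit]:
    """Construct the (visual, auditory, multisensory) plan units.

    The unisensory plans copy position and reliability from memory. The
    multisensory plan sits at the reliability-weighted average of the two
    memorized positions (componentwise on ech and ecv, normalized by the
    summed reliabilities) and carries the similarity measure as saliency.
    Before any stimulus has been stored (both reliabilities zero) the fused
    position falls back to the origin.
    """
    pl_v = PlanUnit(mem.rel_mv, mem.ech_mv, mem.ecv_mv)
    pl_a = PlanUnit(mem.rel_ma, mem.ech_ma, mem.ecv_ma)
    w = mem.rel_mv + mem.rel_ma
    if w > 0.0:
        ech_av = (mem.rel_mv * mem.ech_mv + mem.rel_ma * mem.ech_ma) / w
        ecv_av = (mem.rel_mv * mem.ecv_mv + mem.rel_ma * mem.ecv_ma) / w
    else:
        ech_av = ecv_av = 0.0
    return pl_v, pl_a, PlanUnit(sim, ech_av, ecv_av)


def decision_variable(
    plans: tuple[PlanUnit, PlanUnit, PlanUnit]
) -> tuple[float, float, float]:
    """The decision variable (dv_v, dv_a, dv_av): the three plan saliencies."""
    pl_v, pl_a, pl_av = plans
    return pl_v.sal, pl_a.sal, pl_av.sal


def decision_result(
    dv: tuple[float, float, float], params: ModelParams
) -> DecisionResult:
    """Apply the soft three-way decision rule to the decision variable.

    The components sum to 1 identically (logistic complement identity), and
    with steep slopes the result is effectively one-hot whenever the
    similarity is clearly on one side of the threshold and the reliabilities
    are clearly distinct.
    """
    dv_v, dv_a, dv_av = dv
    g_av = float(expit(params.sl_av * (dv_av - params.th_av)))
    g_uni = 1.0 - g_av
    g_v = float(expit(params.sl_u * (dv_v - dv_a)))
    return DecisionResult(
        dr_v=g_uni * g_v,
        dr_a=g_uni * (1.0 - g_v),
        dr_av=g_av,
    )


def execution_gate(
    dr: DecisionResult, plans: tuple[PlanUnit, PlanUnit, PlanUnit]
) -> ExecutionSet:
    """Release each plan's position scaled by its decision-result component.

    Selective disinhibition: with a one-hot decision result the winning
    plan's position passes through unchanged and the losers are zeroed.
    """
    pl_v, pl_a, pl_av = plans
    return ExecutionSet(
        ech_exv=dr.dr_v * pl_v.ech,
        ecv_exv=dr.dr_v * pl_v.ecv,
        ech_exa=dr.dr_a * pl_a.ech,
        ecv_exa=dr.dr_a * pl_a.ecv,
        ech_exav=dr.dr_av * pl_av.ech,
        ecv_exav=dr.dr_av * pl_av.ecv,
    )
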