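"""Controlled leaky-integrator short-term memory.

An 8-D state space, four dimensions per modality: a leak bit plus the stored
(reliability, ech, ecv) triple. The leak of each half is driven by the
existence component of the corresponding input signal, so it only ever takes
the digital values 0 or 1, and the integrator behaves as a switch:

===========  ==========================  =========================
             leak = 0                    leak = 1
===========  ==========================  =========================
no input     holds the current value     clears the memory
input        integrates the input        updates to the input
===========  ==========================  =========================

Because the leak always equals the input's existence bit, the reachable
branches are *update-to-input* (stimulus present) and *exact hold* (stimulus
absent): after stimulus offset the stored position and reliability never
drift, for any number of steps. The clearing branch is implemented for
completeness via the optional leak overrides but never arises in the
built-in scenarios. All dimensions are zero before any input arrives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .stimuli import SignalSample

__all__ = ["MemoryState", "ZERO_MEMORY", "memory_step"]


@dataclass(frozen=True)
class MemoryState:
    """Stored representation of both modalities; angles in radians."""

    lk_mv: int
    rel_mv: float
    ech_mv: float
    ecv_mv: float
    lk_ma: int
    rel_ma: float
    ech_ma: float
    ecv_ma: float


ZERO_MEMORY = MemoryState(0, 0.0, 0.0, 0.0, 0, 0.0, 0.0, 0.0)


def _half_step(
    stored: tuple[float, float, float], sample: SignalSample, lk: int
) -> tuple[int, float, float, float]:
    if sample.ext == 1:
        # input present: track it exactly (update-to-input)
        return lk, sample.rel, sample.ech, sample.ecv
    if lk == 1:
        # leak open with no input: clear
        return lk, 0.0, 0.0, 0.0
    # leak closed, no input: bit-exact hold
    return lk, *stored


def memory_step(
    state: MemoryState,
    v: SignalSample,
    a: SignalSample,
    *,
    lk_v: int | None = None,
    lk_a: int | None = None,
) -> MemoryState:
    """Advance the memory by one time step given the current input samples.

    By default each half's leak is the existence bit of its input, which
    yields update-to-input while the stimulus is on and exact hold after
    offset. ``lk_v`` / ``lk_a`` override the leaks (the clearing branch is
    only reachable through an override).
    """
    lv = v.ext if lk_v is None else lk_v
    la = a.ext if lk_a is None else lk_a
    vis = _half_step((state.rel_mv, state.ech_mv, state.ecv_mv), v, lv)
    aud = _half_step((state.rel_ma, state.ech_ma, state.ecv_ma), a, la)
    return MemoryState(*vis, *aud)
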