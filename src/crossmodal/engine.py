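"""Scenario configuration, the per-timestep simulation loop, flip-point
search, parameter sweeps, the closed-form disparity oracle, and trace I/O.

A scenario is one trial: a time grid, one visual and one auditory stimulus,
and the model parameters. :func:`run_scenario` wires the modules into the
full per-timestep pipeline — sample stimuli, update memory, measure the
great-circle distance between the memorized positions, accumulate disparity
while any stimulus is present, map to similarity, build the three plans,
apply the decision rule, gate the execution layer — and records every model
variable at every step. The whole model is deterministic.

Because the stimuli are piecewise constant, the accumulated disparity is
piecewise linear in time and :func:`closed_form_disparity` computes it
analytically; it serves as an independent check on the discrete stepper.
:func:`find_flip` bisects a stimulus parameter (spatial disparity, onset
delay, or duration) for the point where the end-of-trial sameness call
flips, and :func:`sweep_grid` maps the call over a grid of spatial and
temporal disparities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .decision import build_plans, decision_result, decision_variable, execution_gate
from .memory import ZERO_MEMORY, memory_step
from .similarity import (
    ZERO_DISPARITY,
    ModelParams,
    disparity_step,
    sameness_call,
    similarity,
    spherical_distance,
)
from .stimuli import StimulusSpec, make_time_grid, stimulus_signal

__all__ = [
    "ConfigError",
    "NoFlipError",
    "GridConfig",
    "StimulusConfig",
    "ParamsConfig",
    "ScenarioConfig",
    "FlipResult",
    "TrialSummary",
    "run_scenario",
    "summarize_trace",
    "closed_form_disparity",
    "find_flip",
    "sweep_grid",
    "write_trace",
    "read_config",
    "write_config",
    "base_config",
    "builtin_scenarios",
]

# columns of the trace table, one row per timestep; angles in degrees
TRACE_COLUMNS = [
    "t",
    "ext_v",
    "ext_a",
    "lk_mv",
    "rel_mv",
    "ech_mv",
    "ecv_mv",
    "lk_ma",
    "rel_ma",
    "ech_ma",
    "ecv_ma",
    "dist",
    "disp",
    "sim",
    "dv_v",
    "dv_a",
    "dv_av",
    "dr_v",
    "dr_a",
    "dr_av",
    "ech_exv",
    "ecv_exv",
    "ech_exa",
    "ecv_exa",
    "ech_exav",
    "ecv_exav",
    "sameness",
]


class ConfigError(ValueError):
    """A scenario configuration is malformed; the message names the fields."""


class NoFlipError(ValueError):
    """Bisection bracket endpoints produce the same sameness call."""


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_end: float = Field(1.0, gt=0)
    dt: float = Field(0.001, gt=0)


class StimulusConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    onset: float = Field(ge=0)
    duration: float = Field(gt=0)
    ech_deg: float
    ecv_deg: float = 0.0
    reliability: float = Field(0.5, ge=0, le=1)


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_int: float = Field(21.0, gt=0)
    th_av: float = Field(0.5, gt=0, lt=1)
    sl_av: float = Field(200.0, gt=0)
    sl_u: float = Field(200.0, gt=0)

    def to_params(self) -> ModelParams:
        return ModelParams(self.k_int, self.th_av, self.sl_av, self.sl_u)


class ScenarioConfig(BaseModel):
    """Full specification of one trial, JSON-serializable."""

    model_config = ConfigDict(extra="forbid")
    grid: GridConfig = GridConfig()
    visual: StimulusConfig
    auditory: StimulusConfig
    params: ParamsConfig = ParamsConfig()
    label: str = ""
    # optional forced-report time; the categorical trial outcome is read at
    # the last grid point at or before this time (default: end of trial)
    report_time: float | None = Field(None, gt=0)

    @model_validator(mode="after")
    def _windows_inside_grid(self) -> "ScenarioConfig":
        for name, stim in (("visual", self.visual), ("auditory", self.auditory)):
            if stim.onset + stim.duration > self.grid.t_end + 1e-12:
                raise ValueError(
                    f"{name} stimulus window [{stim.onset}, "
                    f"{stim.onset + stim.duration}] extends past grid end "
                    f"{self.grid.t_end}"
                )
        if self.report_time is not None and self.report_time > self.grid.t_end:
            raise ValueError(
                f"report_time {self.report_time} exceeds grid end {self.grid.t_end}"
            )
        return self

    def spec(self, modality: str) -> StimulusSpec:
        stim = self.visual if modality == "visual" else self.auditory
        return StimulusSpec(
            modality=modality,
            onset=stim.onset,
            duration=stim.duration,
            ech=stim.ech_deg,
            ecv=stim.ecv_deg,
            reliability=stim.reliability,
        )


@dataclass(frozen=True)
class FlipResult:
    """Outcome of a bisection for the sameness-call flip point."""

    swept_parameter: str
    flip_value: float
    lo: float
    hi: float
    sim_gap: float  # |final sim - th_av| achieved at the flip value


@dataclass(frozen=True)
class TrialSummary:
    """Categorical outcome of one trial."""

    label: str
    sim_final: float
    sameness: int
    winner: str  # 'av', 'visual', or 'auditory'
    tied: bool


def _wrap_validation_error(err: ValidationError) -> ConfigError:
    parts = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        parts.append(f"{loc}: {e['msg']}")
    return ConfigError("invalid scenario config — " + "; ".join(parts))


def run_scenario(cfg: ScenarioConfig) -> pd.DataFrame:
    """Simulate one trial and return the full per-timestep trace.

    Each row records, at one grid time, the input existence bits, the memory
    state, the memorized-position distance, the accumulated disparity and
    similarity, the decision variable and decision result, the gated
    execution positions, and the sameness call. Each row reflects the state
    *after* that step's update, so the disparity at time t includes the
    contribution of the sample at t. Angle columns are in degrees.
    """
    grid = make_time_grid(cfg.grid.t_end, cfg.grid.dt)
    v_spec = cfg.spec("visual")
    a_spec = cfg.spec("auditory")
    params = cfg.params.to_params()

    times = grid.times()
    n = len(times)
    out = np.empty((n, len(TRACE_COLUMNS)))

    mem = ZERO_MEMORY
    dsp = ZERO_DISPARITY
    to_deg = math.degrees
    for i, t in enumerate(times):
        v = stimulus_signal(v_spec, t)
        a = stimulus_signal(a_spec, t)
        mem = memory_step(mem, v, a)
        dist = spherical_distance(mem.ech_mv, mem.ecv_mv, mem.ech_ma, mem.ecv_ma)
        gate = 1 if (v.ext or a.ext) else 0
        dsp = disparity_step(dsp, dist, gate, grid.dt, params)
        sim = similarity(dsp.disp)
        plans = build_plans(mem, sim)
        dv = decision_variable(plans)
        dr = decision_result(dv, params)
        ex = execution_gate(dr, plans)
        sam = sameness_call(sim, params)
        out[i] = (
            t,
            v.ext,
            a.ext,
            mem.lk_mv,
            mem.rel_mv,
            to_deg(mem.ech_mv),
            to_deg(mem.ecv_mv),
            mem.lk_ma,
            mem.rel_ma,
            to_deg(mem.ech_ma),
            to_deg(mem.ecv_ma),
            to_deg(dist),
            dsp.disp,
            sim,
            dv[0],
            dv[1],
            dv[2],
            dr.dr_v,
            dr.dr_a,
            dr.dr_av,
            to_deg(ex.ech_exv),
            to_deg(ex.ecv_exv),
            to_deg(ex.ech_exa),
            to_deg(ex.ecv_exa),
            to_deg(ex.ech_exav),
            to_deg(ex.ecv_exav),
            sam,
        )
    return pd.DataFrame(out, columns=TRACE_COLUMNS)


def summarize_trace(trace: pd.DataFrame, cfg: ScenarioConfig) -> TrialSummary:
    """Categorical trial outcome, read at the report time (default: trial end).

    If the sameness call is 1 the multisensory plan wins. Otherwise the more
    reliable unisensory plan wins; an exact reliability tie is broken toward
    the visual plan and flagged.
    """
    if cfg.report_time is None:
        row = trace.iloc[-1]
    else:
        row = trace[trace["t"] <= cfg.report_time + 1e-12].iloc[-1]
    sam = int(row["sameness"])
    tied = False
    if sam == 1:
        winner = "av"
    elif row["dv_v"] > row["dv_a"]:
        winner = "visual"
    elif row["dv_v"] < row["dv_a"]:
        winner = "auditory"
    else:
        winner, tied = "visual", True
    return TrialSummary(
        label=cfg.label,
        sim_final=float(row["sim"]),
        sameness=sam,
        winner=winner,
        tied=tied,
    )


def closed_form_disparity(cfg: ScenarioConfig) -> Callable[[float], float]:
    """Analytic disparity trajectory for piecewise-constant stimuli.

    Between stimulus on/offset events the memorized-position distance is a
    constant d and the gate is constant, so disp grows linearly at rate
    k_int * d while the gate is on and is flat otherwise: when both stimuli
    have been stored d is their great-circle separation; when only one has,
    d is that stimulus's distance to the zero-initialized memory origin.
    Returns a callable disp(t); exposes the breakpoints on attributes
    ``breaks`` and ``values``.
    """
    v = cfg.spec("visual")
    a = cfg.spec("auditory")
    k = cfg.params.k_int
    t_end = cfg.grid.t_end

    events = sorted(
        {0.0, t_end}
        | {x for x in (v.onset, v.offset, a.onset, a.offset) if 0.0 <= x <= t_end}
    )
    ech_v, ecv_v = math.radians(v.ech), math.radians(v.ecv)
    ech_a, ecv_a = math.radians(a.ech), math.radians(a.ecv)
    d_pair = spherical_distance(ech_v, ecv_v, ech_a, ecv_a)
    d_v0 = spherical_distance(ech_v, ecv_v, 0.0, 0.0)
    d_a0 = spherical_distance(0.0, 0.0, ech_a, ecv_a)

    breaks = [events[0]]
    values = [0.0]
    for t0, t1 in zip(events[:-1], events[1:]):
        tm = 0.5 * (t0 + t1)
        gate = (v.onset <= tm < v.offset) or (a.onset <= tm < a.offset)
        stored_v = tm >= v.onset
        stored_a = tm >= a.onset
        if stored_v and stored_a:
            d = d_pair
        elif stored_v:
            d = d_v0
        elif stored_a:
            d = d_a0
        else:
            d = 0.0
        rate = k * d if gate else 0.0
        breaks.append(t1)
        values.append(values[-1] + rate * (t1 - t0))

    br = np.asarray(breaks)
    va = np.asarray(values)

    def disp(t: float) -> float:
        return float(np.interp(t, br, va))

    disp.breaks = br  # type: ignore[attr-defined]
    disp.values = va  # type: ignore[attr-defined]
    return disp


def apply_parameter(cfg: ScenarioConfig, name: str, value: float) -> ScenarioConfig:
    """Return a copy of ``cfg`` with one swept stimulus parameter applied.

    Supported names: ``sd`` (auditory ech = visual ech + value, degrees),
    ``onset_delay`` (auditory onset = visual onset + value, s), ``duration``
    (common duration of both stimuli, s) and ``auditory_duration`` (the
    auditory duration alone, s).
    """
    d = cfg.model_dump()
    if name == "sd":
        d["auditory"]["ech_deg"] = d["visual"]["ech_deg"] + value
    elif name == "onset_delay":
        d["auditory"]["onset"] = d["visual"]["onset"] + value
    elif name == "duration":
        d["visual"]["duration"] = value
        d["auditory"]["duration"] = value
    elif name == "auditory_duration":
        d["auditory"]["duration"] = value
    else:
        raise ConfigError(
            f"unknown swept parameter {name!r}; expected one of "
            "'sd', 'onset_delay', 'duration', 'auditory_duration'"
        )
    try:
        return ScenarioConfig.model_validate(d)
    except ValidationError as err:
        raise _wrap_validation_error(err) from err


def _final_call(cfg: ScenarioConfig) -> tuple[int, float]:
    trace = run_scenario(cfg)
    row = trace.iloc[-1]
    return int(row["sameness"]), float(row["sim"])


def find_flip(
    cfg: ScenarioConfig,
    swept: str,
    lo: float,
    hi: float,
    tol: float | None = None,
) -> FlipResult:
    """Bisect a swept parameter for the sameness-call flip point.

    The end-of-trial sameness call must differ at ``lo`` and ``hi``;
    otherwise :class:`NoFlipError` is raised. The bracket is halved until
    its width is at most ``tol`` (default: 0.01 for the spatial-disparity
    sweep in degrees, 0.001 for temporal sweeps in seconds) and the flip
    value is the final bracket midpoint.
    """
    if tol is None:
        tol = 0.01 if swept == "sd" else 0.001
    call_lo, _ = _final_call(apply_parameter(cfg, swept, lo))
    call_hi, _ = _final_call(apply_parameter(cfg, swept, hi))
    if call_lo == call_hi:
        raise NoFlipError(
            f"sameness call is {call_lo} at both ends of [{lo}, {hi}] "
            f"for parameter {swept!r}; no flip to bracket"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        call_mid, _ = _final_call(apply_parameter(cfg, swept, mid))
        if call_mid == call_lo:
            lo = mid
        else:
            hi = mid
    flip = 0.5 * (lo + hi)
    _, sim_at_flip = _final_call(apply_parameter(cfg, swept, flip))
    return FlipResult(
        swept_parameter=swept,
        flip_value=flip,
        lo=lo,
        hi=hi,
        sim_gap=abs(sim_at_flip - cfg.params.th_av),
    )


def sweep_grid(
    cfg_template: ScenarioConfig,
    sd_values: Sequence[float],
    dt_values: Sequence[float],
) -> pd.DataFrame:
    """Final similarity and sameness call over a (spatial x temporal) grid.

    ``sd_values`` are spatial disparities in degrees (auditory ech offset
    from the visual ech); ``dt_values`` are auditory onset delays in
    seconds. One full trial is simulated per cell; the returned table has
    one row per (sd, dt) pair, ordered by sd then dt.
    """
    if len(sd_values) == 0 or len(dt_values) == 0:
        raise ConfigError("sd_values and dt_values must be non-empty")
    rows = []
    for sd in sd_values:
        cfg_sd = apply_parameter(cfg_template, "sd", sd)
        for dtv in dt_values:
            cfg = apply_parameter(cfg_sd, "onset_delay", dtv)
            call, sim = _final_call(cfg)
            rows.append({"sd": sd, "dt": dtv, "sim_final": sim, "sameness": call})
    return pd.DataFrame(rows)


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    """Write a simulation trace as CSV, one row per timestep."""
    trace.to_csv(path, index=False)


def read_config(path: str | Path) -> ScenarioConfig:
    """Read and validate a scenario config from a JSON file.

    Raises :class:`ConfigError` naming every missing, unknown, or invalid
    key if the file does not satisfy the schema.
    """
    text = Path(path).read_text()
    try:
        return ScenarioConfig.model_validate_json(text)
    except ValidationError as err:
        raise _wrap_validation_error(err) from err


def write_config(cfg: ScenarioConfig, path: str | Path) -> None:
    """Write a scenario config as JSON (lossless round trip with read_config)."""
    Path(path).write_text(cfg.model_dump_json(indent=2) + "\n")


# --- built-in scenario catalog -------------------------------------------
#
# Default geometry: both stimuli on a common meridian (ecv = 0) with the
# visual stimulus at ech = 9 deg, the auditory at ech = 9 deg + sd, so the
# great-circle separation equals |sd| and the visual stimulus sits 9 deg
# from the memory origin. Default timing: onset 0.2 s, duration 0.3 s,
# reliabilities 0.5, trial span 1 s at dt = 1 ms.

VISUAL_ECH_DEG = 9.0


def base_config(
    sd: float = 7.0,
    *,
    onset: float = 0.2,
    duration: float = 0.3,
    onset_delay: float = 0.0,
    auditory_duration: float | None = None,
    rel_v: float = 0.5,
    rel_a: float = 0.5,
    t_end: float = 1.0,
    dt: float = 0.001,
    label: str = "",
    params: ParamsConfig | None = None,
) -> ScenarioConfig:
    """Scenario on the default geometry with spatial disparity ``sd`` (deg)."""
    return ScenarioConfig(
        grid=GridConfig(t_end=t_end, dt=dt),
        visual=StimulusConfig(
            onset=onset,
            duration=duration,
            ech_deg=VISUAL_ECH_DEG,
            ecv_deg=0.0,
            reliability=rel_v,
        ),
        auditory=StimulusConfig(
            onset=onset + onset_delay,
            duration=duration if auditory_duration is None else auditory_duration,
            ech_deg=VISUAL_ECH_DEG + sd,
            ecv_deg=0.0,
            reliability=rel_a,
        ),
        params=params or ParamsConfig(),
        label=label,
    )


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """The built-in condition catalog mirroring the five study families.

    * ``spatial-sd*``: synchronous stimuli, spatial disparity varied from
      1.5 to 21.7 deg.
    * ``temporal-delay*``: stimuli 7 deg apart, auditory onset delayed by
      0.05-0.25 s.
    * ``reliability-rela*``: widely separated synchronous stimuli (15 deg),
      visual reliability 0.5, auditory reliability 0.2-0.8.
    * ``duration-common*``: synchronous stimuli 7.5 deg apart, common
      duration 0.25-0.55 s.
    * ``duration-auditory*``: visual 0.2 s, common onset, auditory duration
      0.25-0.55 s, 7.5 deg apart.
    """
    cat: dict[str, ScenarioConfig] = {}
    for sd in (1.5, 5.5, 10.5, 15.6, 21.7):
        cat[f"spatial-sd{sd:g}"] = base_config(sd, label=f"spatial sd={sd:g} deg")
    for delay in (0.05, 0.10, 0.15, 0.20, 0.25):
        cat[f"temporal-delay{delay:g}"] = base_config(
            7.0, onset_delay=delay, label=f"temporal delay={delay:g} s"
        )
    for rel_a in (0.2, 0.4, 0.6, 0.8):
        cat[f"reliability-rela{rel_a:g}"] = base_config(
            15.0, rel_a=rel_a, label=f"reliability rel_a={rel_a:g}"
        )
    for dur in (0.25, 0.35, 0.45, 0.55):
        cat[f"duration-common{dur:g}"] = base_config(
            7.5, duration=dur, label=f"common duration={dur:g} s"
        )
    for dur in (0.25, 0.35, 0.45, 0.55):
        cat[f"duration-auditory{dur:g}"] = base_config(
            7.5,
            duration=0.2,
            auditory_duration=dur,
            label=f"auditory duration={dur:g} s",
        )
    return cat
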