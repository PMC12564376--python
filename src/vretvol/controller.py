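"""Rule-based adaptive micro-relaxation controller.

Discrete-time (1 Hz) replay of the closed-loop pacing rule used during VR
exposure:

* signals: heart rate (5-s trailing median, z-scored to the participant's
  pre-exposure baseline) and head-movement variability (5-s trailing
  rolling SD of head-pose velocity, z-scored to the first 2 min);
* trigger, checked each second: HR z >= +1.0 sustained for >= 10 s OR
  HMV z >= +1.0 sustained for >= 5 s issues a 30-45 s breathing prompt and
  holds difficulty for the prompt's duration;
* >= 3 triggers inside any 5-min window sustains the current difficulty
  for the remainder of the block; 5 min with no trigger steps difficulty
  up one level;
* raw heart rate above a hard ceiling (120 bpm) switches immediately to a
  relaxation scene, exited once smoothed HR stays below the ceiling for
  30 consecutive seconds.

Event times in the log are seconds since the start of the exposure block
(the part of the trace after the baseline segment).  Identical trace +
config always produce an identical log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ControllerConfig",
    "ControllerEvent",
    "ControllerLog",
    "baseline_hr_z",
    "hmv_z",
    "run_session",
]


@dataclass
class ControllerConfig:
    hr_z_threshold: float = 1.0
    hr_sustain_s: int = 10
    hmv_z_threshold: float = 1.0
    hmv_sustain_s: int = 5
    prompt_duration_s: int = 30
    trigger_window_s: int = 300
    trigger_count_hold: int = 3
    quiescence_stepup_s: int = 300
    hr_hard_ceiling_bpm: float = 120.0
    hr_smooth_window_s: int = 5
    hmv_window_s: int = 5
    hmv_baseline_s: int = 120
    relax_exit_sustain_s: int = 30

    def __post_init__(self):
        durations = (
            self.hr_sustain_s, self.hmv_sustain_s, self.prompt_duration_s,
            self.trigger_window_s, self.quiescence_stepup_s,
            self.hr_smooth_window_s, self.hmv_window_s, self.hmv_baseline_s,
            self.relax_exit_sustain_s,
        )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")
        if not 30 <= self.prompt_duration_s <= 45:
            raise ValueError("prompt_duration_s must be within [30, 45]")


@dataclass
class ControllerEvent:
    time_s: float
    kind: str  # trigger | prompt_start | prompt_end | hold | step_up |
    #            relax_scene_enter | relax_scene_exit
    detail: str = ""


@dataclass
class ControllerLog:
    events: list = field(default_factory=list)
    final_difficulty: int = 1
    n_triggers: int = 0

    def times(self, kind: str) -> list:
        return [e.time_s for e in self.events if e.kind == kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [asdict(e) for e in self.events], columns=["time_s", "kind", "detail"]
        ).rename(columns={"time_s": "t_s", "kind": "event"})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_trace(trace: pd.DataFrame) -> None:
    t = trace["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone timestamps in trace")


def _baseline_mask(trace: pd.DataFrame, baseline_s: int) -> np.ndarray:
    """Pre-exposure rows: scene == 'baseline' if present, else first baseline_s."""
    if "scene" in trace.columns and (trace["scene"] == "baseline").any():
        return (trace["scene"] == "baseline").to_numpy()
    t = trace["t_s"].to_numpy()
    return t < t[0] + baseline_s


def baseline_hr_z(trace: pd.DataFrame, config: ControllerConfig | None = None) -> np.ndarray:
    """Heart rate, 5-s trailing median, z-scored to the pre-exposure baseline.

    Trailing windows: the first window-1 samples use the partial window.
    Length equals the trace length.
    """
    config = config or ControllerConfig()
    _check_trace(trace)
    mask = _baseline_mask(trace, config.hmv_baseline_s)
    if mask.sum() < 60:
        raise ValueError("pre-exposure baseline segment must cover >= 60 s")
    hr = pd.Series(trace["hr_bpm"].to_numpy())
    smooth = hr.rolling(config.hr_smooth_window_s, min_periods=1).median().to_numpy()
    base = smooth[mask]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero baseline HR variability: z-score undefined")
    return (smooth - mu) / sd


def hmv_z(trace: pd.DataFrame, config: ControllerConfig | None = None) -> np.ndarray:
    """Head-movement variability (5-s rolling SD), z-scored to the first 2 min."""
    config = config or ControllerConfig()
    _check_trace(trace)
    if len(trace) < config.hmv_baseline_s:
        raise ValueError("trace shorter than the HMV baseline window")
    v = pd.Series(trace["head_vel_dps"].to_numpy())
    rsd = v.rolling(config.hmv_window_s, min_periods=1).std(ddof=0).to_numpy()
    base = rsd[: config.hmv_baseline_s]
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero head-movement variability over the baseline window")
    return (rsd - mu) / sd


def run_session(trace: pd.DataFrame, config: ControllerConfig | None = None) -> ControllerLog:
    """Replay the trigger/hold/step-up/relaxation rule over one trace.

    The baseline segment only feeds z-scoring; the state machine runs over
    the exposure block, one evaluation per second, with times reported
    relative to the block start.
    """
    config = config or ControllerConfig()
    _check_trace(trace)
    hr_z_full = baseline_hr_z(trace, config)
    hmv_z_full = hmv_z(trace, config)
    mask = _baseline_mask(trace, config.hmv_baseline_s)
    block = ~mask
    hr_z = hr_z_full[block]
    hm_z = hmv_z_full[block]
    hr_raw = trace["hr_bpm"].to_numpy()[block]
    hr_smooth = (
        pd.Series(trace["hr_bpm"].to_numpy())
        .rolling(config.hr_smooth_window_s, min_periods=1)
        .median()
        .to_numpy()[block]
    )
    difficulty = int(trace["difficulty"].to_numpy()[block][0]) if "difficulty" in trace else 1

    log = ControllerLog(final_difficulty=difficulty)
    n = hr_z.size

    hr_run = hm_run = 0
    prompt_end_t: float | None = None
    holding = False
    in_relax = False
    relax_calm_run = 0
    trigger_times: list = []
    quiesce_ref = 0.0  # last trigger / step-up / block start

    for t in range(n):
        # 1. hard-ceiling relaxation switch (raw HR, checked every second)
        if in_relax:
            if hr_smooth[t] < config.hr_hard_ceiling_bpm:
                relax_calm_run += 1
            else:
                relax_calm_run = 0
            if relax_calm_run >= config.relax_exit_sustain_s:
                log.events.append(ControllerEvent(t, "relax_scene_exit"))
                in_relax = False
                relax_calm_run = 0
                hr_run = hm_run = 0
                quiesce_ref = t
            continue
        if hr_raw[t] > config.hr_hard_ceiling_bpm:
            log.events.append(
                ControllerEvent(t, "relax_scene_enter", f"hr={hr_raw[t]:.1f}bpm")
            )
            in_relax = True
            relax_calm_run = 0
            hr_run = hm_run = 0
            continue

        # 2. active prompt: evaluation suspended until it ends
        if prompt_end_t is not None:
            if t >= prompt_end_t:
                log.events.append(ControllerEvent(t, "prompt_end"))
                prompt_end_t = None
                hr_run = hm_run = 0
            else:
                continue

        # 3. sustained-threshold trigger
        hr_run = hr_run + 1 if hr_z[t] >= config.hr_z_threshold else 0
        hm_run = hm_run + 1 if hm_z[t] >= config.hmv_z_threshold else 0
        hr_fire = hr_run >= config.hr_sustain_s
        hm_fire = hm_run >= config.hmv_sustain_s
        if hr_fire or hm_fire:
            cause = "hr+hmv" if (hr_fire and hm_fire) else ("hr" if hr_fire else "hmv")
            log.events.append(ControllerEvent(t, "trigger", cause))
            log.n_triggers += 1
            trigger_times.append(t)
            quiesce_ref = t
            hr_run = hm_run = 0
            log.events.append(ControllerEvent(t, "prompt_start"))
            prompt_end_t = t + config.prompt_duration_s
            if not holding:
                recent = [u for u in trigger_times if u > t - config.trigger_window_s]
                if len(recent) >= config.trigger_count_hold:
                    log.events.append(ControllerEvent(t, "hold"))
                    holding = True
            continue

        # 4. quiescence step-up (suppressed while holding or prompting)
        if not holding and t - quiesce_ref >= config.quiescence_stepup_s:
            difficulty += 1
            log.events.append(ControllerEvent(t, "step_up", f"difficulty={difficulty}"))
            quiesce_ref = t

    log.final_difficulty = difficulty
    return log
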