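"""Trial protocol: anchors, normalization, perturbation schedule, and the
closed loop.

A trial emulates an episode of pathologically elevated vagal tone.  The
sequence is:

1. *Anchor test.*  Maximal 30 Hz stimulation is applied briefly on the
   control electrode; the lowest rolling heart rate defines the 0%
   normalized anchor.  After a 2-minute recovery the resting rate
   defines the 100% anchor.  The setpoint is the 50% midpoint.
2. *Closed loop* (840 s at defaults): 2 min of control at rest, then a
   synthetic vagal tone on the perturbation electrode ramping 1 - 30 Hz
   in 1 Hz / 10 s steps (5 min), ramping back down (5 min), and 2 more
   minutes of control at rest.

At every controller update (2 Hz) the rolling heart-rate estimate is fed
to the fuzzy controller, the resulting ``cout`` is converted to a
stimulation or block command through the calibration, and the plant is
advanced to the next update.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import (
    OFF_COMMAND,
    CalibrationResult,
    WaveformCommand,
    cout_to_command,
)
from .controller import (
    ControllerState,
    FuzzyControllerConfig,
    compute_error,
    controller_step,
)
from .hr_estimation import RollingHrEstimator
from .plant import BeatGenerator, PlantParams, PlantState, plant_step, spawn_rngs

__all__ = [
    "NormalizationAnchors",
    "TrialSchedule",
    "TrialRecord",
    "LoopEngine",
    "build_schedule",
    "measure_anchors",
    "normalize",
    "run_trial",
    "UnresponsivePlantError",
    "ProtocolError",
]

logger = logging.getLogger(__name__)

PLANT_DT = 0.05  # s, plant integration substep
ANCHOR_STIM_S = 30.0  # s, duration of the maximal-stimulation anchor test
ANCHOR_RECOVERY_S = 120.0  # s, rest before reading the 100% anchor
MIN_ANCHOR_SPAN = 20.0  # bpm, responsiveness check
WARMUP_S = 10.0  # s of resting beats before any estimate is read


class ProtocolError(RuntimeError):
    pass


class UnresponsivePlantError(ProtocolError):
    """The anchor test produced too small a heart-rate span."""


@dataclass(frozen=True)
class NormalizationAnchors:
    hr_0pct: float  # bpm, minimum during the maximal-stimulation test
    hr_100pct: float  # bpm, resting baseline after recovery

    def __post_init__(self) -> None:
        if not self.hr_0pct < self.hr_100pct:
            raise ValueError(
                f"require hr_0pct < hr_100pct, got ({self.hr_0pct}, {self.hr_100pct})"
            )


def normalize(hr: float, anchors: NormalizationAnchors) -> float:
    """Heart rate as a percentage of the anchor span (may leave [0, 100])."""
    span = anchors.hr_100pct - anchors.hr_0pct
    return 100.0 * (hr - anchors.hr_0pct) / span


@dataclass(frozen=True)
class TrialSchedule:
    """Phase timing and the piecewise-constant perturbation profile."""

    pre_control_s: float = 120.0
    ramp_up_s: float = 300.0
    ramp_down_s: float = 300.0
    post_control_s: float = 120.0
    step_hz: float = 1.0
    step_dwell_s: float = 10.0
    peak_freq: float = 30.0

    def __post_init__(self) -> None:
        if min(
            self.pre_control_s,
            self.ramp_up_s,
            self.ramp_down_s,
            self.post_control_s,
        ) < 0:
            raise ValueError("phase durations must be >= 0")
        if self.step_hz <= 0 or self.step_dwell_s <= 0 or self.peak_freq <= 0:
            raise ValueError("step_hz, step_dwell_s and peak_freq must be > 0")
        n_steps = self.peak_freq / self.step_hz
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("peak_freq must be an integer number of steps")
        expected = round(n_steps) * self.step_dwell_s
        if not math.isclose(self.ramp_up_s, expected) or not math.isclose(
            self.ramp_down_s, expected
        ):
            raise ValueError(
                f"ramp durations must equal peak_freq/step_hz * step_dwell_s = {expected} s"
            )

    @property
    def duration_s(self) -> float:
        """Total controller-on time (840 s at defaults)."""
        return (
            self.pre_control_s + self.ramp_up_s + self.ramp_down_s + self.post_control_s
        )

    def perturb_freq(self, t: float) -> float:
        """Perturbation frequency (Hz) at trial time ``t`` (s from controller on)."""
        if t < self.pre_control_s:
            return 0.0
        t_up = t - self.pre_control_s
        if t_up < self.ramp_up_s:
            return min(
                self.peak_freq, (math.floor(t_up / self.step_dwell_s) + 1) * self.step_hz
            )
        t_down = t_up - self.ramp_up_s
        if t_down < self.ramp_down_s:
            return max(
                self.step_hz,
                self.peak_freq - math.floor(t_down / self.step_dwell_s) * self.step_hz,
            )
        return 0.0

    def phase(self, t: float) -> str:
        if t < self.pre_control_s:
            return "pre"
        if t < self.pre_control_s + self.ramp_up_s:
            return "ramp_up"
        if t < self.pre_control_s + self.ramp_up_s + self.ramp_down_s:
            return "ramp_down"
        return "post"


def build_schedule(**kwargs) -> TrialSchedule:
    """Construct and validate a trial schedule (defaults give 840 s)."""
    return TrialSchedule(**kwargs)


@dataclass
class TrialRecord:
    """Logged closed-loop trajectories plus trial metadata."""

    data: pd.DataFrame
    anchors: NormalizationAnchors
    schedule: TrialSchedule
    meta: dict = field(default_factory=dict)

    COLUMNS = (
        "t",
        "hr",
        "hr_norm",
        "dhr",
        "mhr",
        "dcout",
        "cout",
        "mode",
        "stim_freq_hz",
        "block_amp_ma",
        "perturb_freq_hz",
        "phase",
    )

    @property
    def update_interval(self) -> float:
        return float(np.median(np.diff(self.data["t"].to_numpy())))


class LoopEngine:
    """Integrates plant, beat emission, and heart-rate estimation.

    One engine instance owns a plant state, a beat generator (with its
    jitter stream), and a rolling estimator, so calibration sweeps, the
    anchor test, and the closed loop all see one continuous animal.
    """

    def __init__(
        self,
        params: PlantParams,
        rng: np.random.Generator,
        dt: float = PLANT_DT,
        warmup_s: float = WARMUP_S,
    ) -> None:
        self.params = params
        self.dt = dt
        self.t = 0.0
        self.state = PlantState(hr=params.baseline_hr, target_hr=params.baseline_hr)
        self.beats = BeatGenerator(rng, params.rr_jitter_sd)
        self.estimator = RollingHrEstimator()
        if warmup_s > 0:
            self.run_open(warmup_s, OFF_COMMAND, 0.0)

    def hr_estimate(self) -> float:
        return self.estimator.estimate(self.t)

    def _substep(self, command: WaveformCommand, perturb_freq: float) -> None:
        hr0, t0 = self.state.hr, self.t
        self.state = plant_step(self.state, command, perturb_freq, self.dt, self.params)
        self.t += self.dt
        for beat in self.beats.advance(t0, self.t, hr0, self.state.hr):
            self.estimator.add_beat(beat)

    def run_open(
        self,
        duration: float,
        command: WaveformCommand,
        perturb_freq: float | Callable[[float], float],
        min_hr_hook: bool = False,
    ) -> float | None:
        """Advance the plant under a fixed command.

        The rolling estimator is ticked every 0.5 s throughout (the real
        system estimates continuously), so held values stay fresh across
        data gaps.  When ``min_hr_hook`` is set, returns the minimum
        rolling estimate observed, as in the anchor test.
        """
        n = round(duration / self.dt)
        min_hr = math.inf
        reads_every = max(1, round(0.5 / self.dt))
        for i in range(n):
            f = perturb_freq(self.t) if callable(perturb_freq) else perturb_freq
            self._substep(command, f)
            if (i + 1) % reads_every == 0:
                hr = self.hr_estimate()
                if min_hr_hook:
                    min_hr = min(min_hr, hr)
        return min_hr if min_hr_hook else None


def _measure_anchors_on(engine: LoopEngine) -> NormalizationAnchors:
    max_stim = WaveformCommand("stim", frequency=30.0, pulse_width_us=50.0)
    hr_min = engine.run_open(ANCHOR_STIM_S, max_stim, 0.0, min_hr_hook=True)
    engine.run_open(ANCHOR_RECOVERY_S, OFF_COMMAND, 0.0)
    hr_rest = engine.hr_estimate()
    if hr_rest - hr_min < MIN_ANCHOR_SPAN:
        raise UnresponsivePlantError(
            f"anchor span {hr_rest - hr_min:.1f} bpm is below the "
            f"{MIN_ANCHOR_SPAN:.0f} bpm responsiveness threshold"
        )
    return NormalizationAnchors(hr_0pct=hr_min, hr_100pct=hr_rest)


def measure_anchors(params: PlantParams, rng: np.random.Generator) -> NormalizationAnchors:
    """Run the pre-trial maximal-stimulation anchor test on a fresh plant."""
    engine = LoopEngine(params, rng)
    return _measure_anchors_on(engine)


def run_trial(
    params: PlantParams,
    calib: CalibrationResult,
    schedule: TrialSchedule | None = None,
    gain: float = 5.0,
    seed: int = 0,
    no_control: bool = False,
    controller_config: FuzzyControllerConfig | None = None,
) -> TrialRecord:
    """Execute one full trial and return the logged record.

    The anchor test runs first on the same plant; the setpoint is fixed
    at the anchors' midpoint in bpm for the whole trial.  Trial time
    ``t = 0`` is the moment the controller turns on.  With
    ``no_control`` the loop runs open (electrode off) as the reference
    condition.  ``controller_config`` overrides membership/rule settings;
    its gain and setpoint are replaced by ``gain`` and the midpoint.
    """
    if schedule is None:
        schedule = TrialSchedule()
    (rng_beats,) = spawn_rngs(seed, 1)
    engine = LoopEngine(params, rng_beats)
    anchors = _measure_anchors_on(engine)
    setpoint = 0.5 * (anchors.hr_0pct + anchors.hr_100pct)

    from dataclasses import replace as _replace

    base = controller_config if controller_config is not None else FuzzyControllerConfig()
    cfg = _replace(base, gain=gain, setpoint=setpoint)
    cstate = ControllerState()

    update_dt = 1.0 / cfg.update_rate
    n_sub = round(update_dt / engine.dt)
    if not math.isclose(n_sub * engine.dt, update_dt, rel_tol=1e-9):
        raise ProtocolError(
            f"plant step {engine.dt} s does not divide the controller "
            f"update interval {update_dt} s"
        )
    n_updates = round(schedule.duration_s * cfg.update_rate)

    t_on = engine.t  # absolute engine time of controller start
    rows = []
    for k in range(n_updates + 1):
        t = k * update_dt  # trial time
        hr = engine.hr_estimate()
        prev_cout = cstate.cout
        cout, cstate = controller_step(hr, cstate, cfg)
        dcout = (cout - prev_cout) / (cfg.gain / cfg.update_rate)
        if no_control:
            cmd = OFF_COMMAND
        else:
            cmd = cout_to_command(cout, calib)
        err = compute_error(hr, setpoint)
        mhr = 0.0 if k == 0 else (err - rows[-1][3]) * cfg.update_rate
        rows.append(
            (
                t,
                hr,
                normalize(hr, anchors),
                err,
                mhr,
                dcout,
                cout,
                cmd.mode,
                cmd.frequency if cmd.mode == "stim" else 0.0,
                cmd.amplitude if cmd.mode == "block" else 0.0,
                schedule.perturb_freq(t),
                schedule.phase(t),
            )
        )
        if k < n_updates:
            for _ in range(n_sub):
                f = schedule.perturb_freq(engine.t - t_on)
                engine._substep(cmd, f)

    data = pd.DataFrame(rows, columns=list(TrialRecord.COLUMNS))
    meta = {
        "gain": gain,
        "seed": seed,
        "tau": params.time_constant,
        "no_control": no_control,
        "setpoint_bpm": setpoint,
        "update_rate_hz": cfg.update_rate,
        "hr_0pct": anchors.hr_0pct,
        "hr_100pct": anchors.hr_100pct,
        "n_controller_updates": cstate.n_updates,
    }
    return TrialRecord(data=data, anchors=anchors, schedule=schedule, meta=meta)
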