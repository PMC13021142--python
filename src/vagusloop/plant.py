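"""Synthetic cardiac-vagal plant.

Stands in for the anesthetized rat: maps the perturbation-electrode
frequency (the synthetic vagal tone), the control-electrode stimulation
frequency, and the control-electrode block amplitude to an instantaneous
heart rate, and emits R-event times for the estimator to consume.

Model
-----
Vagal drive (bpm of heart-rate depression)::

    D = clamp(min(S_p * f_perturb, max_drop) * T(amp) + S_c * f_stim,
              0, max_drop)

where ``T(amp)`` is the kilohertz-block transmission factor (1 below the
starting block amplitude, falling linearly to 0 as the block deepens)
and ``max_drop`` is the effector ceiling: the span between the resting
baseline and the heart-rate floor reached under maximal vagal drive
(the intrinsic/escape rate, ~250 bpm in the anesthetized rat).  The
frequency-response therefore saturates at ``f* = max_drop / S_p``
(typically 10-25 Hz), matching the observed calibration procedure of
stepping frequency until the heart rate stops dropping; the block
scales the *saturated* drive, so under a maximal 30 Hz perturbation the
heart-rate recovery per mA of block equals the block sensitivity
exactly and recovery begins exactly at the starting block amplitude.
The heart rate relaxes toward ``baseline_hr - D`` with a single
first-order time constant ``tau``.  Beats are emitted by integrating the
instantaneous rate; each inter-beat interval carries additive Gaussian
jitter.

The population model draws per-animal sensitivities from truncated
normal distributions whose bounds match the observed calibration ranges
(stimulation sensitivity 5-12 bpm/Hz, starting block amplitude 0.5-3 mA
peak-to-peak, block sensitivity 14.5-160 bpm/mA) and whose location is
solved so the *truncated* means equal the reported population means
(9.2 bpm/Hz, 1.8 mA, 64.3 bpm/mA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .calibration import WaveformCommand

__all__ = [
    "PlantParams",
    "PlantState",
    "sample_animal",
    "transmission_factor",
    "plant_step",
    "emit_beats",
    "BeatGenerator",
    "spawn_rngs",
]

# Population statistics (mean, sd, lower bound, upper bound)
STIM_SENSITIVITY_POP = (9.2, 2.5, 5.0, 12.0)  # bpm/Hz
BLOCK_START_POP = (1.8, 0.9, 0.5, 3.0)  # mA p-p
BLOCK_SENSITIVITY_POP = (64.3, 45.0, 14.5, 160.0)  # bpm/mA p-p
BASELINE_HR_POP = (400.0, 30.0, 300.0, 500.0)  # bpm
HR_FLOOR_POP = (250.0, 25.0)  # bpm, intrinsic/escape rate under maximal drive
MIN_MAX_DROP = 100.0  # bpm, smallest anchor span in the population
MAX_PERTURB_FREQ = 30.0  # Hz
RR_FLOOR_S = 0.020  # physiological floor on inter-beat intervals


@dataclass(frozen=True)
class PlantParams:
    baseline_hr: float  # bpm, resting HR (the 100% anchor)
    max_drop: float  # bpm, HR span from the 100% to the 0% anchor
    perturb_sensitivity: float  # bpm/Hz on the perturbation electrode
    control_sensitivity: float  # bpm/Hz on the control electrode
    block_start_amp: float  # mA p-p, largest amplitude with no block
    block_sensitivity: float  # bpm/mA p-p
    time_constant: float = 3.0  # s, first-order HR lag
    rr_jitter_sd: float = 2.0  # ms, beat-timing noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.baseline_hr > self.max_drop > 0):
            raise ValueError(
                "require baseline_hr > max_drop > 0, got "
                f"({self.baseline_hr}, {self.max_drop})"
            )
        for name in (
            "perturb_sensitivity",
            "control_sensitivity",
            "block_sensitivity",
            "time_constant",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.block_start_amp < 0:
            raise ValueError("block_start_amp must be >= 0")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be >= 0")


@dataclass(frozen=True)
class PlantState:
    hr: float  # bpm, instantaneous
    target_hr: float  # bpm, asymptote under the current drives
    t: float = 0.0  # s
    next_beat_phase: float = 0.0  # fractional beat accumulated, in [0, 1)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one global seed.

    Streams are indexed by fixed spawn keys, so adding a consumer never
    perturbs the draws of existing ones.
    """
    root = np.random.SeedSequence(int(seed))
    return [np.random.Generator(np.random.PCG64(child)) for child in root.spawn(n)]


@lru_cache(maxsize=None)
def _matched_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, float, float]:
    """Standardized (a, b, loc, scale) of a truncated normal on [lo, hi]
    whose truncated mean equals ``mean``.

    The underlying location is solved numerically; the scale is kept at
    the reported population sd (the realized spread is therefore somewhat
    narrower than the reported sd, a direct consequence of the hard
    range bounds).
    """

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    loc = optimize.brentq(
        lambda m: trunc_mean(m) - mean, mean - 6 * sd, mean + 6 * sd, xtol=1e-10
    )
    return (lo - loc) / sd, (hi - loc) / sd, loc, sd


def _draw_truncated(rng: np.random.Generator, pop: tuple[float, float, float, float]) -> float:
    mean, sd, lo, hi = pop
    a, b, loc, scale = _matched_truncnorm(mean, sd, lo, hi)
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))


def sample_animal(
    rng: np.random.Generator,
    time_constant: float = 3.0,
    rr_jitter_sd: float = 2.0,
    seed: int = 0,
) -> PlantParams:
    """Draw one synthetic animal from the population model.

    Sensitivities come from the truncated-normal population model; the
    maximal drop is the span between the resting baseline and the
    heart-rate floor under maximal vagal drive (the intrinsic/escape
    rate, ~250 bpm), bounded so the drive saturates at or below a 30 Hz
    perturbation.  The control electrode shares the perturbation
    electrode's sensitivity (same nerve, same cuff design).
    """
    perturb_sensitivity = _draw_truncated(rng, STIM_SENSITIVITY_POP)
    block_start_amp = _draw_truncated(rng, BLOCK_START_POP)
    block_sensitivity = _draw_truncated(rng, BLOCK_SENSITIVITY_POP)
    mu, sd, lo, hi = BASELINE_HR_POP
    baseline_hr = float(
        stats.truncnorm.rvs(
            (lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, random_state=rng
        )
    )
    floor_mu, floor_sd = HR_FLOOR_POP
    floor_lo = max(
        floor_mu - 3 * floor_sd,
        baseline_hr - MAX_PERTURB_FREQ * perturb_sensitivity,
    )
    floor_hi = baseline_hr - MIN_MAX_DROP
    hr_floor = float(
        stats.truncnorm.rvs(
            (floor_lo - floor_mu) / floor_sd,
            (floor_hi - floor_mu) / floor_sd,
            loc=floor_mu,
            scale=floor_sd,
            random_state=rng,
        )
    )
    max_drop = baseline_hr - hr_floor
    return PlantParams(
        baseline_hr=baseline_hr,
        max_drop=max_drop,
        perturb_sensitivity=perturb_sensitivity,
        control_sensitivity=perturb_sensitivity,
        block_start_amp=block_start_amp,
        block_sensitivity=block_sensitivity,
        time_constant=time_constant,
        rr_jitter_sd=rr_jitter_sd,
        seed=seed,
    )


def transmission_factor(amp: float, params: PlantParams) -> float:
    """Fraction of perturbation-evoked vagal activity surviving the block.

    1 at or below the starting block amplitude, then falling linearly at
    a rate chosen so that, under a maximal 30 Hz perturbation, the heart
    rate recovers by ``block_sensitivity`` bpm per mA of block amplitude.
    """
    if amp < 0:
        raise ValueError(f"amp must be >= 0, got {amp}")
    if amp <= params.block_start_amp:
        return 1.0
    t = 1.0 - params.block_sensitivity * (amp - params.block_start_amp) / params.max_drop
    return min(1.0, max(0.0, t))


def _vagal_drive(
    params: PlantParams, command: WaveformCommand, perturb_freq: float
) -> float:
    f_stim = command.frequency if command.mode == "stim" else 0.0
    amp = command.amplitude if command.mode == "block" else 0.0
    perturb = min(params.perturb_sensitivity * perturb_freq, params.max_drop)
    drive = perturb * transmission_factor(amp, params) + (
        params.control_sensitivity * f_stim
    )
    return min(params.max_drop, max(0.0, drive))


def plant_step(
    state: PlantState,
    command: WaveformCommand,
    perturb_freq: float,
    dt: float,
    params: PlantParams,
    rng: np.random.Generator | None = None,
) -> PlantState:
    """Advance the heart-rate dynamics by ``dt`` seconds.

    The target heart rate is ``baseline - drive``; the instantaneous
    rate relaxes toward it exponentially with time constant ``tau``.
    ``rng`` is accepted for optional stochastic extensions (e.g. baseline
    drift) and unused by the deterministic core.
    """
    if not 0 < dt <= 0.05:
        raise ValueError(f"dt must be in (0, 0.05] s, got {dt}")
    if perturb_freq < 0:
        raise ValueError("perturb_freq must be >= 0")
    target = params.baseline_hr - _vagal_drive(params, command, perturb_freq)
    decay = math.exp(-dt / params.time_constant)
    hr = target + (state.hr - target) * decay
    return replace(state, hr=hr, target_hr=target, t=state.t + dt)


class BeatGenerator:
    """Incremental R-event emitter.

    Integrates the instantaneous rate (beats/s = hr/60) over each plant
    substep; a nominal beat falls wherever the integral crosses an
    integer.  Each emitted inter-beat interval is the nominal interval
    plus Gaussian jitter, floored at a 20 ms physiological minimum.
    """

    def __init__(self, rng: np.random.Generator, rr_jitter_sd_ms: float) -> None:
        self._rng = rng
        self._sd = rr_jitter_sd_ms / 1000.0
        self._phase = 0.0  # fractional beat count
        self._count = 0  # beats emitted so far (guards against fp double-emission)
        self._last_nominal: float | None = None
        self._last_emitted: float | None = None

    @property
    def phase(self) -> float:
        return self._phase

    def advance(self, t0: float, t1: float, hr0: float, hr1: float) -> list[float]:
        """Integrate from t0 to t1 (hr linear in between); return beat times."""
        if t1 <= t0:
            return []
        rate0, rate1 = hr0 / 60.0, hr1 / 60.0
        beats_in_step = 0.5 * (rate0 + rate1) * (t1 - t0)
        out: list[float] = []
        phase_end = self._phase + beats_in_step
        k = self._count + 1
        while k <= phase_end + 1e-9:
            # invert the (linear-rate) integral for the nominal crossing time
            frac = (k - self._phase) / beats_in_step if beats_in_step > 0 else 1.0
            frac = min(1.0, max(0.0, frac))
            if abs(rate1 - rate0) < 1e-12 * max(rate0, 1.0):
                t_nominal = t0 + frac * (t1 - t0)
            else:
                # solve rate0*s + 0.5*(rate1-rate0)/(t1-t0)*s^2 = k - phase
                a = 0.5 * (rate1 - rate0) / (t1 - t0)
                b = rate0
                c = -(k - self._phase)
                disc = max(0.0, b * b - 4 * a * c)
                s = (-b + math.sqrt(disc)) / (2 * a)
                t_nominal = t0 + min(t1 - t0, max(0.0, s))
            out.append(self._emit(t_nominal))
            self._count = k
            k += 1
        self._phase = phase_end
        return out

    def _emit(self, t_nominal: float) -> float:
        if self._last_nominal is None:
            t = t_nominal
        else:
            interval = t_nominal - self._last_nominal
            if self._sd > 0:
                interval += float(self._rng.normal(0.0, self._sd))
            interval = max(RR_FLOOR_S, interval)
            base = self._last_emitted if self._last_emitted is not None else t_nominal
            t = base + interval
        self._last_nominal = t_nominal
        self._last_emitted = t
        return t


def emit_beats(
    times: np.ndarray,
    hr: np.ndarray,
    rng: np.random.Generator,
    rr_jitter_sd: float = 2.0,
) -> np.ndarray:
    """R-event times for a sampled heart-rate trace.

    ``times`` and ``hr`` are matching arrays (seconds, bpm); the rate is
    interpolated linearly between samples.
    """
    times = np.asarray(times, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if times.shape != hr.shape or times.ndim != 1 or times.size < 2:
        raise ValueError("times and hr must be matching 1-D arrays of length >= 2")
    if np.any(hr <= 0):
        raise ValueError("hr trace must be strictly positive")
    gen = BeatGenerator(rng, rr_jitter_sd)
    beats: list[float] = []
    for i in range(times.size - 1):
        beats.extend(gen.advance(times[i], times[i + 1], hr[i], hr[i + 1]))
    return np.asarray(beats)
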