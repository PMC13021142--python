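"""Calibration of the bimodal electrode: linear sensitivity fits and the
bidirectional conversion from the controller output coefficient to a
waveform command.

Two sweeps are performed per animal.  The stimulation sweep steps the
control-electrode frequency from 1 to 30 Hz and fits heart-rate change
against frequency, yielding a sensitivity in bpm/Hz.  The block sweep
first drives the heart rate down with a maximal 30 Hz perturbation, then
raises the 10 kHz block amplitude in 0.1 mA steps until the heart rate
begins to rise (the largest non-blocking amplitude is the *starting
block current*) and on to full recovery, fitting heart-rate recovery
against amplitude in bpm/mA peak-to-peak.

With those two slopes, a positive ``cout`` divided by the stimulation
sensitivity gives a stimulation frequency, and ``|cout|`` divided by the
block sensitivity, plus the starting block current, gives a block
amplitude — so one ``cout`` unit is roughly one bpm of heart-rate effect
in either mode, and block commands skip the ineffective sub-threshold
amplitude region.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationError",
    "NoBlockError",
    "CalibrationResult",
    "WaveformCommand",
    "OFF_COMMAND",
    "fit_stim_calibration",
    "fit_block_calibration",
    "cout_to_command",
    "run_stim_sweep",
    "run_block_sweep",
    "calibrate_plant",
]

logger = logging.getLogger(__name__)

STIM_PULSE_WIDTH_US = 50.0
BLOCK_CARRIER_HZ = 10_000.0
MAX_STIM_FREQ = 30.0  # Hz
MAX_BLOCK_AMP = 10.0  # mA p-p, hard cap on commanded block amplitude
SWEEP_RESOLUTION = 0.1  # mA p-p, block amplitude step
DEFAULT_RISE_THRESHOLD = 1.0  # bpm above the perturbed plateau (see docs)


class CalibrationError(RuntimeError):
    """Raised when a calibration sweep cannot be fitted."""


class NoBlockError(CalibrationError):
    """Raised when the block sweep never raises the heart rate."""


@dataclass(frozen=True)
class CalibrationResult:
    stim_sensitivity: float  # bpm/Hz, positive
    stim_r2: float
    block_start_amp: float  # mA p-p, largest amplitude that did not block
    block_sensitivity: float  # bpm/mA p-p, positive
    block_r2: float
    stim_max_freq: float = MAX_STIM_FREQ  # Hz of maximal HR drop

    def __post_init__(self) -> None:
        if self.stim_sensitivity < 0 or self.block_sensitivity <= 0:
            raise ValueError("sensitivities must be positive")
        if self.block_start_amp < 0:
            raise ValueError("block_start_amp must be >= 0")
        for name in ("stim_r2", "block_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.stim_max_freq <= MAX_STIM_FREQ:
            raise ValueError("stim_max_freq must lie in (0, 30]")


@dataclass(frozen=True)
class WaveformCommand:
    """Electrode command: low-frequency stimulation, 10 kHz block, or off."""

    mode: str  # "stim" | "block" | "off"
    frequency: float = 0.0  # Hz (stim mode; carrier is implied in block mode)
    amplitude: float = 0.0  # mA p-p (block mode)
    pulse_width_us: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("stim", "block", "off"):
            raise ValueError(f"unknown command mode {self.mode!r}")
        if self.mode == "stim" and not 0 < self.frequency <= MAX_STIM_FREQ:
            raise ValueError(
                f"stim frequency must lie in (0, {MAX_STIM_FREQ}] Hz, got {self.frequency}"
            )
        if self.mode == "block" and self.amplitude < 0:
            raise ValueError("block amplitude must be >= 0")
        if self.mode == "off" and (self.frequency or self.amplitude):
            raise ValueError("off command must have zero outputs")


OFF_COMMAND = WaveformCommand("off")


def fit_stim_calibration(
    freq_hr_pairs: Iterable[tuple[float, float]],
) -> tuple[float, float]:
    """Fit heart rate against stimulation frequency; return (bpm/Hz, r2).

    The sensitivity is reported as a positive magnitude (stimulation
    lowers the heart rate, so the raw HR-vs-frequency slope is negative).
    """
    pairs = np.asarray(list(freq_hr_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("freq_hr_pairs must be (frequency, hr) pairs")
    freqs, hrs = pairs[:, 0], pairs[:, 1]
    if np.unique(freqs).size < 3:
        raise CalibrationError("need at least 3 distinct frequencies for the fit")
    fit = stats.linregress(freqs, hrs)
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2) if np.ptp(hrs) > 0 else 0.0
    if slope == 0.0:
        warnings.warn(
            "flat stimulation response: sensitivity 0 bpm/Hz", stacklevel=2
        )
        return 0.0, r2
    if slope > 0:
        warnings.warn(
            "heart rate rose with stimulation frequency; reporting |slope|",
            stacklevel=2,
        )
    return abs(slope), r2


def fit_block_calibration(
    amp_hr_pairs: Iterable[tuple[float, float]],
    baseline_hr: float,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
    plateau_hr: float | None = None,
) -> tuple[float, float, float]:
    """Block-sweep fit: returns (starting amplitude, bpm/mA, r2).

    ``amp_hr_pairs`` is the amplitude sweep under a maximal perturbation,
    amplitudes strictly increasing.  The starting block amplitude is the
    largest swept amplitude at which the heart rate had not yet risen
    ``rise_threshold`` bpm above the perturbed plateau; the recovery
    slope is fitted from that point up to the first sample reaching the
    resting baseline.
    """
    pairs = np.asarray(list(amp_hr_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("amp_hr_pairs must be >= 3 (amplitude, hr) pairs")
    amps, hrs = pairs[:, 0], pairs[:, 1]
    if np.any(np.diff(amps) <= 0):
        raise ValueError("amplitudes must be strictly increasing")
    resolution = float(np.median(np.diff(amps)))
    plateau = float(hrs[0]) if plateau_hr is None else float(plateau_hr)

    def _onset(plateau_ref: float) -> int:
        not_risen = np.flatnonzero(hrs <= plateau_ref + rise_threshold)
        if not_risen.size == len(hrs):
            raise NoBlockError(
                f"heart rate never rose more than {rise_threshold} bpm above "
                "the perturbed plateau: no block achieved"
            )
        # The largest amplitude that did not block: last reading still at
        # the plateau.  Taking the *last* such reading (rather than the
        # first one above threshold) makes isolated noise blips below the
        # true onset harmless.
        return int(not_risen[-1]) + 1 if not_risen.size else 0

    # Refine the plateau reference from the pre-onset sweep readings (a
    # single plateau measurement doubles the noise in the comparison).
    onset = _onset(plateau)
    for _ in range(2):
        if onset > 0:
            plateau = float(np.mean(hrs[:onset]))
        onset = _onset(plateau)
    if onset == 0:
        # Rise already under way at the first swept amplitude.
        start_amp = max(0.0, float(amps[0]) - resolution)
        seg_lo = 0
    else:
        start_amp = float(amps[onset - 1])
        seg_lo = onset - 1  # include the last non-risen point: it lies on the line

    recovered = np.flatnonzero(hrs[onset:] >= baseline_hr) + onset
    seg_hi = int(recovered[0]) if recovered.size else len(hrs) - 1
    seg_amps = list(amps[seg_lo : seg_hi + 1])
    seg_hrs = list(hrs[seg_lo : seg_hi + 1])
    # Readings within one typical step-rise of the resting baseline may be
    # clamped at full recovery (the true final current falls between grid
    # amplitudes); cut the fitted segment there.
    if len(seg_hrs) > 4:
        typical = float(np.median(np.diff(seg_hrs[: max(4, len(seg_hrs) // 2)])))
        if typical > 0:
            near_top = [
                i for i, h in enumerate(seg_hrs) if h >= baseline_hr - 0.75 * typical
            ]
            if near_top and near_top[0] >= 3:
                seg_amps = seg_amps[: near_top[0] + 1]
                seg_hrs = seg_hrs[: near_top[0] + 1]
    if len(seg_amps) < 3:
        raise CalibrationError(
            "fewer than 3 sweep points between block onset and recovery"
        )
    fit = stats.linregress(seg_amps, seg_hrs)
    slope = float(fit.slope)
    if slope <= 0:
        raise NoBlockError("non-positive recovery slope in the block sweep")
    # Refine the starting current by back-extrapolating the recovery line
    # to the plateau level; the grid detection above only localizes it to
    # one resolution step, and the residual quantization would bias every
    # small block command by up to slope * resolution bpm.
    refined = (plateau - float(fit.intercept)) / slope
    start_amp = float(min(max(refined, start_amp), start_amp + resolution))
    return start_amp, slope, float(fit.rvalue**2)


def cout_to_command(
    cout: float,
    calib: CalibrationResult,
    max_freq: float = MAX_STIM_FREQ,
    max_block_amp: float = MAX_BLOCK_AMP,
) -> WaveformCommand:
    """Convert the controller output coefficient to an electrode command.

    Positive ``cout`` maps to stimulation at ``cout / stim_sensitivity``
    Hz (clamped to the 1-30 Hz band, 50 us pulses); negative ``cout``
    maps to 10 kHz block at ``|cout| / block_sensitivity`` mA above the
    starting block current; zero turns the electrode off.
    """
    cout = float(cout)
    if not math.isfinite(cout):
        raise ValueError(f"cout must be finite, got {cout!r}")
    if cout > 0:
        if calib.stim_sensitivity <= 0:
            raise CalibrationError("stimulation sensitivity is zero; cannot command")
        freq = min(max_freq, cout / calib.stim_sensitivity)
        if freq <= 0:
            return OFF_COMMAND
        return WaveformCommand("stim", frequency=freq, pulse_width_us=STIM_PULSE_WIDTH_US)
    if cout < 0:
        amp = calib.block_start_amp + (-cout) / calib.block_sensitivity
        return WaveformCommand("block", amplitude=min(max_block_amp, amp))
    return OFF_COMMAND


# ---------------------------------------------------------------------------
# Simulated calibration sweeps against the synthetic plant
# ---------------------------------------------------------------------------


def run_stim_sweep(
    params,
    rng,
    freqs: Sequence[float] | None = None,
    dwell_s: float = 10.0,
    dt: float = 0.05,
    saturation_drop: float = 1.0,
):
    """Run the stimulation-frequency calibration sweep on a plant.

    Steps the control electrode through ``freqs`` (default 1..30 Hz in
    1 Hz steps), dwelling ``dwell_s`` at each and reading the rolling
    heart-rate estimate at the end of the dwell.  Stepping stops once
    the heart rate fails to drop by more than ``saturation_drop`` bpm
    over a step — the maximal achievable drop has been reached.
    Returns ``(pairs, rest_hr, saturated)``.
    """
    from .protocol import LoopEngine  # local import to avoid a cycle

    if freqs is None:
        freqs = [float(f) for f in range(1, int(MAX_STIM_FREQ) + 1)]
    engine = LoopEngine(params, rng, dt=dt)
    engine.run_open(10.0, OFF_COMMAND, 0.0)
    rest_hr = _dwell_reading(engine, 0.0, OFF_COMMAND, 0.0)
    pairs: list[tuple[float, float]] = []
    saturated = False
    prev_hr = rest_hr
    for f in freqs:
        cmd = WaveformCommand("stim", frequency=f, pulse_width_us=STIM_PULSE_WIDTH_US)
        hr = _dwell_reading(engine, dwell_s, cmd, 0.0)
        pairs.append((f, hr))
        if hr > prev_hr - saturation_drop and len(pairs) >= 3:
            saturated = True
            break
        prev_hr = hr
    return pairs, rest_hr, saturated


def _dwell_reading(
    engine,
    dwell_s: float,
    command: WaveformCommand,
    perturb_freq: float,
    average_s: float = 5.0,
) -> float:
    """Settle for a dwell, then average rolling estimates over the last
    ``average_s`` seconds (read every 0.5 s) — one sweep measurement.

    Averaging over half the dwell tames beat-jitter noise in the reading;
    the residual settling transient it admits is identical across equal
    sweep steps, so fitted slopes are unaffected.
    """
    settle = max(0.0, dwell_s - average_s)
    if settle > 0:
        engine.run_open(settle, command, perturb_freq)
    reads = []
    for _ in range(round(average_s / 0.5)):
        engine.run_open(0.5, command, perturb_freq)
        reads.append(engine.hr_estimate())
    return float(np.mean(reads))


def run_block_sweep(
    params,
    rng,
    resolution: float = SWEEP_RESOLUTION,
    dwell_s: float = 10.0,
    settle_s: float = 25.0,
    max_amp: float = 30.0,
    dt: float = 0.05,
):
    """Run the block-amplitude calibration sweep on a plant.

    Applies a maximal 30 Hz perturbation, lets the heart rate settle to
    its plateau, then raises the 10 kHz block amplitude in ``resolution``
    steps until the rolling estimate recovers to the resting baseline.
    Returns (pairs, rest_hr, plateau_hr).
    """
    from .protocol import LoopEngine

    engine = LoopEngine(params, rng, dt=dt)
    engine.run_open(10.0, OFF_COMMAND, 0.0)
    rest_hr = _dwell_reading(engine, 0.0, OFF_COMMAND, 0.0)
    plateau_hr = _dwell_reading(engine, settle_s, OFF_COMMAND, MAX_STIM_FREQ)
    pairs: list[tuple[float, float]] = []
    amp = resolution
    while amp <= max_amp + 1e-9:
        cmd = WaveformCommand("block", amplitude=amp)
        hr = _dwell_reading(engine, dwell_s, cmd, MAX_STIM_FREQ)
        pairs.append((round(amp, 6), hr))
        if hr >= rest_hr - 1.0:
            break
        recent = [h for _, h in pairs[-4:]]
        if (
            len(recent) == 4
            and max(recent) - min(recent) < 1.5
            and hr > rest_hr - 5.0
        ):
            break  # flat top just under the (noisy) rest reading
        amp += resolution
    return pairs, rest_hr, plateau_hr


def calibrate_plant(
    params,
    seed: int,
    dwell_s: float = 10.0,
    dt: float = 0.05,
) -> CalibrationResult:
    """Full calibration of one synthetic animal: both sweeps plus fits."""
    from .plant import spawn_rngs

    rng_stim, rng_block = spawn_rngs(seed, 2)
    stim_pairs, _, saturated = run_stim_sweep(params, rng_stim, dwell_s=dwell_s, dt=dt)
    # A saturated sweep ends on the plateau; trim trailing points whose
    # per-step drop collapsed (the knee) and fit the falling segment only.
    fit_pairs = list(stim_pairs)
    if saturated and len(fit_pairs) > 3:
        drops = -np.diff([hr for _, hr in fit_pairs])
        typical = float(np.median(drops))
        while len(fit_pairs) > 3 and -(fit_pairs[-1][1] - fit_pairs[-2][1]) < 0.5 * typical:
            fit_pairs.pop()
    stim_sens, stim_r2 = fit_stim_calibration(fit_pairs)
    hrs = np.array([hr for _, hr in stim_pairs])
    stim_max_freq = float(stim_pairs[int(np.argmin(hrs))][0])
    block_pairs, rest_hr, plateau_hr = run_block_sweep(
        params, rng_block, dwell_s=dwell_s, dt=dt
    )
    start_amp, block_sens, block_r2 = fit_block_calibration(
        block_pairs, baseline_hr=rest_hr - 1.0, plateau_hr=plateau_hr
    )
    return CalibrationResult(
        stim_sensitivity=stim_sens,
        stim_r2=stim_r2,
        block_start_amp=start_amp,
        block_sensitivity=block_sens,
        block_r2=block_r2,
        stim_max_freq=stim_max_freq,
    )
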