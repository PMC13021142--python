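"""Per-trial performance metrics and trial categorization.

A target band of 40-60% normalized heart rate defines acceptable
control.  Each trial is placed in exactly one of three categories:

* ``Oscillations`` — the heart rate completed at least five
  above-and-below excursions of the band (an excursion pair is one
  maximal segment strictly above the band followed by one strictly
  below it, or vice versa);
* ``Slow`` — not oscillating, but outside the band for more than half
  the controller-on duration;
* ``Stable`` — neither.

Across-gain comparisons use two-sided Wilcoxon rank-sum (Mann-Whitney)
tests on each pair of gains.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import TrialRecord

__all__ = [
    "Band",
    "TrialMetrics",
    "time_to_band",
    "time_in_band",
    "count_excursions",
    "categorize",
    "compute_metrics",
    "compare_gains",
    "OSCILLATION_EXCURSIONS",
    "DEFAULT_ALPHA",
]

logger = logging.getLogger(__name__)

OSCILLATION_EXCURSIONS = 5
DEFAULT_ALPHA = 0.005  # significance level for the pairwise rank-sum tests


@dataclass(frozen=True)
class Band:
    lower: float = 40.0  # % normalized HR
    upper: float = 60.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("band must satisfy lower < upper")


@dataclass(frozen=True)
class TrialMetrics:
    time_to_band: float  # s (inf if the band is never reached)
    time_in_band: float  # s
    excursion_count: int
    fraction_outside: float
    category: str  # "Slow" | "Oscillations" | "Stable"


def _trace(record: TrialRecord | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = record.data if isinstance(record, TrialRecord) else record
    return df["t"].to_numpy(float), df["hr_norm"].to_numpy(float)


def time_to_band(record: TrialRecord | pd.DataFrame, band: Band = Band()) -> float:
    """Seconds from controller start until the normalized HR first drops
    below the band's upper edge (trials start near 100%); ``inf`` if never."""
    t, v = _trace(record)
    below = np.flatnonzero(v < band.upper)
    return float(t[below[0]]) if below.size else math.inf


def time_in_band(record: TrialRecord | pd.DataFrame, band: Band = Band()) -> float:
    """Total time with ``lower <= hr_norm <= upper`` over the record."""
    t, v = _trace(record)
    dt = float(np.median(np.diff(t)))
    inside = (v >= band.lower) & (v <= band.upper)
    return float(inside.sum()) * dt


def _excursion_segments(v: np.ndarray, band: Band) -> list[str]:
    """Maximal runs strictly above ('A') or strictly below ('B') the band,
    in time order."""
    zone = np.where(v > band.upper, 1, np.where(v < band.lower, -1, 0))
    segments: list[str] = []
    prev = 0
    for z in zone:
        if z != 0 and z != prev:
            segments.append("A" if z > 0 else "B")
        prev = z
    return segments


def count_excursions(record: TrialRecord | pd.DataFrame, band: Band = Band()) -> int:
    """Number of completed above-and-below excursion pairs.

    The segment-type sequence (A = above band, B = below band, inside
    runs ignored) is scanned left to right; every time a segment of the
    opposite type follows an unpaired one, a pair is completed.  Repeated
    exits on the same side therefore do not count as oscillation.
    """
    _, v = _trace(record)
    segments = _excursion_segments(v, band)
    pairs = 0
    pending: str | None = None
    for seg in segments:
        if pending is not None and seg != pending:
            pairs += 1
            pending = None
        else:
            pending = seg
    return pairs


def categorize(
    record: TrialRecord | pd.DataFrame,
    band: Band = Band(),
    oscillation_excursions: int = OSCILLATION_EXCURSIONS,
) -> str:
    """Assign the trial to Oscillations, Slow, or Stable (in that precedence)."""
    t, v = _trace(record)
    if count_excursions(record, band) >= oscillation_excursions:
        return "Oscillations"
    dt = float(np.median(np.diff(t)))
    duration = v.size * dt
    outside = duration - time_in_band(record, band)
    if outside > 0.5 * duration:
        return "Slow"
    return "Stable"


def compute_metrics(
    record: TrialRecord | pd.DataFrame,
    band: Band = Band(),
    oscillation_excursions: int = OSCILLATION_EXCURSIONS,
) -> TrialMetrics:
    t, v = _trace(record)
    dt = float(np.median(np.diff(t)))
    duration = v.size * dt
    tin = time_in_band(record, band)
    return TrialMetrics(
        time_to_band=time_to_band(record, band),
        time_in_band=tin,
        excursion_count=count_excursions(record, band),
        fraction_outside=(duration - tin) / duration,
        category=categorize(record, band, oscillation_excursions),
    )


def compare_gains(
    metric_values: dict[str | float, list[float]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests across gain groups.

    Uses the exact null distribution for groups of up to 12 untied
    values, the tie-corrected normal approximation otherwise.  Returns a
    frame with one row per pair: group labels, U statistic, p-value, and
    the significance decision at ``alpha``.
    """
    for label, values in metric_values.items():
        if len(values) < 3:
            raise ValueError(f"group {label!r} needs >= 3 values")
    rows = []
    for (la, xa), (lb, xb) in itertools.combinations(metric_values.items(), 2):
        xa, xb = np.asarray(xa, float), np.asarray(xb, float)
        pooled = np.concatenate([xa, xb])
        has_ties = np.unique(pooled).size < pooled.size
        if np.ptp(pooled) == 0:
            warnings.warn(
                f"groups {la!r} and {lb!r} are identical constants; p = 1",
                stacklevel=2,
            )
            u = len(xa) * len(xb) / 2.0
            p = 1.0
        else:
            method = (
                "exact" if not has_ties and max(len(xa), len(xb)) <= 12 else "asymptotic"
            )
            if has_ties:
                warnings.warn(
                    f"ties between groups {la!r} and {lb!r}: using the "
                    "tie-corrected normal approximation",
                    stacklevel=2,
                )
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "n_a": len(xa),
                "n_b": len(xb),
                "U": u,
                "p_value": min(1.0, p),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
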