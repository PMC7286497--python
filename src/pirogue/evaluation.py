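"""Method-performance machinery: surrogate labeling, confusion matrices,
median/MAD aggregation and the sampling-interval degradation experiment.

Fishing is the positive class throughout; "f_prediction"/"nf_prediction"
are the positive/negative predictive values.  Ratios with a zero
denominator are carried as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm_core import (
    FitOptions,
    StateSequence,
    fit,
    initial_params_from_labels,
    viterbi_decode,
)
from .preprocess import StepSeries, speed_series, steps_and_angles
from .synthetic_data import SimulatedTrip, decimate_simulated

FISHING = 0

MEASURES = ("accuracy", "sensitivity", "specificity", "f_prediction", "nf_prediction")

#: The degraded-interval grid: 10-60 s by 10 s, then 2-10 min by 60 s.
DEFAULT_INTERVAL_GRID_S = tuple(range(10, 61, 10)) + tuple(range(120, 601, 60))

__all__ = [
    "MEASURES",
    "DEFAULT_INTERVAL_GRID_S",
    "ConfusionSummary",
    "speed_threshold_labels",
    "confusion",
    "median_mad",
    "aggregate_median_mad",
    "percent_time_fishing",
    "interval_sweep",
    "max_interval_for_event",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Counts plus the five derived performance measures (NaN = undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_dropped: int = 0

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def f_prediction(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def nf_prediction(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def measures(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
            n_dropped=self.n_dropped + other.n_dropped,
        )


def _flip_short_runs(labels: np.ndarray, value: int, min_run: int) -> np.ndarray:
    """Flip maximal runs of ``value`` shorter than min_run to the other class."""
    out = labels.copy()
    n = len(out)
    i = 0
    while i < n:
        if out[i] != value:
            i += 1
            continue
        j = i
        while j < n and out[j] == value:
            j += 1
        if j - i < min_run:
            out[i:j] = 1 - value
        i = j
    return out


def speed_threshold_labels(
    series: StepSeries, vmax_fishing_kmh: float = 7.0, min_run: int = 1
) -> StateSequence:
    """Surrogate for expert visual labeling: speed threshold + shape smoothing.

    Intervals slower than ``vmax_fishing_kmh`` are fishing; runs shorter
    than ``min_run`` (either class) are flipped to emulate the expert's
    shape criterion.  Pass ``min_run = ceil(min_fishing_event_s /
    interval)`` for the gear at hand; the default of 1 disables smoothing.
    Missing-speed intervals get label -1.
    """
    v = speed_series(series)
    labels = np.where(v < vmax_fishing_kmh, 0, 1).astype(int)
    missing = np.isnan(v)
    if min_run > 1:
        labels = _flip_short_runs(labels, 0, min_run)
        labels = _flip_short_runs(labels, 1, min_run)
    labels[missing] = -1
    return StateSequence(trip_id=series.trip_id, labels=labels)


def confusion(truth: StateSequence, predicted: StateSequence) -> ConfusionSummary:
    """Confusion counts, dropping intervals where either labeling is missing."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"label length mismatch: truth {len(truth)} vs predicted {len(predicted)}"
        )
    t = truth.labels
    p = predicted.labels
    ok = (t >= 0) & (p >= 0)
    t, p = t[ok], p[ok]
    return ConfusionSummary(
        tp=int(np.sum((t == FISHING) & (p == FISHING))),
        fp=int(np.sum((t != FISHING) & (p == FISHING))),
        tn=int(np.sum((t != FISHING) & (p != FISHING))),
        fn=int(np.sum((t == FISHING) & (p != FISHING))),
        n_dropped=int(np.sum(~ok)),
    )


def median_mad(values: Sequence[float]) -> tuple[float, float]:
    """Median and median absolute deviation, NaNs dropped."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return math.nan, math.nan
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


def aggregate_median_mad(per_gear: Sequence[ConfusionSummary]) -> dict[str, tuple[float, float]]:
    """Across-gear median (MAD) for each of the five measures."""
    if not per_gear:
        raise ValueError("need at least one summary")
    return {m: median_mad([getattr(s, m) for s in per_gear]) for m in MEASURES}


def percent_time_fishing(labels: StateSequence) -> float:
    """Percentage of labeled intervals spent fishing."""
    lab = labels.labels
    lab = lab[lab >= 0]
    if len(lab) == 0:
        raise ValueError("no labeled intervals")
    return 100.0 * float(np.mean(lab == FISHING))


def max_interval_for_event(min_event_s: float, min_points: int = 3) -> int:
    """Largest sampling interval keeping >= min_points fixes in an event."""
    if min_event_s <= 0:
        raise ValueError("min_event_s must be positive")
    if min_points < 2:
        raise ValueError("min_points must be at least 2")
    return int(min_event_s // min_points)


def interval_sweep(
    fleet: Sequence[SimulatedTrip],
    intervals_s: Sequence[int] = DEFAULT_INTERVAL_GRID_S,
    fit_opts: FitOptions | None = None,
) -> pd.DataFrame:
    """Refit, decode and score per gear at each degraded sampling interval.

    For every interval: decimate the 5-s fleet, recompute observation
    series, seed the model from the (decimated) reference labels, refit per
    gear, Viterbi-decode, and score against the reference labels.  Returns
    a tidy frame (gear, interval_s, measure, value) with across-gear
    aggregate rows (gear = "MEDIAN" / "MAD") per interval.
    """
    fit_opts = fit_opts or FitOptions(n_restarts=1)
    base = fleet[0].trip.interval_s
    rows = []
    for interval in intervals_s:
        if interval % base:
            raise ValueError(
                f"interval {interval} s is not a multiple of the base {base} s"
            )
        factor = int(interval // base)
        by_gear: dict[str, list[SimulatedTrip]] = {}
        for sim in fleet:
            by_gear.setdefault(sim.gear, []).append(
                decimate_simulated(sim, factor) if factor > 1 else sim
            )
        summaries = []
        for gear in sorted(by_gear):
            sims = by_gear[gear]
            series = [steps_and_angles(s.trip) for s in sims]
            refs = [s.truth for s in sims]
            init = initial_params_from_labels(series, refs)
            result = fit(series, init, fit_opts)
            total = ConfusionSummary(0, 0, 0, 0)
            for ss, ref in zip(series, refs):
                total = total + confusion(ref, viterbi_decode(result.params, ss))
            summaries.append(total)
            for m, v in total.measures().items():
                rows.append({"gear": gear, "interval_s": interval, "measure": m, "value": v})
        for m, (med, mad) in aggregate_median_mad(summaries).items():
            rows.append({"gear": "MEDIAN", "interval_s": interval, "measure": m, "value": med})
            rows.append({"gear": "MAD", "interval_s": interval, "measure": m, "value": mad})
    return pd.DataFrame(rows, columns=["gear", "interval_s", "measure", "value"])
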