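"""Synthetic labeled GPS fleets for the seven gear archetypes.

Trips are generated by a two-state Markov chain at a 5-second reference
interval (dead reckoning on the sphere from gamma step lengths and von
Mises turning angles), with the minimum fishing-event duration enforced by
rejection of too-short fishing runs.  Every trip carries its ground-truth
state sequence, so the whole pipeline is testable without field data.

Calibration numbers live in ``profiles.yaml`` next to this module; values
not anchored to published trip statistics are assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from ._geo import destination, wrap_angle
from .hmm_core import StateEmission, StateSequence, stationary_distribution
from .trackio import GEARS, Trip

REFERENCE_INTERVAL_S = 5.0

#: Published per-gear trip counts for the 99-trip study fleet.
DEFAULT_FLEET_COUNTS = {"SCG": 10, "SG": 14, "MCG": 12, "PS": 32, "HL": 12, "LL": 8, "BG": 11}

FISHING, TRANSIT = 0, 1

__all__ = [
    "REFERENCE_INTERVAL_S",
    "DEFAULT_FLEET_COUNTS",
    "GearProfile",
    "SimulatedTrip",
    "default_gear_profiles",
    "simulate_trip",
    "simulate_fleet",
    "corrupt_track",
]


@dataclass
class GearProfile:
    """Simulation parameter bundle for one gear archetype.

    Emissions are at the 5-s reference interval; ``emissions[0]`` is the
    fishing state and must have the smaller step mean.  ``A`` rows are
    [fishing, transit] at the reference interval.
    """

    gear: str
    emissions: tuple[StateEmission, StateEmission]
    A: np.ndarray
    trip_duration_h: tuple[float, float]
    min_fishing_event_s: float
    start_area: tuple[tuple[float, float], tuple[float, float]]  # (lat range, lon range)
    heading_persistence: float  # transit-heading concentration (= transit kappa)
    max_speed_kmh: float = 49.0  # hard engine ceiling; keeps clean tracks under the filter

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.gear not in GEARS:
            raise ValueError(f"unknown gear {self.gear!r}")
        if self.emissions[FISHING].step_mean >= self.emissions[TRANSIT].step_mean:
            raise ValueError(f"{self.gear}: fishing step mean must be below transit's")
        lo, hi = self.trip_duration_h
        if not (2.3 <= lo <= hi <= 76.2):
            raise ValueError(f"{self.gear}: duration range outside the [2.3, 76.2] h envelope")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-10) or self.A.shape != (2, 2):
            raise ValueError(f"{self.gear}: A must be 2x2 row-stochastic")


@dataclass
class SimulatedTrip:
    """A generated trip bundled with its ground truth and provenance."""

    trip: Trip
    truth: StateSequence  # one label per 5-s interval (n_fixes - 1 labels)
    profile: GearProfile
    seed: int
    audit: dict

    @property
    def gear(self) -> str:
        return self.profile.gear


def _speed_to_step(speed_kmh: float, interval_s: float) -> float:
    return speed_kmh / 3.6 * interval_s


def default_gear_profiles(path=None) -> dict[str, GearProfile]:
    """Load the seven gear archetypes from the versioned profile file."""
    if path is None:
        text = resources.files("pirogue").joinpath("profiles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    dt = float(cfg["reference_interval_s"])
    lat_rng = tuple(cfg["start_area"]["lat"])
    lon_rng = tuple(cfg["start_area"]["lon"])
    out = {}
    for gear, p in cfg["profiles"].items():
        ems = []
        for i, key in enumerate(("fishing_speed_kmh", "transit_speed_kmh")):
            mean_kmh, sd_kmh = p[key]
            ems.append(
                StateEmission(
                    step_mean=_speed_to_step(mean_kmh, dt),
                    step_sd=_speed_to_step(sd_kmh, dt),
                    angle_mean=float(p["angle_mean"][i]),
                    angle_concentration=float(p["angle_concentration"][i]),
                )
            )
        a_ff, a_tt = p["a_stay"]
        out[gear] = GearProfile(
            gear=gear,
            emissions=(ems[0], ems[1]),
            A=np.array([[a_ff, 1.0 - a_ff], [1.0 - a_tt, a_tt]]),
            trip_duration_h=tuple(p["trip_duration_h"]),
            min_fishing_event_s=float(p["min_fishing_event_s"]),
            start_area=(lat_rng, lon_rng),
            heading_persistence=float(p["angle_concentration"][1]),
        )
    return out


def _simulate_states(
    rng: np.random.Generator, A: np.ndarray, pi: np.ndarray, n: int, min_fishing_run: int
) -> np.ndarray:
    """State chain built run-by-run; fishing run lengths are geometric
    conditioned (by rejection) on being >= min_fishing_run."""
    states = np.empty(n, dtype=np.int8)
    pos = 0
    s = int(rng.choice(2, p=pi))
    while pos < n:
        p_leave = 1.0 - A[s, s]
        if p_leave <= 0:
            run = n - pos
        else:
            run = int(rng.geometric(p_leave))
            if s == FISHING:
                while run < min_fishing_run:
                    run = int(rng.geometric(p_leave))
        run = min(run, n - pos)
        states[pos : pos + run] = s
        pos += run
        s = 1 - s
    # a truncated trailing fishing run may violate the minimum: absorb it
    if min_fishing_run > 1 and states[-1] == FISHING:
        tail = n - 1
        while tail >= 0 and states[tail] == FISHING:
            tail -= 1
        if (n - 1 - tail) < min_fishing_run:
            states[tail + 1 :] = TRANSIT
    return states


def simulate_trip(
    profile: GearProfile,
    seed: int,
    interval_s: float = REFERENCE_INTERVAL_S,
    trip_id: str | None = None,
    duration_h: float | None = None,
    start_state: int | None = None,
) -> SimulatedTrip:
    """Generate one labeled trip, fully reproducible from ``seed``.

    The chain always runs at the 5-s reference interval; coarser
    ``interval_s`` (a multiple of 5) is produced by decimating positions
    and majority-voting the truth labels, so decimation experiments see
    internally consistent dynamics.
    """
    rng = np.random.default_rng(seed)
    dt = REFERENCE_INTERVAL_S
    if duration_h is None:
        duration_h = float(rng.uniform(*profile.trip_duration_h))
    n_int = int(round(duration_h * 3600.0 / dt))
    if n_int < 10:
        raise ValueError(f"trip duration {duration_h} h gives {n_int} < 10 intervals")
    # a one-hot start makes degenerate (reducible-A) chains simulable
    pi = np.eye(2)[start_state] if start_state is not None else stationary_distribution(profile.A)
    min_run = max(1, math.ceil(profile.min_fishing_event_s / dt))
    states = _simulate_states(rng, profile.A, pi, n_int, min_run)

    shapes = np.array([e.gamma_shape for e in profile.emissions])
    scales = np.array([1.0 / e.gamma_rate for e in profile.emissions])
    steps = rng.gamma(shapes[states], scales[states])
    # clamp to the physical envelope: no zero steps, no speeds above the cap
    steps = np.clip(steps, 1e-6, _speed_to_step(profile.max_speed_kmh, dt))
    mus = np.array([e.angle_mean for e in profile.emissions])
    kappas = np.maximum([e.angle_concentration for e in profile.emissions], 1e-9)
    turns = rng.vonmises(mus[states], np.asarray(kappas)[states])

    # left-positive turning: bearing decreases by the turn angle
    heading0 = rng.uniform(-np.pi, np.pi)
    headings = heading0 - np.concatenate([[0.0], np.cumsum(turns[1:])])
    lat0 = rng.uniform(*profile.start_area[0])
    lon0 = rng.uniform(*profile.start_area[1])
    lat = np.empty(n_int + 1)
    lon = np.empty(n_int + 1)
    lat[0], lon[0] = lat0, lon0
    for i in range(n_int):
        lat[i + 1], lon[i + 1] = destination(lat[i], lon[i], headings[i], steps[i])

    t0 = np.datetime64("2014-03-01T06:00:00") + np.timedelta64(int(seed) % 86_400, "s")
    times = t0 + (np.arange(n_int + 1) * int(dt)).astype("timedelta64[s]")
    tid = trip_id or f"{profile.gear}-{seed}"
    trip = Trip(
        trip_id=tid, times=times, lat=lat, lon=lon, gear=profile.gear, interval_s=dt
    )
    trans = np.zeros((2, 2))
    np.add.at(trans, (states[:-1], states[1:]), 1.0)
    audit = {
        "duration_h": duration_h,
        "realized_transition_counts": trans.tolist(),
        "realized_transition_freq": (
            trans / np.maximum(trans.sum(axis=1, keepdims=True), 1.0)
        ).tolist(),
        "n_intervals": n_int,
    }
    sim = SimulatedTrip(
        trip=trip,
        truth=StateSequence(trip_id=tid, labels=states.astype(int)),
        profile=profile,
        seed=int(seed),
        audit=audit,
    )
    if interval_s != dt:
        sim = decimate_simulated(sim, int(round(interval_s / dt)))
    return sim


def decimate_simulated(sim: SimulatedTrip, factor: int) -> SimulatedTrip:
    """Coarsen a simulated trip: subsample fixes, majority-vote the labels."""
    from .preprocess import decimate  # local import avoids a cycle

    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return sim
    trip = decimate(sim.trip, factor)
    n_coarse = trip.n_fixes - 1
    fine = sim.truth.labels
    labels = np.empty(n_coarse, dtype=int)
    for k in range(n_coarse):
        block = fine[k * factor : (k + 1) * factor]
        counts = np.bincount(block, minlength=2)
        labels[k] = block[0] if counts[0] == counts[1] else int(np.argmax(counts))
    return SimulatedTrip(
        trip=trip,
        truth=StateSequence(trip_id=sim.trip.trip_id, labels=labels,
                            state_names=sim.truth.state_names),
        profile=sim.profile,
        seed=sim.seed,
        audit={**sim.audit, "decimated_by": factor},
    )


def simulate_fleet(
    profiles: dict[str, GearProfile] | None = None,
    n_trips_per_gear: dict[str, int] | None = None,
    master_seed: int = 0,
) -> list[SimulatedTrip]:
    """Deterministic fleet; default counts mirror the 99-trip study fleet."""
    profiles = profiles or default_gear_profiles()
    counts = n_trips_per_gear or {g: DEFAULT_FLEET_COUNTS[g] for g in profiles}
    fleet = []
    for gi, gear in enumerate(sorted(counts)):
        if counts[gear] < 1:
            raise ValueError(f"{gear}: trip count must be >= 1")
        for ti in range(counts[gear]):
            seed = int(np.random.SeedSequence((master_seed, gi, ti)).generate_state(1)[0])
            fleet.append(
                simulate_trip(profiles[gear], seed=seed, trip_id=f"{gear}-{ti:03d}")
            )
    return fleet


def corrupt_track(
    sim: SimulatedTrip, spike_rate: float, gap_rate: float, seed: int
) -> tuple[Trip, dict]:
    """Inject position spikes (> 50 km/h implied) and recording gaps.

    Returns the corrupted raw trip (no longer regular) and an audit of the
    injected artifacts.  Spikes displace interior fixes by ~3 km; gaps
    delete short runs of fixes.  Rates are per-fix probabilities.
    """
    if not (0.0 <= spike_rate < 1.0 and 0.0 <= gap_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    trip = sim.trip
    rng = np.random.default_rng(seed)
    n = trip.n_fixes
    lat = trip.lat.copy()
    lon = trip.lon.copy()
    keep = np.ones(n, dtype=bool)
    audit: dict = {"spikes": [], "gaps": []}
    if gap_rate > 0:
        starts = np.flatnonzero(rng.random(n) < gap_rate)
        for s in starts:
            if s < 2 or s > n - 3:
                continue
            length = int(rng.integers(1, 13))  # up to 12 fixes = 60 s of dropout
            e = min(s + length, n - 2)
            if keep[s:e].all():
                keep[s:e] = False
                audit["gaps"].append({"start_index": int(s), "n_fixes": int(e - s)})
    if spike_rate > 0:
        candidates = np.flatnonzero(keep)[1:-1]
        picks = candidates[rng.random(len(candidates)) < spike_rate]
        for i in picks:
            bearing = rng.uniform(-np.pi, np.pi)
            lat[i], lon[i] = destination(trip.lat[i], trip.lon[i], bearing, 3000.0)
            audit["spikes"].append({"index": int(i)})
    audit["n_spikes"] = len(audit["spikes"])
    audit["n_gap_fixes"] = int((~keep).sum())
    out = Trip(
        trip_id=trip.trip_id,
        times=trip.times[keep],
        lat=lat[keep],
        lon=lon[keep],
        gear=trip.gear,
        interval_s=None,
    )
    return out, audit
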