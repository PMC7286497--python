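"""Two-state (N-state capable) hidden Markov model for vessel movement.

Emissions are gamma step lengths and von Mises turning angles, assumed
conditionally independent given the state.  The model is fitted by direct
maximization of the forward log-likelihood over an unconstrained
reparameterization, and decoded with the Viterbi algorithm.  Missing
observations contribute a likelihood factor of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize, special, stats

from .preprocess import StepSeries

KAPPA_MAX = 700.0  # keeps I0(kappa) finite in double precision

DEFAULT_STATE_NAMES = ("fishing", "non_fishing")

__all__ = [
    "KAPPA_MAX",
    "DEFAULT_STATE_NAMES",
    "StateEmission",
    "HmmParameters",
    "StateSequence",
    "FitOptions",
    "FitResult",
    "gamma_logpdf",
    "vonmises_logpdf",
    "initial_params_from_labels",
    "forward_loglik",
    "fit",
    "viterbi_decode",
    "pseudo_residuals",
    "stationary_distribution",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class StateEmission:
    """Gamma (step, metres) and von Mises (angle, radians) parameters."""

    step_mean: float
    step_sd: float
    angle_mean: float = 0.0
    angle_concentration: float = 1.0

    def __post_init__(self):
        if not (self.step_mean > 0 and np.isfinite(self.step_mean)):
            raise ValueError(f"step_mean must be positive, got {self.step_mean}")
        if not (self.step_sd > 0 and np.isfinite(self.step_sd)):
            raise ValueError(f"step_sd must be positive, got {self.step_sd}")
        if not (-np.pi < self.angle_mean <= np.pi):
            raise ValueError(f"angle_mean must lie in (-pi, pi], got {self.angle_mean}")
        if not (0.0 <= self.angle_concentration <= KAPPA_MAX):
            raise ValueError(
                f"angle_concentration must lie in [0, {KAPPA_MAX}], "
                f"got {self.angle_concentration}"
            )

    @property
    def gamma_shape(self) -> float:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_rate(self) -> float:
        return self.step_mean / self.step_sd**2


@dataclass
class HmmParameters:
    """Initial distribution, transition matrix and per-state emissions."""

    pi: np.ndarray
    A: np.ndarray
    emissions: list[StateEmission]
    state_names: tuple[str, ...] = DEFAULT_STATE_NAMES

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.emissions)
        if n < 2:
            raise ValueError("need at least 2 states")
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {self.A.shape}")
        if self.pi.shape != (n,):
            raise ValueError(f"pi must have length {n}")
        if len(self.state_names) != n:
            raise ValueError("state_names length must match number of states")
        if np.any(self.pi < 0) or np.any(self.A < 0):
            raise ValueError("pi and A entries must be non-negative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi must sum to 1, sums to {self.pi.sum()}")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("rows of A must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.emissions)

    def permuted(self, order: Sequence[int]) -> "HmmParameters":
        """Same model with states reordered (names keep their positions)."""
        order = list(order)
        return HmmParameters(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            emissions=[self.emissions[i] for i in order],
            state_names=self.state_names,
        )

    def to_dict(self) -> dict:
        return {
            "state_names": list(self.state_names),
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "emissions": [
                {
                    "step_mean": e.step_mean,
                    "step_sd": e.step_sd,
                    "angle_mean": e.angle_mean,
                    "angle_concentration": e.angle_concentration,
                }
                for e in self.emissions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParameters":
        return cls(
            pi=np.asarray(d["pi"]),
            A=np.asarray(d["A"]),
            emissions=[StateEmission(**e) for e in d["emissions"]],
            state_names=tuple(d["state_names"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "HmmParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class StateSequence:
    """Per-interval state labels; -1 marks an unlabeled interval."""

    trip_id: str
    labels: np.ndarray  # int codes into state_names
    state_names: tuple[str, ...] = DEFAULT_STATE_NAMES
    log_joint: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.log_joint is not None and not np.isfinite(self.log_joint):
            raise ValueError("log_joint must be finite")
        if np.any((self.labels < -1) | (self.labels >= len(self.state_names))):
            raise ValueError("labels outside state vocabulary")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def names(self) -> list[str]:
        return [self.state_names[i] if i >= 0 else "" for i in self.labels]


# ---------------------------------------------------------------------------
# Emission densities
# ---------------------------------------------------------------------------

def gamma_logpdf(x, mean, sd):
    """Log-density of the gamma distribution in mean/sd parameterization."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    x = np.asarray(x, dtype=float)
    out = shape * np.log(rate) - special.gammaln(shape) + (shape - 1.0) * np.log(x) - rate * x
    return out if out.ndim else float(out)


def vonmises_logpdf(theta, mu, kappa):
    """Log-density of the von Mises distribution on (-pi, pi].

    log I0 is computed via the exponentially scaled Bessel function, so the
    density stays finite up to kappa = KAPPA_MAX.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    kappa = min(kappa, KAPPA_MAX)
    theta = np.asarray(theta, dtype=float)
    log_i0 = np.log(special.i0e(kappa)) + kappa
    out = kappa * np.cos(theta - mu) - np.log(2.0 * np.pi) - log_i0
    return out if out.ndim else float(out)


def _vonmises_cdf_from_minus_pi(theta, mu, kappa):
    """CDF of the von Mises law on (-pi, pi] with fixed origin -pi.

    Using one common origin for every state keeps the state-weighted
    mixture a valid CDF, which the pseudo-residual transform requires.
    """
    theta = np.asarray(theta, dtype=float)
    z = np.angle(np.exp(1j * (theta - mu)))  # wrapped into [-pi, pi]
    z0 = np.angle(np.exp(1j * (-np.pi - mu)))
    base = stats.vonmises.cdf(z, kappa)  # integral from -pi to z, loc = 0
    off = stats.vonmises.cdf(z0, kappa)
    u = np.mod(base - off, 1.0)
    u = np.where(theta >= np.pi, 1.0, u)
    return u


# ---------------------------------------------------------------------------
# Observation packing
# ---------------------------------------------------------------------------

def _observations(series: StepSeries) -> tuple[np.ndarray, np.ndarray]:
    """Align steps and angles into T = M-1 paired observations.

    Observation t carries step[t]; its angle is the turning angle at grid
    fix t, undefined (NaN) for t = 0.  Zero steps are invalid for the gamma
    density and are flagged missing for the step stream.
    """
    step = series.step.astype(float).copy()
    with np.errstate(invalid="ignore"):
        step[step <= 0.0] = np.nan
    angle = np.full_like(step, np.nan)
    if len(series.angle):
        angle[1:] = series.angle
    return step, angle


def _log_emissions(params: HmmParameters, step: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """(T, N) log emission densities; missing streams contribute 0."""
    T = len(step)
    logb = np.zeros((T, params.n_states))
    s_ok = ~np.isnan(step)
    a_ok = ~np.isnan(angle)
    for j, e in enumerate(params.emissions):
        if s_ok.any():
            logb[s_ok, j] += gamma_logpdf(step[s_ok], e.step_mean, e.step_sd)
        if a_ok.any():
            logb[a_ok, j] += vonmises_logpdf(angle[a_ok], e.angle_mean, e.angle_concentration)
    return logb


def _check_params_finite(params: HmmParameters) -> None:
    for e in params.emissions:
        if not all(
            np.isfinite([e.step_mean, e.step_sd, e.angle_mean, e.angle_concentration])
        ):
            raise ValueError("non-finite emission parameter")
    if not (np.all(np.isfinite(params.pi)) and np.all(np.isfinite(params.A))):
        raise ValueError("non-finite pi or A")


# ---------------------------------------------------------------------------
# Forward algorithm and Viterbi
# ---------------------------------------------------------------------------

def _forward_many(logpi, logA, logb_stack) -> float:
    """Summed log-likelihood over S padded series; logb_stack is (S, T, N).

    Padded tail positions must be all-zero columns (missing observations);
    they leave each series' likelihood unchanged because the rows of A sum
    to one.
    """
    expA = np.exp(logA)
    a = logpi[None, :] + logb_stack[:, 0, :]
    with np.errstate(divide="ignore"):
        for t in range(1, logb_stack.shape[1]):
            m = a.max(axis=1, keepdims=True)
            a = m + np.log(np.exp(a - m) @ expA) + logb_stack[:, t, :]
        m = a.max(axis=1)
        return float(np.sum(m + np.log(np.exp(a - m[:, None]).sum(axis=1))))


def forward_loglik(params: HmmParameters, series: StepSeries) -> float:
    """Observation log-likelihood summed over all state paths."""
    _check_params_finite(params)
    if series.n_obs < 1:
        raise ValueError("series has no observations")
    step, angle = _observations(series)
    logb = _log_emissions(params, step, angle)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
    return _forward_many(logpi, logA, logb[None, :, :])


def viterbi_decode(params: HmmParameters, series: StepSeries) -> StateSequence:
    """Most probable state path (ties broken toward the lower state index)."""
    _check_params_finite(params)
    if series.n_obs < 1:
        raise ValueError("series has no observations")
    step, angle = _observations(series)
    logb = _log_emissions(params, step, angle)
    T, N = logb.shape
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
    delta = logpi + logb[0]
    back = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first (lowest) index wins ties
        delta = cand[back[t], np.arange(N)] + logb[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return StateSequence(
        trip_id=series.trip_id,
        labels=path,
        state_names=params.state_names,
        log_joint=float(delta.max()),
    )


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("A must be square and row-stochastic")
    reach = np.linalg.matrix_power(np.eye(n) + A, n - 1) if n > 1 else np.ones((1, 1))
    if np.any(reach <= 0):
        raise ValueError("A is reducible; no unique stationary distribution")
    # solve delta (A - I) = 0 with the normalization sum(delta) = 1
    M = np.vstack([A.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(M, b, rcond=None)
    delta = np.clip(delta, 0.0, None)
    return delta / delta.sum()


# ---------------------------------------------------------------------------
# Moment initialization from labeled data
# ---------------------------------------------------------------------------

def _kappa_from_r(r: float) -> float:
    """Invert the mean resultant length to a von Mises concentration.

    Standard piecewise approximation (Best & Fisher); capped at KAPPA_MAX
    for degenerate (perfectly aligned) samples.
    """
    if r < 0:
        raise ValueError("resultant length must be non-negative")
    if r >= 1.0:
        return KAPPA_MAX
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    return float(min(max(k, 0.0), KAPPA_MAX))


def initial_params_from_labels(
    series: Sequence[StepSeries],
    labels: Sequence[StateSequence],
    n_states: int = 2,
    state_names: tuple[str, ...] | None = None,
) -> HmmParameters:
    """Moment-based seed parameters from reference-labeled observations.

    Per-state step mean/sd are sample moments of the labeled steps; the
    angle mean is the mean direction and kappa comes from the mean
    resultant length.  A holds the empirical transition frequencies and pi
    the empirical first-interval state frequencies.
    """
    if len(series) != len(labels):
        raise ValueError("series and labels must be aligned 1:1")
    if state_names is None:
        state_names = (
            DEFAULT_STATE_NAMES if n_states == 2 else tuple(f"state_{i}" for i in range(n_states))
        )
    steps_by_state: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    angles_by_state: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    trans = np.zeros((n_states, n_states))
    first = np.zeros(n_states)
    for ss, lab in zip(series, labels):
        y = lab.labels
        if len(y) != ss.n_obs:
            raise ValueError(
                f"trip {ss.trip_id}: {len(y)} labels for {ss.n_obs} observations"
            )
        step, angle = _observations(ss)
        for j in range(n_states):
            sel = y == j
            steps_by_state[j].append(step[sel & ~np.isnan(step)])
            angles_by_state[j].append(angle[sel & ~np.isnan(angle)])
        valid = y >= 0
        if valid.any():
            first[y[np.argmax(valid)]] += 1
        pair = valid[:-1] & valid[1:]
        np.add.at(trans, (y[:-1][pair], y[1:][pair]), 1.0)
    emissions = []
    for j in range(n_states):
        st = np.concatenate(steps_by_state[j]) if steps_by_state[j] else np.empty(0)
        if len(st) < 2:
            raise ValueError(
                f"state {state_names[j]!r} has {len(st)} usable step observations; "
                "need at least 2"
            )
        an = np.concatenate(angles_by_state[j]) if angles_by_state[j] else np.empty(0)
        if len(an) >= 2:
            c, s = np.cos(an).sum(), np.sin(an).sum()
            mu = float(np.arctan2(s, c))
            r = float(np.hypot(c, s) / len(an))
            kappa = _kappa_from_r(r)
        else:
            mu, kappa = 0.0, 0.1
        emissions.append(
            StateEmission(
                step_mean=float(st.mean()),
                step_sd=float(max(st.std(ddof=1), 1e-9)),
                angle_mean=mu if -np.pi < mu <= np.pi else np.pi,
                angle_concentration=kappa,
            )
        )
    rows = trans.sum(axis=1, keepdims=True)
    A = np.where(rows > 0, trans / np.where(rows > 0, rows, 1.0), 1.0 / n_states)
    A = A / A.sum(axis=1, keepdims=True)
    pi = first / first.sum() if first.sum() else np.full(n_states, 1.0 / n_states)
    return HmmParameters(pi=pi, A=A, emissions=emissions, state_names=state_names)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    n_restarts: int = 3
    stationary_pi: bool = False
    maxiter: int = 500
    seed: int = 0
    jitter: float = 0.2


@dataclass
class FitResult:
    params: HmmParameters
    loglik: float
    converged: bool
    n_evaluations: int
    restart_logliks: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _pack_theta(params: HmmParameters, stationary_pi: bool) -> np.ndarray:
    n = params.n_states
    theta = []
    for e in params.emissions:
        theta += [
            np.log(e.step_mean),
            np.log(e.step_sd),
            np.cos(e.angle_mean),
            np.sin(e.angle_mean),
            np.log(max(e.angle_concentration, 1e-6)),
        ]
    A = np.clip(params.A, 1e-8, None)
    for i in range(n):
        for j in range(n):
            if j != i:
                theta.append(np.log(A[i, j] / A[i, i]))
    if not stationary_pi:
        pi = np.clip(params.pi, 1e-8, None)
        theta += list(np.log(pi[1:] / pi[0]))
    return np.asarray(theta, dtype=float)


def _unpack_theta(
    theta: np.ndarray, n: int, stationary_pi: bool, state_names
) -> HmmParameters:
    k = 0
    emissions = []
    for _ in range(n):
        lm, ls, cx, sy, lk = theta[k : k + 5]
        k += 5
        emissions.append(
            StateEmission(
                step_mean=float(np.exp(np.clip(lm, -50, 50))),
                step_sd=float(np.exp(np.clip(ls, -50, 50))),
                angle_mean=float(np.arctan2(sy, cx)) if (sy, cx) != (0.0, 0.0) else 0.0,
                angle_concentration=float(min(np.exp(np.clip(lk, -50, 50)), KAPPA_MAX)),
            )
        )
    A = np.zeros((n, n))
    for i in range(n):
        z = np.zeros(n)
        for j in range(n):
            if j != i:
                z[j] = theta[k]
                k += 1
        z -= z.max()
        row = np.exp(z)
        A[i] = row / row.sum()
    if stationary_pi:
        pi = stationary_distribution(A)
    else:
        z = np.concatenate([[0.0], theta[k : k + n - 1]])
        z -= z.max()
        pi = np.exp(z) / np.exp(z).sum()
    return HmmParameters(pi=pi, A=A, emissions=emissions, state_names=tuple(state_names))


def _stack_logb(params: HmmParameters, obs: list[tuple[np.ndarray, np.ndarray]]):
    T = max(len(s) for s, _ in obs)
    S, N = len(obs), params.n_states
    logb = np.zeros((S, T, N))
    for i, (step, angle) in enumerate(obs):
        logb[i, : len(step), :] = _log_emissions(params, step, angle)
    return logb


def fit(
    series: Sequence[StepSeries],
    init: HmmParameters,
    opts: FitOptions | None = None,
) -> FitResult:
    """Maximize the pooled forward log-likelihood from a seed parameter set.

    Quasi-Newton (L-BFGS-B with numerical gradients) on the unconstrained
    reparameterization; ``opts.n_restarts`` jittered restarts with seeds
    fixed per restart index.  The returned log-likelihood is never below
    the seed's (the seed is always a candidate).  After fitting, states are
    relabeled so that the first-named state ("fishing") has the smallest
    step mean.
    """
    if not series:
        raise ValueError("no series to fit")
    opts = opts or FitOptions()
    _check_params_finite(init)
    n = init.n_states
    obs = [_observations(s) for s in series]
    n_eval = 0

    def nll(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            p = _unpack_theta(theta, n, opts.stationary_pi, init.state_names)
        except (ValueError, FloatingPointError):
            return 1e12
        logb = _stack_logb(p, obs)
        if not np.all(np.isfinite(logb)):
            return 1e12
        with np.errstate(divide="ignore"):
            ll = _forward_many(np.log(np.clip(p.pi, 1e-300, None)),
                               np.log(np.clip(p.A, 1e-300, None)), logb)
        return -ll if np.isfinite(ll) else 1e12

    theta0 = _pack_theta(init, opts.stationary_pi)
    init_ll = -nll(theta0)
    starts = [theta0]
    for r in range(1, opts.n_restarts):
        rng = np.random.default_rng((opts.seed, r))
        jittered = _jitter_params(init, rng, opts.jitter)
        starts.append(_pack_theta(jittered, opts.stationary_pi))

    best_theta, best_ll, converged, restart_lls = theta0, init_ll, False, []
    n_fail = 0
    for th0 in starts:
        try:
            res = optimize.minimize(
                nll, th0, method="L-BFGS-B", options={"maxiter": opts.maxiter}
            )
        except Exception:
            n_fail += 1
            restart_lls.append(-np.inf)
            continue
        restart_lls.append(-res.fun)
        if -res.fun > best_ll:
            best_ll, best_theta, converged = -res.fun, res.x, bool(res.success)
        elif -res.fun == best_ll and res.success:
            converged = True
    if n_fail == len(starts):
        raise RuntimeError(
            f"optimizer failed on all {len(starts)} restarts; best seed loglik {init_ll:.3f}"
        )
    params = _unpack_theta(best_theta, n, opts.stationary_pi, init.state_names)
    # label convention: first-named state is the slow (small-step) one
    order = list(np.argsort([e.step_mean for e in params.emissions], kind="stable"))
    params = params.permuted(order)

    warns = []
    means = np.array([e.step_mean for e in params.emissions])
    if means.max() > 0 and (means.max() - means.min()) / means.max() < 1e-3:
        warns.append(
            "states have near-identical step emissions; the likelihood is flat "
            "in A and state labels are not identifiable"
        )
        converged = True
    if best_ll <= init_ll:
        best_ll, params = init_ll, _relabeled(init)
        converged = True
    return FitResult(
        params=params,
        loglik=best_ll,
        converged=converged,
        n_evaluations=n_eval,
        restart_logliks=restart_lls,
        warnings=warns,
    )


def _relabeled(params: HmmParameters) -> HmmParameters:
    order = list(np.argsort([e.step_mean for e in params.emissions], kind="stable"))
    return params.permuted(order)


def _jitter_params(params: HmmParameters, rng: np.random.Generator, scale: float):
    emissions = []
    for e in params.emissions:
        emissions.append(
            StateEmission(
                step_mean=e.step_mean * (1.0 + rng.uniform(-scale, scale)),
                step_sd=e.step_sd * (1.0 + rng.uniform(-scale, scale)),
                angle_mean=float(
                    np.angle(np.exp(1j * (e.angle_mean + rng.normal(0.0, scale))))
                ),
                angle_concentration=float(
                    np.clip(
                        max(e.angle_concentration, 1e-3) * (1.0 + rng.uniform(-scale, scale)),
                        1e-3,
                        KAPPA_MAX,
                    )
                ),
            )
        )
    n = params.n_states
    A = np.vstack(
        [rng.dirichlet(np.clip(params.A[i], 1e-3, None) * 50.0) for i in range(n)]
    )
    pi = rng.dirichlet(np.clip(params.pi, 1e-3, None) * 50.0)
    return HmmParameters(pi=pi, A=A, emissions=emissions, state_names=params.state_names)


# ---------------------------------------------------------------------------
# Pseudo-residuals
# ---------------------------------------------------------------------------

@dataclass
class PseudoResiduals:
    trip_id: str
    step: np.ndarray  # standard-normal scale, NaN where the step is missing
    angle: np.ndarray


def pseudo_residuals(params: HmmParameters, series: StepSeries) -> PseudoResiduals:
    """One-step-ahead forecast pseudo-residuals for both data streams.

    The forecast distribution of observation t mixes the state emissions
    with the predictive state probabilities given observations 1..t-1 (the
    first observation uses pi).  Each stream's forecast CDF value is mapped
    through the standard normal quantile; under a correct model the
    residuals of each stream are iid standard normal.
    """
    _check_params_finite(params)
    step, angle = _observations(series)
    T = len(step)
    N = params.n_states
    logb = _log_emissions(params, step, angle)
    w = params.pi.astype(float).copy()  # predictive P(q_t | o_{1:t-1})
    step_res = np.full(T, np.nan)
    angle_res = np.full(T, np.nan)
    shapes = np.array([e.gamma_shape for e in params.emissions])
    rates = np.array([e.gamma_rate for e in params.emissions])
    for t in range(T):
        if not np.isnan(step[t]):
            u = float(np.dot(w, stats.gamma.cdf(step[t], shapes, scale=1.0 / rates)))
            step_res[t] = stats.norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
        if not np.isnan(angle[t]):
            u = float(
                sum(
                    w[j]
                    * _vonmises_cdf_from_minus_pi(
                        angle[t], params.emissions[j].angle_mean,
                        max(params.emissions[j].angle_concentration, 1e-12),
                    )
                    for j in range(N)
                )
            )
            angle_res[t] = stats.norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
        # filter and propagate
        b = np.exp(logb[t] - logb[t].max())
        phi = w * b
        s = phi.sum()
        phi = phi / s if s > 0 else np.full(N, 1.0 / N)
        w = phi @ params.A
    return PseudoResiduals(trip_id=series.trip_id, step=step_res, angle=angle_res)
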