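"""Online Bayesian decoding of the hidden state and information metrics.

The posterior log-odds of the hidden state given the input history,
``L(t) = ln p(x=1 | I_0..t) / p(x=0 | I_0..t)``, obeys

    dL/dt = r_on (1 + e^-L) - r_off (1 + e^L) + I(t) - theta,

integrated here by forward Euler at the trace's time step (with a
stiffness guard, see `_kernels`).  The posterior ``p = 1/(1+e^-L)`` doubles
as an estimate ``x_hat`` of the hidden state.  From the pair (x, p) we
estimate the conditional entropy by the time-averaged surprisal, the
mutual information as ``MI = H_xx - H_xy`` (a lower bound), the
mean-squared reconstruction error, and delay-corrected variants obtained
by shifting the estimate by the peak lag of its cross-correlogram with x.

A spike train is decoded through the same ODE by turning it into an
impulse drive: rates ``q_on_hat/q_off_hat`` are counted against the hidden
state, each spike contributes an impulse of area ``w_hat =
ln(q_on_hat/q_off_hat)``, and the offset is ``theta_hat = q_on_hat -
q_off_hat``.

All log-odds are in natural-log units; entropies and informations are
reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from ._kernels import integrate_log_odds_core
from .population import CurrentTrace, SpikeTrain
from .telegraph import HiddenStateTrace, empirical_entropy

__all__ = [
    "PosteriorTrace",
    "RateEstimates",
    "InfoReport",
    "integrate_log_odds_from_input",
    "estimate_rates",
    "spike_train_drive",
    "decode_spike_train",
    "conditional_entropy",
    "mutual_information",
    "mse",
    "mse_measures",
    "shift_correct",
    "score_posterior",
]

L_MAX = 30.0  # |L| clip, natural-log units
P_EPS = 1e-12  # posterior clip before logs
STEP_CAP = 1.0  # Euler substep guard threshold, natural-log units


@dataclass
class PosteriorTrace:
    """Posterior log-odds L and probability p per time bin."""

    L: np.ndarray
    dt: float
    source: str = "input"

    def __post_init__(self) -> None:
        self.L = np.ascontiguousarray(self.L, dtype=float)

    @property
    def p(self) -> np.ndarray:
        """Posterior probability of x = 1, clipped away from {0, 1}."""
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-self.L))
        return np.clip(p, P_EPS, 1.0 - P_EPS)


def integrate_log_odds_from_input(
    trace: CurrentTrace,
    r_on: float,
    r_off: float,
    theta: float | None = None,
    l0: float | None = None,
    l_max: float = L_MAX,
) -> PosteriorTrace:
    """Integrate the log-odds ODE driven by a dimensionless input trace.

    ``theta`` defaults to the offset recorded on the trace; ``l0`` defaults
    to the prior log-odds ``ln(r_on/r_off)``.
    """
    if trace.units != "dimensionless":
        raise ValueError("decoder operates on the dimensionless drive, not ampere")
    if theta is None:
        theta = trace.offset_theta
    if l0 is None:
        l0 = float(np.log(r_on / r_off))
    L = integrate_log_odds_core(
        trace.values, trace.dt, r_on, r_off, theta, l0, l_max, STEP_CAP
    )
    return PosteriorTrace(L, trace.dt, "input")


@dataclass(frozen=True)
class RateEstimates:
    """Spike rates of one train conditioned on the hidden state."""

    q_on_hat: float
    q_off_hat: float

    @property
    def w_hat(self) -> float:
        return float(np.log(self.q_on_hat / self.q_off_hat))

    @property
    def theta_hat(self) -> float:
        return float(self.q_on_hat - self.q_off_hat)


def estimate_rates(
    spikes: SpikeTrain,
    hidden: HiddenStateTrace,
    q_floor: float | None = None,
) -> RateEstimates:
    """Count spikes against the hidden state: spikes during x=1 (resp. 0)
    divided by the total time spent in that state.

    A state with zero spikes gets its rate floored at one expected count
    over the time spent in that state (``1 / T_state``) so the weight stays
    finite; this is reported with a warning.
    """
    dt = hidden.dt
    n_on = int(hidden.x.sum())
    n_off = hidden.x.size - n_on
    if n_on == 0 or n_off == 0:
        raise ValueError("hidden state must visit both states")
    if spikes.n_spikes:
        idx = spikes.bin_indices(dt)
        if idx[-1] >= hidden.x.size:
            raise ValueError("spike times extend beyond the hidden-state trace")
        k_on = int(hidden.x[idx].sum())
        k_off = spikes.n_spikes - k_on
    else:
        k_on = k_off = 0
    t_on = n_on * dt
    t_off = n_off * dt
    q_on = k_on / t_on
    q_off = k_off / t_off
    if k_on == 0:
        q_on = 1.0 / t_on if q_floor is None else q_floor
        warnings.warn("no spikes during x=1; q_on_hat floored", stacklevel=2)
    if k_off == 0:
        q_off = 1.0 / t_off if q_floor is None else q_floor
        warnings.warn("no spikes during x=0; q_off_hat floored", stacklevel=2)
    return RateEstimates(q_on, q_off)


def spike_train_drive(
    spikes: SpikeTrain,
    est: RateEstimates,
    dt: float,
    n_steps: int | None = None,
) -> CurrentTrace:
    """Impulse (delta-spike) drive for decoding a spike train.

    Each spike contributes ``w_hat / dt`` to its bin so that its time
    integral is ``w_hat``; coincident spikes in a bin sum.  The trace's
    offset is ``theta_hat``.
    """
    if n_steps is None:
        n_steps = int(round(spikes.duration / dt))
    drive = np.zeros(n_steps)
    if spikes.n_spikes:
        np.add.at(drive, spikes.bin_indices(dt), est.w_hat / dt)
    return CurrentTrace(drive, dt, "dimensionless", est.theta_hat)


def decode_spike_train(
    spikes: SpikeTrain,
    hidden: HiddenStateTrace,
    r_on: float | None = None,
    r_off: float | None = None,
) -> tuple[PosteriorTrace, RateEstimates]:
    """Full spike-train decoding pipeline: rate estimation, impulse drive,
    log-odds integration.  Returns the posterior and the rate estimates."""
    if r_on is None:
        r_on = hidden.params.r_on
    if r_off is None:
        r_off = hidden.params.r_off
    est = estimate_rates(spikes, hidden)
    drive = spike_train_drive(spikes, est, hidden.dt, hidden.x.size)
    post = integrate_log_odds_from_input(drive, r_on, r_off)
    post.source = "spike_train"
    return post, est


def _clip_p(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_EPS, 1.0 - P_EPS)


def conditional_entropy(
    hidden: HiddenStateTrace | np.ndarray, post: PosteriorTrace | np.ndarray
) -> float:
    """Time-averaged surprisal of x under the posterior, in bits.

    ``H_xy = -< x log2 p + (1-x) log2 (1-p) >_time``; this is the plug-in
    conditional-entropy estimate (an upper bound, making MI a lower bound).
    """
    x = hidden.x if isinstance(hidden, HiddenStateTrace) else np.asarray(hidden)
    p = post.p if isinstance(post, PosteriorTrace) else _clip_p(np.asarray(post, float))
    if x.size != p.size:
        raise ValueError("hidden state and posterior lengths differ")
    xf = x.astype(float)
    h = -(xf * np.log2(p) + (1.0 - xf) * np.log2(1.0 - p))
    return float(h.mean())


def mutual_information(
    hidden: HiddenStateTrace | np.ndarray, post: PosteriorTrace | np.ndarray
) -> float:
    """``MI_hat = H_xx_hat - H_xy_hat`` in bits (may be slightly negative)."""
    x = hidden.x if isinstance(hidden, HiddenStateTrace) else np.asarray(hidden)
    return empirical_entropy(x) - conditional_entropy(x, post)


def mse(
    hidden: HiddenStateTrace | np.ndarray, post: PosteriorTrace | np.ndarray
) -> float:
    """Mean-squared error of the posterior as a hidden-state estimate."""
    x = hidden.x if isinstance(hidden, HiddenStateTrace) else np.asarray(hidden)
    p = post.p if isinstance(post, PosteriorTrace) else np.asarray(post, float)
    if x.size != p.size:
        raise ValueError("length mismatch")
    return float(np.mean((p - x.astype(float)) ** 2))


def _poisson_surrogate(
    n_spikes: int, window: tuple[float, float], rng: np.random.Generator
) -> SpikeTrain:
    """Homogeneous surrogate with exactly the given spike count (uniform
    order statistics, i.e. a Poisson train conditioned on its count)."""
    t0, t1 = window
    times = np.sort(rng.uniform(t0, t1, n_spikes))
    # enforce strict ordering at float resolution (ties have measure zero)
    while times.size > 1 and np.any(np.diff(times) <= 0):  # pragma: no cover
        times = np.sort(rng.uniform(t0, t1, n_spikes))
    return SpikeTrain(times, window)


def mse_measures(
    hidden: HiddenStateTrace,
    post_spike: PosteriorTrace,
    post_input: PosteriorTrace | None = None,
    spikes: SpikeTrain | None = None,
    n_poisson: int = 100,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """(MSE, MSE_P, FMSE) for a decoded spike train.

    ``MSE_P`` normalizes by the mean MSE of ``n_poisson`` homogeneous
    Poisson surrogates with the same spike count, each decoded by the same
    pipeline (requires ``spikes``); ``FMSE`` is the ratio to the
    input-based MSE (requires ``post_input``).  Unavailable ratios are NaN.
    """
    mse_spike = mse(hidden, post_spike)
    mse_p = float("nan")
    if spikes is not None and n_poisson >= 1:
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        vals = np.empty(n_poisson)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare floored-rate surrogates
            for i in range(n_poisson):
                surr = _poisson_surrogate(spikes.n_spikes, spikes.window, rng)
                post, _ = decode_spike_train(surr, hidden)
                vals[i] = mse(hidden, post)
        mse_p = mse_spike / float(vals.mean())
    fmse = float("nan")
    if post_input is not None:
        fmse = mse_spike / mse(hidden, post_input)
    return mse_spike, mse_p, fmse


def shift_correct(
    hidden: HiddenStateTrace | np.ndarray,
    post: PosteriorTrace,
    lag_max: float = 0.05,
) -> tuple[float, float]:
    """Delay-corrected information.

    Finds the lag in ``[0, lag_max]`` seconds at which the
    cross-correlogram of x and the estimate peaks (kernels and membranes
    delay the estimate relative to x), shifts the estimate back by that
    lag, and recomputes MI on the aligned pair.  Ties break toward the
    smallest lag; a flat correlogram warns and returns lag 0.
    """
    x = (hidden.x if isinstance(hidden, HiddenStateTrace) else np.asarray(hidden)).astype(
        float
    )
    p = post.p
    dt = post.dt
    n = x.size
    max_shift = int(round(lag_max / dt))
    if max_shift >= n:
        raise ValueError("record shorter than the maximal lag window")
    xc = x - x.mean()
    pc = p - p.mean()
    cc = np.empty(max_shift + 1)
    for k in range(max_shift + 1):
        cc[k] = float(xc[: n - k] @ pc[k:]) / (n - k)
    if np.allclose(cc, cc[0]):
        warnings.warn("flat cross-correlogram; lag set to 0", stacklevel=2)
        best = 0
    else:
        best = int(np.argmax(cc))  # argmax returns the first (smallest) peak
    mi_star = mutual_information(x[: n - best] if best else x, p[best:] if best else p)
    return best * dt, mi_star


def _nanfield(value: float | None) -> float:
    return float("nan") if value is None else value


@dataclass
class InfoReport:
    """All scalar outcomes for one (signal, hidden-state) pair.

    Entropies and informations are in bits; ``F`` is MI as a fraction of
    the hidden-state entropy, ``FI`` the spike-train MI as a fraction of
    the input MI, ``lag`` the cross-correlogram peak in seconds, and the
    starred quantities their delay-corrected counterparts.
    """

    source: str
    H_xx_hat: float
    H_xy_hat: float
    MI_hat: float
    F: float
    lag: float
    MI_star_hat: float
    MSE: float
    FI: float = float("nan")
    FI_star: float = float("nan")
    MSE_P: float = float("nan")
    FMSE: float = float("nan")
    q_on_hat: float = float("nan")
    q_off_hat: float = float("nan")
    rate: float = float("nan")
    window_index: int = 0
    t0: float = 0.0
    t1: float = float("nan")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def score_posterior(
    hidden: HiddenStateTrace,
    post: PosteriorTrace,
    lag_max: float = 0.05,
) -> InfoReport:
    """Bundle the information and error metrics for one decoded signal."""
    h_xx = empirical_entropy(hidden)
    h_xy = conditional_entropy(hidden, post)
    mi = h_xx - h_xy
    lag, mi_star = shift_correct(hidden, post, lag_max)
    return InfoReport(
        source=post.source,
        H_xx_hat=h_xx,
        H_xy_hat=h_xy,
        MI_hat=mi,
        F=mi / h_xx if h_xx > 0 else float("nan"),
        lag=lag,
        MI_star_hat=mi_star,
        MSE=mse(hidden, post),
    )
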