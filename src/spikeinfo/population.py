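"""The artificial presynaptic population and the current it generates.

``N`` Poisson neurons fire at rate ``q_on_i`` while the hidden state is ON
and ``q_off_i`` while it is OFF.  Rates are drawn i.i.d. from a Gaussian
with mean ``mu_q`` and SD ``mu_q / 8`` (truncated at a small positive
floor).  Each neuron's spikes are weighted by its log-likelihood ratio
``w_i = ln(q_on_i / q_off_i)`` and convolved with a causal exponential
kernel of 5 ms time constant and unit area, mimicking post-synaptic
currents.  The summed, weighted, convolved trace is the dimensionless
stimulus ``I(t)``; an affine map (holding current + scale factor) turns it
into an injectable current for a current-clamp rig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .telegraph import HiddenStateTrace

__all__ = [
    "PresynapticPopulation",
    "KernelSpec",
    "CurrentTrace",
    "ScalingParams",
    "SpikeTrain",
    "draw_population",
    "generate_population_spikes",
    "exponential_kernel",
    "build_input",
    "scale_current",
]

RATE_FLOOR = 1e-6  # Hz; Gaussian draws below this are redrawn


@dataclass
class SpikeTrain:
    """Ordered spike times (seconds) on a fixed observation window."""

    times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.ascontiguousarray(self.times, dtype=float)
        t0, t1 = self.window
        if t1 <= t0:
            raise ValueError("window must have positive length")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < t0 or self.times[-1] >= t1:
                raise ValueError("spike times must lie within the window")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    @property
    def rate(self) -> float:
        """Mean firing rate over the window, Hz."""
        return self.n_spikes / self.duration

    def shifted(self, t0: float) -> "SpikeTrain":
        """Re-reference the window to start at zero minus ``t0``."""
        return SpikeTrain(self.times - t0, (self.window[0] - t0, self.window[1] - t0))

    def bin_indices(self, dt: float) -> np.ndarray:
        """Index of the time bin holding each spike (floor(t/dt))."""
        return np.floor((self.times - self.window[0]) / dt).astype(np.int64)


@dataclass
class PresynapticPopulation:
    """Realized rates, weights and offset of the artificial population.

    Invariants (checked): ``w_i = ln(q_on_i/q_off_i)`` and
    ``theta = sum_i(q_on_i - q_off_i)`` unless the population was drawn
    with ``zero_theta=True`` (the idealized choice in which the constant
    offset is taken to be exactly zero).
    """

    q_on: np.ndarray
    q_off: np.ndarray
    w: np.ndarray
    mu_q: float
    sigma_q: float
    theta: float

    def __post_init__(self) -> None:
        self.q_on = np.asarray(self.q_on, dtype=float)
        self.q_off = np.asarray(self.q_off, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.q_on.shape == self.q_off.shape == self.w.shape):
            raise ValueError("q_on, q_off, w must share a shape")
        if np.any(self.q_on < 0) or np.any(self.q_off < 0):
            raise ValueError("rates must be nonnegative")
        if abs(self.sigma_q - self.mu_q / 8.0) > 1e-12 * max(1.0, self.mu_q):
            raise ValueError("sigma_q must equal mu_q / 8")

    @property
    def N(self) -> int:
        return self.q_on.size


def draw_population(
    N: int,
    mu_q: float,
    seed: int | np.random.Generator | None = None,
    *,
    zero_theta: bool = False,
    rate_floor: float = RATE_FLOOR,
) -> PresynapticPopulation:
    """Draw ON/OFF rates from Gaussian(mu_q, mu_q/8) and derive weights.

    Draws below ``rate_floor`` are redrawn (the SD is small enough that
    virtually all draws are positive, but the weights require strictly
    positive rates).  ``zero_theta=True`` forces the recorded offset to be
    exactly 0 instead of the realized ``sum(q_on - q_off)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not mu_q > 0:
        raise ValueError("mu_q must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma_q = mu_q / 8.0

    def truncated(size: int) -> np.ndarray:
        out = rng.normal(mu_q, sigma_q, size)
        bad = out < rate_floor
        while np.any(bad):
            out[bad] = rng.normal(mu_q, sigma_q, int(bad.sum()))
            bad = out < rate_floor
        return out

    q_on = truncated(N)
    q_off = truncated(N)
    w = np.log(q_on / q_off)
    theta = 0.0 if zero_theta else float(np.sum(q_on - q_off))
    return PresynapticPopulation(q_on, q_off, w, mu_q, sigma_q, theta)


def generate_population_spikes(
    pop: PresynapticPopulation,
    hidden: HiddenStateTrace,
    seed: int | np.random.Generator | None = None,
) -> list[SpikeTrain]:
    """State-modulated Bernoulli spike trains, one per neuron.

    Per neuron and per time bin a spike occurs with probability
    ``q(x_t) * dt`` (at most one spike per bin).  Sampling is done by the
    exact equivalent: a binomial count over the ON (resp. OFF) bins plus a
    uniform choice of bins without replacement.  Spikes are stamped at the
    start of their bin.
    """
    dt = hidden.dt
    qmax = max(pop.q_on.max(), pop.q_off.max())
    if qmax * dt >= 1:
        raise ValueError(f"max rate * dt = {qmax * dt:.3g} >= 1; refine dt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    on_bins = np.flatnonzero(hidden.x == 1)
    off_bins = np.flatnonzero(hidden.x == 0)
    window = (0.0, hidden.x.size * dt)
    trains: list[SpikeTrain] = []
    for i in range(pop.N):
        picked = []
        for bins, q in ((on_bins, pop.q_on[i]), (off_bins, pop.q_off[i])):
            if bins.size == 0:
                continue
            k = rng.binomial(bins.size, min(q * dt, 1.0))
            if k:
                picked.append(rng.choice(bins, size=k, replace=False, shuffle=False))
        if picked:
            idx = np.sort(np.concatenate(picked))
            times = idx * dt
        else:
            times = np.empty(0)
        trains.append(SpikeTrain(times, window))
    return trains


@dataclass(frozen=True)
class KernelSpec:
    """Causal exponential PSC kernel: time constant ``tau_k``, unit area."""

    tau_k: float = 0.005
    surface: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_k > 0:
            raise ValueError("tau_k must be positive")


def exponential_kernel(spec: KernelSpec, dt: float, cutoff: float = 12.0) -> np.ndarray:
    """Sampled causal kernel ``k_j ∝ exp(-j dt / tau_k)``, j >= 0.

    Normalized so the discrete integral ``sum_j k_j * dt`` equals
    ``spec.surface`` exactly.  Truncated at ``cutoff`` time constants.
    Rejects ``dt >= tau_k`` (the kernel would be undersampled).
    """
    if dt >= spec.tau_k:
        raise ValueError(f"dt={dt} undersamples the kernel (tau_k={spec.tau_k})")
    n = int(np.ceil(cutoff * spec.tau_k / dt))
    k = np.exp(-np.arange(n) * dt / spec.tau_k)
    k *= spec.surface / (k.sum() * dt)
    return k


@dataclass
class CurrentTrace:
    """A uniformly sampled input signal with time-step metadata.

    ``units`` is ``"dimensionless"`` for the model-side signal (Hz-like
    drive entering the log-odds ODE) or ``"ampere"`` after scaling.
    ``offset_theta`` records the population offset the trace was generated
    with, which the decoder subtracts.
    """

    values: np.ndarray
    dt: float
    units: str = "dimensionless"
    offset_theta: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_steps(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def slice(self, i0: int, i1: int) -> "CurrentTrace":
        return CurrentTrace(
            self.values[i0:i1], self.dt, self.units, self.offset_theta, dict(self.meta)
        )


def build_input(
    pop: PresynapticPopulation,
    spikes: Sequence[SpikeTrain],
    kernel: KernelSpec | np.ndarray = KernelSpec(),
    dt: float | None = None,
    n_steps: int | None = None,
) -> CurrentTrace:
    """Weight-sum the spike trains and convolve with the PSC kernel.

    Returns the dimensionless population current: each spike of neuron i
    contributes ``w_i`` times the unit-area kernel, so the time integral of
    a single spike's contribution is exactly ``w_i``.  Convolution is
    causal with zero initial condition (no wrap-around).
    """
    if len(spikes) != pop.N:
        raise ValueError("one spike train per neuron required")
    if not spikes:
        raise ValueError("empty population")
    window = spikes[0].window
    for st in spikes:
        if st.window != window:
            raise ValueError("spike trains must share the observation window")
    if dt is None:
        raise ValueError("dt is required")
    if n_steps is None:
        n_steps = int(round((window[1] - window[0]) / dt))

    impulse = np.zeros(n_steps)
    for w_i, st in zip(pop.w, spikes):
        if st.n_spikes:
            idx = st.bin_indices(dt)
            np.add.at(impulse, idx, w_i)
    k = exponential_kernel(kernel, dt) if isinstance(kernel, KernelSpec) else kernel
    values = fftconvolve(impulse, k)[:n_steps]
    return CurrentTrace(values, dt, "dimensionless", pop.theta, {"N": pop.N})


@dataclass(frozen=True)
class ScalingParams:
    """Affine map from the dimensionless drive to the injected current:
    ``I_injected = I_hold + I_scale * I_markov``.  Amperes; ``I_scale``
    must be positive."""

    I_hold: float
    I_scale: float

    def __post_init__(self) -> None:
        if not self.I_scale > 0:
            raise ValueError("I_scale must be positive")


def scale_current(trace: CurrentTrace, scaling: ScalingParams) -> CurrentTrace:
    """Scale a dimensionless trace to ampere for injection.

    Applying this to an already-scaled trace is rejected (double scaling).
    """
    if trace.units != "dimensionless":
        raise ValueError(f"trace already in {trace.units}; refusing to double-scale")
    values = scaling.I_hold + scaling.I_scale * trace.values
    meta = dict(trace.meta)
    meta.update(I_hold=scaling.I_hold, I_scale=scaling.I_scale)
    return CurrentTrace(values, trace.dt, "ampere", trace.offset_theta, meta)
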