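"""The hidden stimulus: a two-state (telegraph) Markov process.

A binary variable x(t) switches 0 -> 1 at rate ``r_on`` and 1 -> 0 at rate
``r_off`` (both in Hz).  Its stationary occupancy of the ON state is
``p1 = r_on / (r_on + r_off)`` and its relaxation time constant is
``tau = 1 / (r_on + r_off)``.  Everything downstream — the presynaptic
population, the decoder, the Bayesian neuron — is scored against this
process, whose entropy per time step is the binary entropy of ``p1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from ._kernels import telegraph_chain

__all__ = [
    "MarkovParams",
    "HiddenStateTrace",
    "simulate_hidden_state",
    "entropy_rate",
    "empirical_entropy",
]


@dataclass(frozen=True)
class MarkovParams:
    """Generative parameters of the telegraph process.

    Parameters
    ----------
    r_on, r_off : float
        Switching rates in Hz; both must be positive.
    dt : float
        Simulation time step in seconds.  The per-step switching
        probabilities ``r_on * dt`` and ``r_off * dt`` must be < 1.
    duration : float
        Total simulated time in seconds (>= dt).
    seed : int, optional
        Seed for the trace generator; ``simulate_hidden_state`` may also be
        handed an explicit Generator, in which case the seed is ignored.
    """

    r_on: float
    r_off: float
    dt: float
    duration: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.r_on > 0 and self.r_off > 0):
            raise ValueError("switching rates must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")
        if self.r_on * self.dt >= 1 or self.r_off * self.dt >= 1:
            raise ValueError(
                "time step too coarse: require r_on*dt < 1 and r_off*dt < 1 "
                f"(got {self.r_on * self.dt:.3g}, {self.r_off * self.dt:.3g})"
            )

    @property
    def tau(self) -> float:
        """Relaxation time constant 1/(r_on + r_off), seconds."""
        return 1.0 / (self.r_on + self.r_off)

    @property
    def p1(self) -> float:
        """Stationary probability of the ON state."""
        return self.r_on / (self.r_on + self.r_off)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def prior_log_odds(self) -> float:
        """ln(p1 / (1 - p1)), the decoder's resting point."""
        return float(np.log(self.r_on / self.r_off))


@dataclass
class HiddenStateTrace:
    """A realization of the telegraph process, one 0/1 value per time bin."""

    x: np.ndarray
    params: MarkovParams

    def __post_init__(self) -> None:
        self.x = np.ascontiguousarray(self.x, dtype=np.uint8)
        if self.x.ndim != 1 or self.x.size == 0:
            raise ValueError("trace must be a nonempty 1-d array")
        if np.any(self.x > 1):
            raise ValueError("trace values must be 0 or 1")

    @property
    def dt(self) -> float:
        return self.params.dt

    @property
    def duration(self) -> float:
        return self.x.size * self.params.dt

    @property
    def occupancy(self) -> float:
        """Empirical fraction of time in the ON state."""
        return float(self.x.mean())

    def slice(self, i0: int, i1: int) -> "HiddenStateTrace":
        """A view of bins ``[i0, i1)`` as a new trace (same parameters)."""
        sub = self.x[i0:i1]
        p = self.params
        return HiddenStateTrace(
            sub,
            MarkovParams(p.r_on, p.r_off, p.dt, sub.size * p.dt, p.seed),
        )


def simulate_hidden_state(
    params: MarkovParams, rng: np.random.Generator | None = None
) -> HiddenStateTrace:
    """Simulate the discrete-time telegraph process.

    Per step, 0 -> 1 with probability ``r_on * dt`` and 1 -> 0 with
    probability ``r_off * dt``.  The initial state is drawn from the
    stationary distribution Bernoulli(p1), so no burn-in is needed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x0 = np.uint8(rng.random() < params.p1)
    u = rng.random(params.n_steps)
    x = telegraph_chain(u, x0, params.r_on * params.dt, params.r_off * params.dt)
    return HiddenStateTrace(x, params)


def entropy_rate(p1: float) -> float:
    """Binary entropy of the hidden state in bits, ``H(p1)``.

    ``0 * log2(0)`` is taken as 0, so the degenerate states return 0 bits.
    """
    if not 0.0 <= p1 <= 1.0:
        raise ValueError(f"p1 must lie in [0, 1], got {p1}")
    return float(-(xlogy(p1, p1) + xlogy(1.0 - p1, 1.0 - p1)) / np.log(2.0))


def empirical_entropy(trace: HiddenStateTrace | np.ndarray) -> float:
    """Entropy estimate from a realization: ``H(<x>_time)`` in bits.

    This is the plug-in estimate using the empirical occupancy; for long
    traces it converges to ``entropy_rate(p1)``.
    """
    x = trace.x if isinstance(trace, HiddenStateTrace) else np.asarray(trace)
    if x.size == 0:
        raise ValueError("empty trace")
    return entropy_rate(float(x.mean()))
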