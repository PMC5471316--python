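"""The "Bayesian neuron": an ideal-observer spiking encoder.

The neuron tracks two log-odds: L, the posterior given its input, and G,
the posterior that a downstream observer could reconstruct from its output
spikes alone.  G drifts under the prior dynamics only; whenever L exceeds
G by more than eta/2 the neuron fires and jumps G by eta, so each spike
conveys exactly the "new" evidence the observer is missing:

    dL/dt = r_on (1 + e^-L) - r_off (1 + e^L) + I(t) - theta
    dG/dt = r_on (1 + e^-G) - r_off (1 + e^G)
    if L > G + eta/2:  spike, G -> G + eta

eta is the single free parameter and sets the output firing rate (larger
eta, fewer and more reliable spikes); it is calibrated by bisection to
match a target rate on a frozen input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import bayesian_neuron_core
from .decoding import L_MAX, STEP_CAP
from .population import CurrentTrace, SpikeTrain

__all__ = ["BNParams", "BNHistory", "simulate_bn", "calibrate_eta", "EtaBracketError"]


@dataclass(frozen=True)
class BNParams:
    """Parameters of the optimal encoder; ``eta`` in natural-log-odds units."""

    r_on: float
    r_off: float
    theta: float = 0.0
    eta: float = 1.0
    dt: float = 2e-4

    def __post_init__(self) -> None:
        if not (self.r_on > 0 and self.r_off > 0):
            raise ValueError("rates must be positive")
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")


@dataclass
class BNHistory:
    """Per-bin L and G trajectories plus the spike mask (post-update)."""

    L: np.ndarray
    G: np.ndarray
    spike_mask: np.ndarray
    dt: float


def simulate_bn(
    trace: CurrentTrace, params: BNParams, l0: float | None = None
) -> tuple[SpikeTrain, BNHistory]:
    """Simulate the encoder on a dimensionless input trace.

    Deterministic given the trace.  Per bin the states are Euler-updated,
    then the threshold is tested once; at most one spike per bin.  G starts
    equal to L(0) (zero initial surprise), and L(0) is the prior log-odds
    unless overridden.
    """
    if trace.units != "dimensionless":
        raise ValueError("the encoder consumes the dimensionless drive")
    if trace.dt != params.dt:
        raise ValueError(f"trace dt {trace.dt} != params dt {params.dt}")
    if l0 is None:
        l0 = float(np.log(params.r_on / params.r_off))
    L, G, sp = bayesian_neuron_core(
        trace.values,
        params.dt,
        params.r_on,
        params.r_off,
        params.theta,
        params.eta,
        l0,
        l0,
        L_MAX,
        STEP_CAP,
    )
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(G))):
        raise FloatingPointError(
            f"non-finite encoder state (eta={params.eta}, theta={params.theta})"
        )
    bins = np.flatnonzero(sp)
    train = SpikeTrain(bins * params.dt, (0.0, trace.duration))
    return train, BNHistory(L, G, sp.astype(bool), params.dt)


class EtaBracketError(RuntimeError):
    """The target firing rate is not attainable within the eta bounds."""


def calibrate_eta(
    trace: CurrentTrace,
    params: BNParams,
    target_rate: float,
    rtol: float = 0.05,
    bounds: tuple[float, float] = (1e-3, 60.0),
    max_iter: int = 60,
) -> float:
    """Bisection on eta to match a target firing rate on a frozen input.

    Exploits that the realized rate is non-increasing in eta.  Raises
    `EtaBracketError` if the target is outside the rates attainable at the
    bounds (a 0 Hz target is never attainable at finite eta).
    """
    if not target_rate > 0:
        raise EtaBracketError("target rate must be positive (0 Hz needs eta -> inf)")

    def rate_at(eta: float) -> float:
        train, _ = simulate_bn(trace, replace(params, eta=eta))
        return train.rate

    lo, hi = bounds
    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_hi <= target_rate <= r_lo):
        raise EtaBracketError(
            f"target {target_rate:.3g} Hz outside attainable range "
            f"[{r_hi:.3g}, {r_lo:.3g}] Hz for eta in {bounds}"
        )
    best_eta, best_err = lo, abs(r_lo - target_rate)
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # eta spans decades; bisect geometrically
        r_mid = rate_at(mid)
        err = abs(r_mid - target_rate)
        if err < best_err:
            best_eta, best_err = mid, err
        if err <= rtol * target_rate:
            return mid
        if r_mid > target_rate:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-6:
            break
    if best_err <= rtol * target_rate:
        return best_eta
    raise EtaBracketError(
        f"bisection stalled: best rate error {best_err:.3g} Hz at eta={best_eta:.4g} "
        f"(target {target_rate:.3g} Hz, rtol {rtol})"
    )
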