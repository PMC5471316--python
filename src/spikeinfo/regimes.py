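"""Parameter studies: built-in stimulus regimes, the tau x mu_q
information sweep, the eta sweep of the Bayesian neuron, and the
saturating fit of information fraction versus firing rate.

The five built-in regimes all keep ``r_off = 2 r_on`` so the hidden state
occupies ON a third of the time and its entropy is ~0.9183 bits
regardless of switching speed; the regimes then differ only in how fast
the state switches (tau) and how hard the presynaptic population fires
(mu_q), i.e. in autocorrelation time and amplitude of the input at
controlled information content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import decoding
from .bayesian_neuron import BNParams, calibrate_eta, simulate_bn
from .model import InformationTransfer
from .population import KernelSpec, build_input, draw_population, generate_population_spikes
from .telegraph import HiddenStateTrace, MarkovParams, simulate_hidden_state

__all__ = [
    "RegimeSpec",
    "builtin_regimes",
    "generate_regime_input",
    "sweep_information",
    "tradeoff_slope",
    "bn_rate_info_curve",
    "peak_rate",
    "SaturationModel",
    "SaturationResults",
    "fit_saturation",
]


@dataclass(frozen=True)
class RegimeSpec:
    """A named (r_on, r_off, mu_q) stimulus configuration."""

    name: str
    r_on: float
    r_off: float
    mu_q: float

    def __post_init__(self) -> None:
        if abs(self.r_off - 2.0 * self.r_on) > 1e-9 * self.r_off:
            raise ValueError("built-in regimes require r_off = 2 r_on")

    @property
    def tau(self) -> float:
        """Relaxation time constant in seconds."""
        return 1.0 / (self.r_on + self.r_off)

    @property
    def p1(self) -> float:
        return self.r_on / (self.r_on + self.r_off)

    def markov_params(self, dt: float, duration: float, seed=None) -> MarkovParams:
        return MarkovParams(self.r_on, self.r_off, dt, duration, seed)


# Exact-ratio rates: the slow ON rate is 20/3 Hz so that tau is exactly
# 50/10/20 ms; the table below also records the rounded decimals the way
# they are usually quoted.
_R_SLOW = 20.0 / 3.0

_REGIMES = {
    "S": RegimeSpec("S", _R_SLOW, 2 * _R_SLOW, 0.5),
    "F": RegimeSpec("F", 5 * _R_SLOW, 10 * _R_SLOW, 2.5),
    "P": RegimeSpec("P", 2.5 * _R_SLOW, 5 * _R_SLOW, 1.3),
    "SH": RegimeSpec("SH", _R_SLOW, 2 * _R_SLOW, 2.5),
    "FL": RegimeSpec("FL", 5 * _R_SLOW, 10 * _R_SLOW, 0.5),
}

#: Rounded rates (Hz) as conventionally printed, keyed by regime name.
PRINTED_RATES = {
    "S": (6.7, 13.3),
    "F": (33.3, 66.7),
    "P": (16.7, 33.3),
    "SH": (6.7, 13.3),
    "FL": (33.3, 66.7),
}


def builtin_regimes() -> list[RegimeSpec]:
    """The five standard regimes: S, F, P, SH, FL."""
    return list(_REGIMES.values())


def get_regime(name: str) -> RegimeSpec:
    try:
        return _REGIMES[name.upper()]
    except KeyError:
        raise KeyError(f"unknown regime {name!r}; choose from {sorted(_REGIMES)}")


def generate_regime_input(
    regime: RegimeSpec,
    N: int = 1000,
    duration: float = 20.0,
    dt: float = 2e-4,
    seed: int | np.random.SeedSequence | None = None,
    kernel: KernelSpec = KernelSpec(),
):
    """Hidden state + population + input current for one regime.

    One seed governs everything through independent child streams (frozen-
    noise reproducibility).  Returns (hidden, population, trace).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    r_hidden, r_pop, r_spk = [np.random.default_rng(s) for s in ss.spawn(3)]
    hidden = simulate_hidden_state(regime.markov_params(dt, duration), rng=r_hidden)
    pop = draw_population(N, regime.mu_q, r_pop)
    trains = generate_population_spikes(pop, hidden, r_spk)
    trace = build_input(pop, trains, kernel, dt=dt, n_steps=hidden.x.size)
    return hidden, pop, trace


def sweep_information(
    tau_grid,
    mu_q_grid,
    N: int = 1000,
    duration: float = 20.0,
    seeds=range(5),
    dt: float = 2e-4,
) -> pd.DataFrame:
    """Mean input-information fraction F over a (tau, mu_q) grid.

    ``r_off = 2 r_on`` is maintained so the hidden-state entropy is the
    same in every cell.  Returns one row per cell with the seed-mean and
    SD of F and MI.  Cells whose switching rate is too fast for the time
    step are rejected.
    """
    tau_grid = np.asarray(list(tau_grid), float)
    mu_q_grid = np.asarray(list(mu_q_grid), float)
    if tau_grid.size == 0 or mu_q_grid.size == 0:
        raise ValueError("empty grid")
    seeds = list(seeds)
    rows = []
    for i, tau in enumerate(tau_grid):
        r_on = 1.0 / (3.0 * tau)
        for j, mu_q in enumerate(mu_q_grid):
            regime = RegimeSpec(f"tau{tau:g}_mu{mu_q:g}", r_on, 2 * r_on, mu_q)
            f_vals, mi_vals, h_vals = [], [], []
            for s in seeds:
                ss = np.random.SeedSequence([int(s), i, j])
                hidden, _, trace = generate_regime_input(
                    regime, N=N, duration=duration, dt=dt, seed=ss
                )
                post = decoding.integrate_log_odds_from_input(
                    trace, regime.r_on, regime.r_off
                )
                h_xx = decoding.empirical_entropy(hidden)
                mi = h_xx - decoding.conditional_entropy(hidden, post)
                h_vals.append(h_xx)
                mi_vals.append(mi)
                f_vals.append(mi / h_xx)
            rows.append(
                dict(
                    tau=tau,
                    mu_q=mu_q,
                    F_mean=float(np.mean(f_vals)),
                    F_sd=float(np.std(f_vals, ddof=1)) if len(seeds) > 1 else 0.0,
                    MI_mean=float(np.mean(mi_vals)),
                    H_xx_mean=float(np.mean(h_vals)),
                    n_seeds=len(seeds),
                )
            )
    return pd.DataFrame(rows)


def tradeoff_slope(sweep: pd.DataFrame, level: float = 0.5):
    """log-log slope of the mu_q needed to reach F = ``level`` versus tau.

    For each tau the crossing is interpolated linearly in (log mu_q, F);
    taus whose F column does not bracket the level are skipped.  Returns
    ``(slope, crossings)`` where crossings is a DataFrame (tau, mu_star).
    """
    crossings = []
    for tau, sub in sweep.groupby("tau"):
        sub = sub.sort_values("mu_q")
        f = sub.F_mean.to_numpy()
        mu = sub.mu_q.to_numpy()
        above = f >= level
        if not above.any() or above.all():
            continue
        k = int(np.argmax(above))  # first cell at/above the level
        if k == 0:
            continue
        x0, x1 = np.log(mu[k - 1]), np.log(mu[k])
        f0, f1 = f[k - 1], f[k]
        mu_star = np.exp(x0 + (level - f0) * (x1 - x0) / (f1 - f0))
        crossings.append((tau, mu_star))
    if len(crossings) < 2:
        raise ValueError("fewer than two taus cross the requested level")
    cr = pd.DataFrame(crossings, columns=["tau", "mu_star"])
    slope = float(np.polyfit(np.log(cr.tau), np.log(cr.mu_star), 1)[0])
    return slope, cr


def bn_rate_info_curve(
    regime: RegimeSpec,
    eta_grid=None,
    N: int = 1000,
    duration: float = 20.0,
    seed: int | np.random.SeedSequence | None = 0,
    dt: float = 2e-4,
    rate_span: tuple[float, float] = (1.0, 100.0),
    n_eta: int = 15,
    lag_max: float = 0.05,
) -> pd.DataFrame:
    """(firing rate, FI) of the Bayesian neuron across an eta sweep.

    The input is generated once (frozen) for the regime.  If no eta grid
    is given, eta is calibrated at both ends of ``rate_span`` on the
    frozen input and a geometric grid of ``n_eta`` values is used.  Etas
    that yield no spikes report FI = 0.
    """
    hidden, _, trace = generate_regime_input(
        regime, N=N, duration=duration, dt=dt, seed=seed
    )
    post_in = decoding.integrate_log_odds_from_input(trace, regime.r_on, regime.r_off)
    mi_in = decoding.mutual_information(hidden, post_in)
    _, mi_in_star = decoding.shift_correct(hidden, post_in, lag_max)
    params = BNParams(regime.r_on, regime.r_off, theta=trace.offset_theta, dt=dt)
    if eta_grid is None:
        eta_hi = calibrate_eta(trace, params, rate_span[0], rtol=0.2)
        eta_lo = calibrate_eta(trace, params, rate_span[1], rtol=0.2)
        eta_grid = np.geomspace(eta_lo, eta_hi, n_eta)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # floored q_off at large eta is expected
        for eta in np.asarray(eta_grid, float):
            train, _ = simulate_bn(trace, BNParams(
                regime.r_on, regime.r_off, trace.offset_theta, float(eta), dt
            ))
            if train.n_spikes == 0:
                rows.append(dict(eta=float(eta), rate=0.0, MI_spike=0.0,
                                 MI_input=mi_in, MI_input_star=mi_in_star,
                                 FI=0.0, lag=0.0, FI_star=0.0))
                continue
            post_sp, _ = decode(train, hidden, regime)
            mi_sp = decoding.mutual_information(hidden, post_sp)
            lag, mi_sp_star = decoding.shift_correct(hidden, post_sp, lag_max)
            rows.append(
                dict(
                    eta=float(eta),
                    rate=train.rate,
                    MI_spike=mi_sp,
                    MI_input=mi_in,
                    MI_input_star=mi_in_star,
                    FI=mi_sp / mi_in if mi_in > 0 else float("nan"),
                    lag=lag,
                    FI_star=mi_sp_star / mi_in_star if mi_in_star > 0 else float("nan"),
                )
            )
    return pd.DataFrame(rows).sort_values("rate").reset_index(drop=True)


def decode(train, hidden: HiddenStateTrace, regime: RegimeSpec):
    """Decode a spike train against a hidden state with regime rates."""
    return decoding.decode_spike_train(train, hidden, regime.r_on, regime.r_off)


def peak_rate(curve: pd.DataFrame, col: str = "FI") -> float:
    """Firing rate at the information maximum of an eta-sweep curve.

    Refined by a quadratic fit in log-rate through the argmax and its
    neighbors; falls back to the raw argmax at the curve edges.
    """
    sub = curve[curve.rate > 0].reset_index(drop=True)
    if not len(sub):
        raise ValueError("no spiking points on the curve")
    k = int(sub[col].idxmax())
    if k == 0 or k == len(sub) - 1:
        return float(sub.rate[k])
    x = np.log(sub.rate[k - 1 : k + 2].to_numpy())
    y = sub[col][k - 1 : k + 2].to_numpy()
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:  # degenerate (flat/convex) triple: keep the raw argmax
        return float(sub.rate[k])
    return float(np.exp(-b / (2 * a)))


def windowed_analysis(
    hidden: HiddenStateTrace,
    input_trace=None,
    spikes=None,
    window: float = 20.0,
    **fit_kw,
) -> list[decoding.InfoReport]:
    """Split a record into consecutive windows and score each one.

    Thin wrapper over `InformationTransfer.fit`; returns the per-window
    reports (one per signal source per window).
    """
    model = InformationTransfer(hidden, input_trace=input_trace, spikes=spikes)
    return model.fit(window=window, **fit_kw).reports


def _saturation(r, f_sat, nu_sat):
    return 2.0 * f_sat * (1.0 / (1.0 + np.exp(-nu_sat * r)) - 0.5)


class SaturationModel:
    """Saturating relation between firing rate and information fraction.

    ``FI(r) = 2 f_sat (1/(1+exp(-nu_sat r)) - 1/2)``: zero at zero rate,
    rising with slope ``f_sat nu_sat / 2`` and saturating at ``f_sat``.
    Fitted by nonlinear least squares; `fit` returns a `SaturationResults`
    with asymptotic standard errors and confidence intervals.
    """

    def __init__(self, rate, fi) -> None:
        rate = np.asarray(rate, float)
        fi = np.asarray(fi, float)
        keep = np.isfinite(rate) & np.isfinite(fi)
        self.rate = rate[keep]
        self.fi = fi[keep]
        if self.rate.size < 4:
            raise ValueError("need at least 4 points to fit the saturation curve")
        if np.any(self.rate < 0):
            raise ValueError("rates must be nonnegative")

    def fit(self, p0=None) -> "SaturationResults":
        if p0 is None:
            f0 = max(float(self.fi.max()), 1e-3)
            pos = self.rate[self.rate > 0]
            nu0 = 1.0 / float(np.median(pos)) if pos.size else 0.1
            p0 = (f0, nu0)
        try:
            popt, pcov = optimize.curve_fit(
                _saturation, self.rate, self.fi, p0=p0, maxfev=20000
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"saturation fit did not converge (p0={p0}, n={self.rate.size}): {err}"
            ) from None
        return SaturationResults(self, popt, pcov)


@dataclass
class SaturationResults:
    model: SaturationModel
    _popt: np.ndarray
    _pcov: np.ndarray

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._popt, index=["f_sat", "nu_sat"])

    @property
    def f_sat(self) -> float:
        return float(self._popt[0])

    @property
    def nu_sat(self) -> float:
        return float(self._popt[1])

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._pcov)), index=["f_sat", "nu_sat"])

    @property
    def df_resid(self) -> int:
        return self.model.rate.size - 2

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """t-based asymptotic confidence intervals."""
        tcrit = stats.t.ppf(1 - alpha / 2, max(self.df_resid, 1))
        half = tcrit * self.bse
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half}
        )

    def predict(self, rate) -> np.ndarray:
        return _saturation(np.asarray(rate, float), *self._popt)

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        resid = self.model.fi - self.predict(self.model.rate)
        lines = [
            "Saturating rate-information fit",
            "=" * 56,
            f"n points: {self.model.rate.size}   resid. SD: {resid.std(ddof=2):.4g}",
            f"{'param':<8}{'estimate':>12}{'std err':>12}"
            f"{'[' + format(alpha / 2, '.3g'):>10}{format(1 - alpha / 2, '.3g') + ']':>10}",
        ]
        for name in ("f_sat", "nu_sat"):
            lines.append(
                f"{name:<8}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
                f"{ci.loc[name, 'lower']:>10.4g}{ci.loc[name, 'upper']:>10.4g}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.rate, self.model.fi, "o", ms=4, label="data")
        rr = np.linspace(0, self.model.rate.max() * 1.05, 200)
        ax.plot(rr, self.predict(rr), "-", label="fit")
        ax.set_xlabel("firing rate (Hz)")
        ax.set_ylabel("FI")
        ax.legend()
        return ax


def fit_saturation(points) -> SaturationResults:
    """Fit the saturating curve to ``(rate, FI)`` pairs.

    ``points`` may be a DataFrame with ``rate``/``FI`` columns or an
    iterable of pairs.
    """
    if isinstance(points, pd.DataFrame):
        rate, fi = points["rate"], points["FI"]
    else:
        arr = np.asarray(list(points), float)
        rate, fi = arr[:, 0], arr[:, 1]
    return SaturationModel(rate, fi).fit()
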