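"""Model/Results interface for information-transfer estimation.

`InformationTransfer` plays the role a regression model class plays in a
statistics package: it is built from data (the hidden-state trace plus an
input current and/or an output spike train), `fit` runs the decoding
pipeline — optionally on consecutive windows — and returns an
`InformationTransferResults` object carrying per-window estimates, their
spread, and a `summary()` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decoding
from .decoding import InfoReport, PosteriorTrace
from .population import CurrentTrace, SpikeTrain
from .telegraph import HiddenStateTrace

__all__ = ["InformationTransfer", "InformationTransferResults"]


class InformationTransfer:
    """Estimate how much information a signal carries about the hidden state.

    Parameters
    ----------
    hidden : HiddenStateTrace
        The ground-truth binary stimulus trace.
    input_trace : CurrentTrace, optional
        Dimensionless population current aligned with ``hidden``.
    spikes : SpikeTrain, optional
        An output spike train on the same observation window (recorded or
        simulated).  When both signals are given, the results include the
        transfer fractions FI (MI ratio) and FMSE (error ratio).
    r_on, r_off : float, optional
        Decoder switching rates; default to the generative rates of
        ``hidden``.

    Examples
    --------
    >>> model = InformationTransfer(hidden, input_trace=trace, spikes=train)
    >>> res = model.fit(window=20.0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        hidden: HiddenStateTrace,
        input_trace: CurrentTrace | None = None,
        spikes: SpikeTrain | None = None,
        r_on: float | None = None,
        r_off: float | None = None,
    ) -> None:
        if input_trace is None and spikes is None:
            raise ValueError("provide an input trace, a spike train, or both")
        if input_trace is not None:
            if input_trace.units != "dimensionless":
                raise ValueError("decode the dimensionless drive, not ampere")
            if input_trace.n_steps != hidden.x.size:
                raise ValueError("input trace and hidden state lengths differ")
            if abs(input_trace.dt - hidden.dt) > 1e-15:
                raise ValueError("input trace and hidden state dt differ")
        self.hidden = hidden
        self.input_trace = input_trace
        self.spikes = spikes
        self.r_on = hidden.params.r_on if r_on is None else r_on
        self.r_off = hidden.params.r_off if r_off is None else r_off

    def fit(
        self,
        window: float | None = None,
        lag_max: float = 0.05,
        n_poisson: int = 0,
        seed: int | np.random.Generator | None = None,
    ) -> "InformationTransferResults":
        """Run the decoding pipeline and collect information metrics.

        ``window`` splits the record into consecutive windows of that
        length in seconds (trailing remainder dropped with a warning);
        each window is decoded independently, with the spike rates
        re-estimated per window.  ``n_poisson > 0`` additionally computes
        the Poisson-normalized error MSE_P from that many surrogates.
        """
        dt = self.hidden.dt
        n = self.hidden.x.size
        if window is None:
            bins_per_win = n
        else:
            bins_per_win = int(round(window / dt))
            if bins_per_win > n:
                raise ValueError("window longer than the record")
            if n % bins_per_win:
                warnings.warn(
                    f"record is not a whole number of {window} s windows; "
                    "trailing remainder dropped",
                    stacklevel=2,
                )
        n_windows = n // bins_per_win
        rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )

        reports: list[InfoReport] = []
        for j in range(n_windows):
            i0, i1 = j * bins_per_win, (j + 1) * bins_per_win
            hid = self.hidden.slice(i0, i1)
            post_in: PosteriorTrace | None = None
            if self.input_trace is not None:
                post_in = decoding.integrate_log_odds_from_input(
                    self.input_trace.slice(i0, i1), self.r_on, self.r_off
                )
                rep = decoding.score_posterior(hid, post_in, lag_max)
                rep.window_index, rep.t0, rep.t1 = j, i0 * dt, i1 * dt
                reports.append(rep)
            if self.spikes is not None:
                rep = self._fit_spike_window(
                    hid, (i0 * dt, i1 * dt), post_in, lag_max, n_poisson, rng
                )
                rep.window_index, rep.t0, rep.t1 = j, i0 * dt, i1 * dt
                reports.append(rep)
        return InformationTransferResults(self, reports, window)

    def _fit_spike_window(
        self,
        hid: HiddenStateTrace,
        span: tuple[float, float],
        post_in: PosteriorTrace | None,
        lag_max: float,
        n_poisson: int,
        rng: np.random.Generator,
    ) -> InfoReport:
        t0, t1 = span
        mask = (self.spikes.times >= t0) & (self.spikes.times < t1)
        sub = SpikeTrain(self.spikes.times[mask] - t0, (0.0, t1 - t0))
        if sub.n_spikes == 0:
            # an empty train carries no information by convention
            h_xx = decoding.empirical_entropy(hid)
            return InfoReport(
                source="spike_train",
                H_xx_hat=h_xx,
                H_xy_hat=h_xx,
                MI_hat=0.0,
                F=0.0,
                lag=0.0,
                MI_star_hat=0.0,
                MSE=float("nan"),
                FI=0.0 if post_in is not None else float("nan"),
                rate=0.0,
            )
        post_sp, est = decoding.decode_spike_train(sub, hid, self.r_on, self.r_off)
        rep = decoding.score_posterior(hid, post_sp, lag_max)
        rep.q_on_hat, rep.q_off_hat = est.q_on_hat, est.q_off_hat
        rep.rate = sub.rate
        rep.MSE, rep.MSE_P, rep.FMSE = decoding.mse_measures(
            hid,
            post_sp,
            post_input=post_in,
            spikes=sub,
            n_poisson=n_poisson,
            seed=rng,
        )
        if post_in is not None:
            mi_in = decoding.mutual_information(hid, post_in)
            _, mi_in_star = decoding.shift_correct(hid, post_in, lag_max)
            if mi_in <= 0:
                warnings.warn(
                    "input MI <= 0; FI undefined for this window", stacklevel=2
                )
                rep.FI = float("nan")
            else:
                rep.FI = rep.MI_hat / mi_in
            rep.FI_star = rep.MI_star_hat / mi_in_star if mi_in_star > 0 else float("nan")
        return rep


@dataclass
class InformationTransferResults:
    """Per-window information estimates with convenience accessors."""

    model: InformationTransfer
    reports: list[InfoReport]
    window: float | None

    @property
    def frame(self) -> pd.DataFrame:
        """One row per (window, source) with every scalar metric."""
        return pd.DataFrame([r.as_dict() for r in self.reports])

    def _by_source(self, source: str) -> pd.DataFrame:
        df = self.frame
        return df[df.source == source]

    @property
    def params(self) -> pd.Series:
        """Window-mean of the headline metrics, statsmodels-style."""
        df = self.frame
        out = {}
        for source, tag in (("input", "input"), ("spike_train", "spike")):
            sub = df[df.source == source]
            if len(sub):
                out[f"MI_{tag}"] = sub.MI_hat.mean()
                out[f"F_{tag}"] = sub.F.mean()
        sub = df[df.source == "spike_train"]
        if len(sub) and sub.FI.notna().any():
            out["FI"] = sub.FI.mean()
        return pd.Series(out)

    def summary(self) -> str:
        """Plain-text summary table (mean +/- SD across windows)."""
        df = self.frame
        p = self.model.hidden.params
        lines = [
            "Information transfer estimate",
            "=" * 64,
            f"r_on: {p.r_on:.4g} Hz   r_off: {p.r_off:.4g} Hz   "
            f"tau: {p.tau * 1e3:.4g} ms   p1: {p.p1:.4g}",
            f"record: {self.model.hidden.duration:.4g} s   dt: {p.dt * 1e3:.4g} ms   "
            f"windows: {df.window_index.nunique()}"
            + (f" x {self.window:.4g} s" if self.window else ""),
            "-" * 64,
            f"{'metric':<14}{'source':<14}{'mean':>12}{'sd':>12}{'n':>8}",
        ]
        for source in ("input", "spike_train"):
            sub = df[df.source == source]
            if not len(sub):
                continue
            for col in ("H_xx_hat", "MI_hat", "F", "FI", "MI_star_hat", "MSE",
                        "MSE_P", "FMSE", "rate", "lag"):
                vals = sub[col].dropna()
                if not len(vals):
                    continue
                lines.append(
                    f"{col:<14}{source:<14}{vals.mean():>12.4f}"
                    f"{(vals.std(ddof=1) if len(vals) > 1 else 0.0):>12.4f}"
                    f"{len(vals):>8d}"
                )
        lines.append("=" * 64)
        lines.append("entropies/informations in bits; lag in s; rates in Hz")
        return "\n".join(lines)

    def plot_posterior(self, t0: float = 0.0, t1: float | None = None, ax=None):
        """Plot the hidden state with the decoded posterior(s) over [t0, t1].

        Re-decodes the full record (the fitted windows only store scalars).
        """
        import matplotlib.pyplot as plt

        m = self.model
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        dt = m.hidden.dt
        n = m.hidden.x.size
        i0 = int(t0 / dt)
        i1 = n if t1 is None else min(n, int(t1 / dt))
        tt = np.arange(i0, i1) * dt
        ax.fill_between(
            tt, m.hidden.x[i0:i1], step="pre", alpha=0.2, color="0.4", label="x"
        )
        if m.input_trace is not None:
            post = decoding.integrate_log_odds_from_input(
                m.input_trace, m.r_on, m.r_off
            )
            ax.plot(tt, post.p[i0:i1], lw=0.8, label="p(x=1 | input)")
        if m.spikes is not None and m.spikes.n_spikes:
            post, _ = decoding.decode_spike_train(m.spikes, m.hidden, m.r_on, m.r_off)
            ax.plot(tt, post.p[i0:i1], lw=0.8, label="p(x=1 | spikes)")
            sel = (m.spikes.times >= tt[0]) & (m.spikes.times < tt[-1])
            ax.plot(
                m.spikes.times[sel],
                np.full(int(sel.sum()), 1.05),
                "|",
                color="k",
                ms=8,
                label="spikes",
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("p(x=1)")
        ax.legend(loc="upper right", fontsize=8)
        return ax
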