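"""Inverse problem: estimate T2* (and fat fraction) from a decay curve.

Three fitting variants mirror clinical relaxometry practice:

``mono``
    Single-exponential ``S0 * exp(-TE/T2*) [+ offset]`` — the standard
    segmental myocardial fit.
``truncated``
    Monoexponential fit that iteratively discards trailing echoes whose
    predicted signal has sunk below the magnitude-noise floor; used for
    heavily iron-loaded tissue where late echoes are pure noise.
``fat_water``
    Joint (S0, T2*, FF) fit of the multipeak fat-water magnitude model of
    :mod:`ferrofat.signal_model`, with a multi-start over FF to escape the
    fat/water dominance ambiguity.

All variants use bounded trust-region nonlinear least squares
(:func:`scipy.optimize.least_squares`).  A statsmodels-style surface is
provided: build a :class:`DecayModel` from data, call :meth:`DecayModel.fit`,
and obtain a :class:`DecayFitResults` with estimates, standard errors,
``summary()``, ``predict()`` and ``plot()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .signal_model import AcquisitionProtocol, EchoTrain, FatSpectrum

__all__ = [
    "FitResult",
    "DecayModel",
    "DecayFitResults",
    "fit_monoexponential",
    "fit_truncated",
    "fit_fat_water",
]

#: Default T2* search interval, ms.
T2S_BOUNDS_MS = (0.1, 1000.0)
#: FF starting grid for the fat-water multi-start.
FF_STARTS = (0.05, 0.25, 0.45, 0.65)
#: Truncation drops trailing echoes predicted below this multiple of the
#: estimated noise SD.
TRUNCATION_SNR_FACTOR = 2.0
#: Minimum number of echoes any fit may use.
MIN_ECHOES = 4
#: Seed for the deterministic perturbation of restarts on non-convergence.
_RESTART_SEED = 20230428

_SOLVER_TOL = dict(ftol=1e-12, xtol=1e-12, gtol=1e-12)


class InputError(ValueError):
    """Invalid fitting input (too few echoes, missing data)."""


@dataclass(frozen=True)
class FitResult:
    """Point estimates from one decay-curve fit.

    ``ff`` is ``None`` for the mono/truncated variants.  ``at_bound`` marks
    a T2* estimate pinned at a search bound (degenerate data, e.g. a
    constant signal).  ``param_cov`` is the Gauss-Newton covariance
    ``rss/(n-p) * (J'J)^-1`` in the order given by ``param_names``.
    """

    model: str
    s0: float
    t2star_ms: float
    ff: float | None
    offset: float
    n_echoes_used: int
    rss: float
    converged: bool
    at_bound: bool = False
    warnings: tuple[str, ...] = ()
    param_names: tuple[str, ...] = ()
    param_cov: np.ndarray | None = field(default=None, repr=False, compare=False)


def _loglinear_t2s(te: np.ndarray, y: np.ndarray, bounds: tuple[float, float]) -> tuple[float, float]:
    """Log-linear initial guess (S0, T2*) from the high-signal echoes."""
    mask = y > max(y.max() * 0.02, 1e-300)
    if mask.sum() < 2:
        return float(max(y.max(), 1e-12)), bounds[1]
    slope, intercept = np.polyfit(te[mask], np.log(y[mask]), 1)
    t2s = -1.0 / slope if slope < 0 else bounds[1]
    t2s = float(np.clip(t2s, bounds[0], bounds[1]))
    s0 = float(np.exp(intercept))
    return max(s0, 1e-12), t2s


def _solve(residual, x0, lb, ub, max_restarts: int = 3):
    """Bounded least squares with deterministic perturbed restarts."""
    x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
    best = least_squares(residual, x0, bounds=(lb, ub), method="trf", **_SOLVER_TOL)
    if not best.success:
        rng = np.random.default_rng(_RESTART_SEED)
        for _ in range(max_restarts):
            jitter = x0 * (1.0 + 0.2 * rng.standard_normal(x0.size))
            sol = least_squares(
                residual, np.clip(jitter, lb, ub), bounds=(lb, ub), method="trf", **_SOLVER_TOL
            )
            if sol.cost < best.cost or (sol.success and not best.success):
                best = sol
            if best.success:
                break
    return best


def _covariance(sol, n: int) -> np.ndarray | None:
    p = sol.x.size
    if n <= p:
        return None
    s2 = 2.0 * sol.cost / (n - p)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:
        return None
    return cov


def fit_monoexponential(
    train: EchoTrain,
    with_offset: bool = False,
    t2s_bounds: tuple[float, float] = T2S_BOUNDS_MS,
) -> FitResult:
    """Least-squares single-exponential fit ``S0*exp(-TE/T2*) [+ offset]``.

    Requires at least 4 echoes.  Non-convergence after deterministic
    restarts yields a flagged result rather than an exception; a T2*
    estimate pinned at a search bound (e.g. for a constant signal) sets
    ``at_bound``.
    """
    te, y = train.echo_times_ms, train.signals
    if len(train) < MIN_ECHOES:
        raise InputError(f"monoexponential fit requires >= {MIN_ECHOES} echoes")
    s0_init, t2s_init = _loglinear_t2s(te, y, t2s_bounds)

    if with_offset:
        def residual(x):
            return x[0] * np.exp(-te / x[1]) + x[2] - y
        x0 = [s0_init, t2s_init, max(y.min(), 0.0)]
        lb = [0.0, t2s_bounds[0], 0.0]
        ub = [np.inf, t2s_bounds[1], max(y.max(), 1e-12)]
        names = ("s0", "t2star_ms", "offset")
    else:
        def residual(x):
            return x[0] * np.exp(-te / x[1]) - y
        x0 = [s0_init, t2s_init]
        lb = [0.0, t2s_bounds[0]]
        ub = [np.inf, t2s_bounds[1]]
        names = ("s0", "t2star_ms")

    sol = _solve(residual, x0, lb, ub)
    t2s = float(sol.x[1])
    rel = max(t2s_bounds[1] - t2s_bounds[0], 1e-12)
    at_bound = min(t2s - t2s_bounds[0], t2s_bounds[1] - t2s) < 1e-6 * rel
    return FitResult(
        model="mono",
        s0=float(sol.x[0]),
        t2star_ms=t2s,
        ff=None,
        offset=float(sol.x[2]) if with_offset else 0.0,
        n_echoes_used=len(train),
        rss=float(2.0 * sol.cost),
        converged=bool(sol.success),
        at_bound=bool(at_bound),
        param_names=names,
        param_cov=_covariance(sol, len(train)),
    )


def fit_truncated(
    train: EchoTrain,
    t2s_bounds: tuple[float, float] = T2S_BOUNDS_MS,
    snr_factor: float = TRUNCATION_SNR_FACTOR,
) -> FitResult:
    """Monoexponential fit with noise-floor truncation of late echoes.

    The noise SD is estimated from the offset of a mono+offset fit on the
    full train (the Rician floor mean at zero signal is ``sd*sqrt(pi/2)``).
    Trailing echoes are then dropped while the current offset-free fit
    predicts a noiseless signal below ``snr_factor`` times that SD at the
    last kept echo, refitting after each drop.  Truncation never goes
    below 4 echoes; hitting the floor sets a warning flag.
    """
    if len(train) < MIN_ECHOES + 1:
        raise InputError("truncated fit requires >= 5 echoes")
    full = fit_monoexponential(train, with_offset=True, t2s_bounds=t2s_bounds)
    noise_sd = full.offset / math.sqrt(math.pi / 2.0)

    n_keep = len(train)
    fit = fit_monoexponential(train, with_offset=False, t2s_bounds=t2s_bounds)
    while n_keep > MIN_ECHOES:
        pred_last = fit.s0 * math.exp(-train.echo_times_ms[n_keep - 1] / fit.t2star_ms)
        if pred_last < snr_factor * noise_sd:
            n_keep -= 1
            fit = fit_monoexponential(train.truncated(n_keep), with_offset=False, t2s_bounds=t2s_bounds)
        else:
            break

    warnings = ()
    if n_keep == MIN_ECHOES:
        pred_last = fit.s0 * math.exp(-train.echo_times_ms[n_keep - 1] / fit.t2star_ms)
        if pred_last < snr_factor * noise_sd:
            warnings = ("truncated_to_minimum",)

    return FitResult(
        model="truncated",
        s0=fit.s0,
        t2star_ms=fit.t2star_ms,
        ff=None,
        offset=0.0,
        n_echoes_used=n_keep,
        rss=fit.rss,
        converged=fit.converged,
        at_bound=fit.at_bound,
        warnings=warnings,
        param_names=fit.param_names,
        param_cov=fit.param_cov,
    )


def fit_fat_water(
    train: EchoTrain,
    spectrum: FatSpectrum,
    with_offset: bool = False,
    ff_starts: tuple[float, ...] = FF_STARTS,
    t2s_bounds: tuple[float, float] = T2S_BOUNDS_MS,
) -> FitResult:
    """Joint (S0, T2*, FF) fit of the multipeak fat-water magnitude model.

    Runs a multi-start over ``ff_starts`` and keeps the lowest-residual
    solution; FF is constrained to [0, 1] with no FF <= 0.5 restriction,
    so heavily fat-replaced tissue (FF > 50%) is representable.  Requires
    at least 6 echoes.
    """
    te, y = train.echo_times_ms, train.signals
    if len(train) < 6:
        raise InputError("fat-water fit requires >= 6 echoes")
    phasor = spectrum.phasor(te)
    s0_init, t2s_init = _loglinear_t2s(te, y, t2s_bounds)

    if with_offset:
        def residual(x):
            mod = np.abs((1.0 - x[2]) + x[2] * phasor)
            return x[0] * np.exp(-te / x[1]) * mod + x[3] - y
        lb = [0.0, t2s_bounds[0], 0.0, 0.0]
        ub = [np.inf, t2s_bounds[1], 1.0, max(y.max(), 1e-12)]
        names = ("s0", "t2star_ms", "ff", "offset")
    else:
        def residual(x):
            mod = np.abs((1.0 - x[2]) + x[2] * phasor)
            return x[0] * np.exp(-te / x[1]) * mod - y
        lb = [0.0, t2s_bounds[0], 0.0]
        ub = [np.inf, t2s_bounds[1], 1.0]
        names = ("s0", "t2star_ms", "ff")

    best = None
    for ff0 in ff_starts:
        x0 = [s0_init, t2s_init, ff0] + ([0.0] if with_offset else [])
        sol = _solve(residual, x0, lb, ub, max_restarts=1)
        if best is None or sol.cost < best.cost:
            best = sol

    converged = bool(best.success)
    t2s = float(best.x[1])
    rel = max(t2s_bounds[1] - t2s_bounds[0], 1e-12)
    at_bound = min(t2s - t2s_bounds[0], t2s_bounds[1] - t2s) < 1e-6 * rel
    return FitResult(
        model="fat_water",
        s0=float(best.x[0]),
        t2star_ms=t2s,
        ff=float(best.x[2]),
        offset=float(best.x[3]) if with_offset else 0.0,
        n_echoes_used=len(train),
        rss=float(2.0 * best.cost),
        converged=converged,
        at_bound=bool(at_bound),
        warnings=() if converged else ("non_convergence",),
        param_names=names,
        param_cov=_covariance(best, len(train)),
    )


class DecayModel:
    """Multiecho decay model bound to one ROI's data.

    Parameters
    ----------
    echo_times_ms, signals
        The decay curve (echo times in ms, mean magnitude signals).
    spectrum
        Fat spectrum used by the ``fat_water`` variant; optional for the
        monoexponential variants.
    with_offset
        Include a constant offset term in the fitted model.

    Examples
    --------
    >>> model = DecayModel(train.echo_times_ms, train.signals, spectrum=spec)
    >>> res = model.fit("fat_water")
    >>> print(res.summary())
    """

    def __init__(
        self,
        echo_times_ms,
        signals,
        *,
        spectrum: FatSpectrum | None = None,
        with_offset: bool = False,
        organ: str | None = None,
    ):
        self.train = EchoTrain(
            echo_times_ms=np.asarray(echo_times_ms, dtype=float),
            signals=np.asarray(signals, dtype=float),
            organ=organ,
        )
        self.spectrum = spectrum
        self.with_offset = with_offset

    @classmethod
    def from_echo_train(cls, train: EchoTrain, **kwargs) -> "DecayModel":
        return cls(train.echo_times_ms, train.signals, organ=train.organ, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        te_col: str = "te_ms",
        signal_col: str = "signal",
        **kwargs,
    ) -> "DecayModel":
        return cls(df[te_col].to_numpy(float), df[signal_col].to_numpy(float), **kwargs)

    def fit(self, model: str = "fat_water", **kwargs) -> "DecayFitResults":
        """Fit the chosen variant (``mono`` | ``truncated`` | ``fat_water``)."""
        if model == "mono":
            res = fit_monoexponential(self.train, with_offset=self.with_offset, **kwargs)
        elif model == "truncated":
            res = fit_truncated(self.train, **kwargs)
        elif model == "fat_water":
            if self.spectrum is None:
                raise InputError("fat_water fit requires a FatSpectrum")
            res = fit_fat_water(
                self.train, self.spectrum, with_offset=self.with_offset, **kwargs
            )
        else:
            raise ValueError(f"unknown model: {model!r}")
        return DecayFitResults(self, res)


class DecayFitResults:
    """Results wrapper: estimates, standard errors, diagnostics."""

    def __init__(self, model: DecayModel, fit: FitResult):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> dict[str, float]:
        out = {"s0": self.fit.s0, "t2star_ms": self.fit.t2star_ms}
        if self.fit.ff is not None:
            out["ff"] = self.fit.ff
        if "offset" in self.fit.param_names:
            out["offset"] = self.fit.offset
        return out

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors from the Gauss-Newton covariance."""
        if self.fit.param_cov is None:
            return {name: float("nan") for name in self.fit.param_names}
        se = np.sqrt(np.clip(np.diag(self.fit.param_cov), 0.0, None))
        return dict(zip(self.fit.param_names, se.tolist()))

    def predict(self, echo_times_ms=None) -> np.ndarray:
        te = (
            self.model.train.echo_times_ms
            if echo_times_ms is None
            else np.asarray(echo_times_ms, dtype=float)
        )
        f = self.fit
        decay = f.s0 * np.exp(-te / f.t2star_ms)
        if f.ff is not None and self.model.spectrum is not None:
            decay = decay * np.abs((1 - f.ff) + f.ff * self.model.spectrum.phasor(te))
        return decay + f.offset

    def summary(self) -> str:
        f = self.fit
        bse = self.bse
        lines = [
            f"Multiecho decay fit ({f.model})",
            "=" * 44,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
            "-" * 44,
        ]
        for name, value in self.params.items():
            se = bse.get(name, float("nan"))
            lines.append(f"{name:<12}{value:>14.6g}{se:>14.3g}")
        lines += [
            "-" * 44,
            f"echoes used: {f.n_echoes_used}   RSS: {f.rss:.4g}",
            f"converged: {f.converged}   at bound: {f.at_bound}",
        ]
        if f.warnings:
            lines.append("warnings: " + ", ".join(f.warnings))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data and fitted curve on a log-y axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        te = self.model.train.echo_times_ms
        ax.plot(te, self.model.train.signals, "o", label="data")
        grid = np.linspace(te[0], te[-1], 200)
        ax.plot(grid, self.predict(grid), "-", label=f"{self.fit.model} fit")
        ax.set_xlabel("TE (ms)")
        ax.set_ylabel("signal")
        ax.set_yscale("log")
        ax.legend()
        return ax
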