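"""Two-state fit of CD thermograms with cold and heat transitions.

The observed ellipticity is modelled as a population-weighted mix of two
linear baselines,

    theta(T) = f(T) * (aF + bF*T) + (1 - f(T)) * (aU + bU*T)

with ``f`` the equilibrium folded fraction from the Gibbs–Helmholtz
stability curve (:mod:`coldfold.thermo`).  Cold- and heat-denatured
states share a single unfolded baseline; with two visible transitions
this keeps the seven-parameter model (dH, dCp, Tm, aF, bF, aU, bU)
identifiable.  The cold-denaturation temperature is never a free
parameter — it is always re-derived from the fitted triple, mirroring
the stability-curve route to the thermodynamic table.

Exposed statsmodels-style: build a :class:`ThermogramModel` from a
:class:`~coldfold.thermogram.Thermogram` (or a DataFrame), call
``fit()``, and read estimates, standard errors and a ``summary()`` off
the returned :class:`ThermogramResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .thermo import (
    CELSIUS_OFFSET,
    NoColdTransitionError,
    StabilityParams,
    cold_denaturation_temp,
    delta_g,
    fraction_folded,
    max_stability_temp,
)
from .thermogram import Thermogram

__all__ = [
    "Baseline",
    "InitialGuess",
    "UnidentifiableDataError",
    "model_signal",
    "initial_guess",
    "ThermogramModel",
    "ThermogramResults",
    "fit_thermogram",
]

# fit bounds, user-facing units (kcal, degC)
BOUNDS_DH = (1.0, 200.0)
BOUNDS_DCP = (0.1, 10.0)
BOUNDS_TM_C = (0.0, 110.0)
_BASELINE_BOUND = 1e4


class UnidentifiableDataError(ValueError):
    """The data carry no usable transition signal (e.g. constant trace)."""


@dataclass(frozen=True)
class Baseline:
    """Linear baseline theta = intercept + slope*T, T in degC."""

    intercept: float
    slope: float

    def __call__(self, T_celsius):
        return self.intercept + self.slope * np.asarray(T_celsius, dtype=float)


@dataclass
class InitialGuess:
    params: StabilityParams
    baseline_folded: Baseline
    baseline_unfolded: Baseline
    weak_signal: bool = False


def model_signal(T_celsius, params: StabilityParams, baseline_folded: Baseline,
                 baseline_unfolded: Baseline):
    """Model ellipticity (mdeg) at temperatures ``T_celsius``.

    Equals the folded baseline where f -> 1 and the unfolded baseline
    where f -> 0; at Tm it is the midpoint of the two baselines.
    """
    T_celsius = np.asarray(T_celsius, dtype=float)
    f = fraction_folded(T_celsius + CELSIUS_OFFSET, params)
    return f * baseline_folded(T_celsius) + (1.0 - f) * baseline_unfolded(T_celsius)


def initial_guess(thermogram: Thermogram) -> InitialGuess:
    """Heuristic starting point for the seven-parameter fit.

    A coarse grid over (dH, dCp, Tm) with the baselines solved exactly by
    linear least squares at each candidate (variable projection) picks
    the best-SSR start.  The shared unfolded baseline's tail fit (both
    ends of the range are unfolded when a cold transition is visible)
    backs the weak-signal fallback, which returns fixed defaults
    (dH = 25 kcal/mol, dCp = 2 kcal/K/mol) with ``weak_signal=True``.
    """
    t, y = thermogram.temperature, thermogram.ellipticity
    n = t.size
    span = float(np.ptp(y))
    weak = span < 1e-12 or span < 0.05 * max(1e-12, float(np.abs(y).max()))

    # unfolded baseline from the two tails
    k = max(3, n // 10)
    tt = np.concatenate([t[:k], t[-k:]])
    yy = np.concatenate([y[:k], y[-k:]])
    try:
        bU_slope, bU_int = np.polyfit(tt, yy, 1)
    except Exception:
        bU_slope, bU_int = 0.0, float(np.mean(y))
    baseline_unfolded = Baseline(float(bU_int), float(bU_slope))

    # folded plateau: mid-range extreme deviation from the unfolded line
    mid = slice(n // 5, 4 * n // 5)
    resid = y[mid] - baseline_unfolded(t[mid])
    if weak or resid.size == 0:
        i_ext = n // 2
        baseline_folded = Baseline(float(y[i_ext]) - 5.0, 0.01)
        Tm_C = float(t[n // 2 + n // 4]) if n >= 4 else 35.0
        return InitialGuess(
            StabilityParams.from_celsius(25.0, 2.0, min(max(Tm_C, 1.0), 109.0)),
            baseline_folded, baseline_unfolded, weak_signal=True,
        )
    # coarse variable-projection scan: the signal is linear in the four
    # baseline coefficients once (dH, dCp, Tm) is fixed, so each grid
    # candidate costs one linear solve; the best-SSR triple starts the fit
    best: tuple | None = None
    for Tm_C in np.arange(max(t[0] + 5.0, 10.0), min(t[-1] + 5.0, 109.0), 1.0):
        for dH in (10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 60.0):
            for dCp in (1.5, 2.5):
                p = StabilityParams.from_celsius(dH, dCp, Tm_C)
                f = fraction_folded(t + CELSIUS_OFFSET, p)
                A = np.column_stack([f, f * t, 1.0 - f, (1.0 - f) * t])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                ssr = float(np.sum((A @ coef - y) ** 2))
                if best is None or ssr < best[0]:
                    best = (ssr, p, coef)
    _, params0, coef = best
    return InitialGuess(
        params0,
        Baseline(float(coef[0]), float(coef[1])),
        Baseline(float(coef[2]), float(coef[3])),
    )


def _pack(params: StabilityParams, bf: Baseline, bu: Baseline) -> np.ndarray:
    return np.array([
        params.dH, params.dCp, params.Tm_celsius,
        bf.intercept, bf.slope, bu.intercept, bu.slope,
    ])


def _unpack(x: np.ndarray):
    params = StabilityParams.from_celsius(x[0], x[1], x[2])
    return params, Baseline(x[3], x[4]), Baseline(x[5], x[6])


_PARAM_NAMES = ["dH", "dCp", "Tm_C", "aF", "bF", "aU", "bU"]


class ThermogramModel:
    """Two-state Gibbs–Helmholtz model of a CD thermogram.

    Parameters
    ----------
    thermogram : Thermogram
        Sorted, validated temperature/ellipticity data.

    Examples
    --------
    >>> model = ThermogramModel(thermogram)
    >>> res = model.fit()
    >>> res.params.Tm_celsius, res.cold_denaturation_celsius()
    """

    def __init__(self, thermogram: Thermogram):
        self.thermogram = thermogram
        self.exog = thermogram.temperature
        self.endog = thermogram.ellipticity
        self.weights = (
            1.0 / thermogram.sigma if thermogram.sigma is not None else
            np.ones_like(self.endog)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: str = "temperature_C",
                       ellipticity: str = "ellipticity_mdeg", label: str = "") -> "ThermogramModel":
        sigma = df["sigma_mdeg"].to_numpy() if "sigma_mdeg" in df else None
        return cls(Thermogram(df[temperature].to_numpy(), df[ellipticity].to_numpy(),
                              label=label, sigma=sigma))

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        params, bf, bu = _unpack(x)
        return self.weights * (model_signal(self.exog, params, bf, bu) - self.endog)

    def fit(self, init: InitialGuess | None = None, max_nfev: int = 2000) -> "ThermogramResults":
        """Bounded least squares from the heuristic (or supplied) start.

        One fallback restart from a perturbed start (+10 % on dH and dCp)
        is attempted if the first solve does not converge.  Raises
        :class:`UnidentifiableDataError` for a constant trace.
        """
        if np.ptp(self.endog) < 1e-12:
            raise UnidentifiableDataError("constant signal: transitions unidentifiable")
        if init is None:
            init = initial_guess(self.thermogram)
        x0 = _pack(init.params, init.baseline_folded, init.baseline_unfolded)
        lo = np.array([BOUNDS_DH[0], BOUNDS_DCP[0], BOUNDS_TM_C[0],
                       -_BASELINE_BOUND, -_BASELINE_BOUND, -_BASELINE_BOUND, -_BASELINE_BOUND])
        hi = np.array([BOUNDS_DH[1], BOUNDS_DCP[1], BOUNDS_TM_C[1],
                       _BASELINE_BOUND, _BASELINE_BOUND, _BASELINE_BOUND, _BASELINE_BOUND])
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

        sol = least_squares(self._residuals, x0, bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                            max_nfev=max_nfev)
        if not sol.success:
            x1 = x0.copy()
            x1[0] *= 1.10
            x1[1] *= 1.10
            x1 = np.clip(x1, lo + 1e-9, hi - 1e-9)
            retry = least_squares(self._residuals, x1, bounds=(lo, hi),
                                  method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                  max_nfev=max_nfev)
            if retry.success or retry.cost < sol.cost:
                sol = retry
        return ThermogramResults(self, sol, init)


class ThermogramResults:
    """Fit results: estimates, uncertainties, diagnostics, summary table.

    Attributes
    ----------
    params : StabilityParams
        Fitted thermodynamic triple (dH, dCp, Tm in kelvin).
    baseline_folded, baseline_unfolded : Baseline
    rss : float
        Residual sum of squares (weighted if sigmas were supplied).
    bse : dict
        Standard errors per parameter name, from the Gauss–Newton
        curvature at the optimum.
    converged : bool
    """

    def __init__(self, model: ThermogramModel, sol, init: InitialGuess):
        self.model = model
        self._sol = sol
        self.init = init
        self.params, self.baseline_folded, self.baseline_unfolded = _unpack(sol.x)
        self.rss = float(2.0 * sol.cost)
        self.converged = bool(sol.success)
        self.nobs = model.endog.size
        self.bse = dict(zip(_PARAM_NAMES, self._stderr(sol)))

    @staticmethod
    def _stderr(sol) -> np.ndarray:
        n, p = sol.fun.size, sol.x.size
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof
        J = sol.jac
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)

    # -- derived quantities -------------------------------------------------
    def cold_denaturation_celsius(self) -> float | None:
        """Tc re-derived from the fitted triple; None if no cold root."""
        try:
            return cold_denaturation_temp(self.params) - CELSIUS_OFFSET
        except NoColdTransitionError:
            return None

    def max_stability_celsius(self) -> float:
        return max_stability_temp(self.params) - CELSIUS_OFFSET

    def predict(self, T_celsius=None) -> np.ndarray:
        """Fitted ellipticity at the data (or supplied) temperatures."""
        if T_celsius is None:
            T_celsius = self.model.exog
        return model_signal(T_celsius, self.params, self.baseline_folded,
                            self.baseline_unfolded)

    def fraction_folded(self, T_celsius=None):
        if T_celsius is None:
            T_celsius = self.model.exog
        return fraction_folded(np.asarray(T_celsius, float) + CELSIUS_OFFSET, self.params)

    def overlay_frame(self) -> pd.DataFrame:
        """Per-point table: temperature, observed, fitted, folded fraction."""
        return pd.DataFrame({
            "temperature_C": self.model.exog,
            "observed_mdeg": self.model.endog,
            "fitted_mdeg": self.predict(),
            "fraction_folded": self.fraction_folded(),
        })

    def stability_curve(self, T_celsius=None) -> pd.DataFrame:
        """Table of (T, dG) tracing the fitted stability curve."""
        if T_celsius is None:
            T_celsius = self.model.exog
        T_celsius = np.asarray(T_celsius, dtype=float)
        return pd.DataFrame({
            "temperature_C": T_celsius,
            "dG_kcal_mol": delta_g(T_celsius + CELSIUS_OFFSET, self.params),
        })

    def to_dict(self) -> dict:
        tc = self.cold_denaturation_celsius()
        return {
            "label": self.model.thermogram.label,
            "dH_kcal_mol": self.params.dH,
            "dCp_kcal_K_mol": self.params.dCp,
            "Tm_C": self.params.Tm_celsius,
            "Tc_C": tc,
            "Ts_C": self.max_stability_celsius(),
            "baseline_folded": [self.baseline_folded.intercept, self.baseline_folded.slope],
            "baseline_unfolded": [self.baseline_unfolded.intercept, self.baseline_unfolded.slope],
            "rss": self.rss,
            "stderr": self.bse,
            "converged": self.converged,
            "n_points": int(self.nobs),
        }

    def summary(self) -> str:
        est = _pack(self.params, self.baseline_folded, self.baseline_unfolded)
        lines = [
            "Two-state thermogram fit",
            "=" * 52,
            f"label: {self.model.thermogram.label}   n = {self.nobs}"
            f"   rss = {self.rss:.4g}   converged = {self.converged}",
            f"{'param':>6} {'estimate':>12} {'std err':>12}",
        ]
        for name, v in zip(_PARAM_NAMES, est):
            lines.append(f"{name:>6} {v:>12.4g} {self.bse[name]:>12.3g}")
        tc = self.cold_denaturation_celsius()
        tc_s = f"{tc:.2f}" if tc is not None else "none above model floor"
        lines.append("-" * 52)
        lines.append(f"derived: Ts = {self.max_stability_celsius():.2f} C, Tc = {tc_s} C")
        return "\n".join(lines)


def fit_thermogram(thermogram: Thermogram, init: InitialGuess | None = None,
                   **options) -> ThermogramResults:
    """Functional wrapper: ``ThermogramModel(thermogram).fit(init)``."""
    return ThermogramModel(thermogram).fit(init=init, **options)
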