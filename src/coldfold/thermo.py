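"""Two-state Gibbs–Helmholtz stability-curve thermodynamics.

A two-state protein with a constant heat-capacity change of unfolding
``dCp`` has a dome-shaped stability curve

    dG(T) = dH * (1 - T/Tm) + dCp * [(T - Tm) - T * ln(T/Tm)]

where ``dG`` is the free energy of *unfolding* (positive when the folded
state is favoured), ``dH`` the unfolding enthalpy at the heat-denaturation
midpoint ``Tm``, and all temperatures are absolute.  Because ``dCp > 0``
the curve is concave with a single maximum at the temperature of maximal
stability ``Ts`` and, when the dome dips below zero on the low-temperature
side, a second zero ``Tc`` — the cold-denaturation temperature.  This
module evaluates the curve and everything derived from it: ``Ts`` (closed
form), ``Tc`` (bracketed root-finding), the midpoint entropy ``dS = dH/Tm``
and the equilibrium folded fraction ``f = K/(1+K)`` with
``K = exp(dG/(R*T))``.

Energies are in kcal throughout; temperatures are kelvin internally and
degrees Celsius at the user-facing surface.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT_KCAL",
    "CELSIUS_OFFSET",
    "COLD_SEARCH_FLOOR_K",
    "StabilityParams",
    "NoColdTransitionError",
    "delta_g",
    "entropy_at_tm",
    "max_stability_temp",
    "cold_denaturation_temp",
    "fraction_folded",
    "stability_report",
    "report_to_csv",
    "report_to_json",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Additive offset between degrees Celsius and kelvin.
CELSIUS_OFFSET = 273.15

#: Lowest temperature (K) at which the model is trusted; below this no
#: cold root is searched for — the constant-dCp extrapolation is not
#: physical that far from the measured range.
COLD_SEARCH_FLOOR_K = 200.0

#: Absolute function tolerance (kcal/mol) for the cold-root solver.
ROOT_TOL_KCAL = 1e-9


class NoColdTransitionError(ValueError):
    """The stability curve has no zero between the search floor and Ts."""


@dataclass(frozen=True)
class StabilityParams:
    """Thermodynamic triple defining a two-state stability curve.

    Parameters
    ----------
    dH : float
        Enthalpy of unfolding at ``Tm``, kcal mol^-1.  Must be positive.
    dCp : float
        Heat-capacity change of unfolding, kcal K^-1 mol^-1.  Must be
        positive (it is the curvature source of the stability dome).
    Tm : float
        Heat-denaturation midpoint, kelvin.
    """

    dH: float
    dCp: float
    Tm: float

    def __post_init__(self) -> None:
        if not (self.dH > 0):
            raise ValueError(f"dH must be positive, got {self.dH}")
        if not (self.dCp > 0):
            raise ValueError(f"dCp must be positive, got {self.dCp}")
        if not (self.Tm > 0):
            raise ValueError(f"Tm must be positive kelvin, got {self.Tm}")

    @classmethod
    def from_celsius(cls, dH: float, dCp: float, Tm_C: float) -> "StabilityParams":
        """Build from a melting temperature given in degrees Celsius."""
        return cls(dH=dH, dCp=dCp, Tm=Tm_C + CELSIUS_OFFSET)

    @property
    def Tm_celsius(self) -> float:
        return self.Tm - CELSIUS_OFFSET


def _check_temperature(T: np.ndarray | float) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def delta_g(T, params: StabilityParams):
    """Unfolding free energy dG(T) in kcal mol^-1 at temperature T (K).

    Vectorised over ``T``.  Positive values mean the folded state is
    favoured; the curve is zero at ``Tm`` by construction and, if a cold
    transition exists, again at ``Tc``.
    """
    T = _check_temperature(T)
    Tm = params.Tm
    val = params.dH * (1.0 - T / Tm) + params.dCp * ((T - Tm) - T * np.log(T / Tm))
    return float(val) if val.ndim == 0 else val


def entropy_at_tm(params: StabilityParams) -> float:
    """Unfolding entropy at the midpoint, dS = dH/Tm, kcal K^-1 mol^-1."""
    return params.dH / params.Tm


def max_stability_temp(params: StabilityParams) -> float:
    """Temperature of maximal stability Ts (K), where dG peaks.

    Setting d(dG)/dT = 0 gives the closed form
    ``Ts = Tm * exp(-dH / (dCp * Tm))``; since dH, dCp > 0 this always
    lies below Tm.
    """
    return params.Tm * math.exp(-params.dH / (params.dCp * params.Tm))


def cold_denaturation_temp(params: StabilityParams, floor: float = COLD_SEARCH_FLOOR_K) -> float:
    """Cold-denaturation temperature Tc (K): the low-T zero of dG.

    Solved by bracketed root-finding (Brent) on [floor, Ts]; the curve is
    monotone increasing on that interval so the root is unique when it
    exists.

    Raises
    ------
    NoColdTransitionError
        If dG does not change sign on the bracket — either the dome never
        dips below zero above ``floor``, or the curve is non-positive at
        its own maximum.
    """
    Ts = max_stability_temp(params)
    if Ts <= floor:
        raise NoColdTransitionError(
            f"stability maximum Ts={Ts:.1f} K lies below the search floor {floor} K"
        )
    g_floor = delta_g(floor, params)
    g_ts = delta_g(Ts, params)
    if g_ts <= 0:
        raise NoColdTransitionError("stability curve is non-positive at its maximum")
    if g_floor > 0:
        raise NoColdTransitionError(
            f"no cold transition in range: dG({floor:.0f} K) = {g_floor:.3g} kcal/mol > 0"
        )
    return float(
        brentq(lambda T: delta_g(T, params), floor, Ts, xtol=1e-9, rtol=8.9e-16)
    )


def fraction_folded(T, params: StabilityParams):
    """Equilibrium folded fraction f(T) = K/(1+K), K = exp(dG/(R*T)).

    Vectorised over ``T`` (kelvin).  Equals 0.5 exactly where dG = 0,
    i.e. at both Tm and Tc.
    """
    T = _check_temperature(T)
    g = delta_g(T, params)
    # logistic form avoids overflow for strongly stabilising dG
    f = 1.0 / (1.0 + np.exp(-np.asarray(g) / (GAS_CONSTANT_KCAL * T)))
    return float(f) if f.ndim == 0 else f


def stability_report(params: StabilityParams, construct: str = "") -> dict:
    """All derived quantities for one parameter set, user-facing units.

    Returns a dict with keys ``construct, dH_kcal_mol, dCp_kcal_K_mol,
    dS_kcal_K_mol, Tm_C, Tc_C, Ts_C, folding_pct``.  If no cold root
    exists above the model floor, ``Tc_C`` is None and a warning is
    emitted instead of raising.
    """
    Ts = max_stability_temp(params)
    try:
        Tc_C = cold_denaturation_temp(params) - CELSIUS_OFFSET
    except NoColdTransitionError as exc:
        warnings.warn(f"{construct or 'parameter set'}: {exc}", stacklevel=2)
        Tc_C = None
    return {
        "construct": construct,
        "dH_kcal_mol": params.dH,
        "dCp_kcal_K_mol": params.dCp,
        "dS_kcal_K_mol": entropy_at_tm(params),
        "Tm_C": params.Tm_celsius,
        "Tc_C": Tc_C,
        "Ts_C": Ts - CELSIUS_OFFSET,
        "folding_pct": 100.0 * fraction_folded(Ts, params),
    }


_REPORT_COLUMNS = [
    "construct",
    "dH_kcal_mol",
    "dCp_kcal_K_mol",
    "dS_kcal_K_mol",
    "Tm_C",
    "Tc_C",
    "Ts_C",
    "folding_pct",
]


def report_to_csv(rows: Iterable[dict], path) -> None:
    """Write stability-report rows to CSV with a fixed column order."""
    pd.DataFrame(list(rows), columns=_REPORT_COLUMNS).to_csv(path, index=False)


def report_to_json(rows: Sequence[dict], path) -> None:
    """Write stability-report rows to a JSON array."""
    with open(path, "w") as fh:
        json.dump(list(rows), fh, indent=2)
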