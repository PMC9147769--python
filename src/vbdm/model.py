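"""Core virus-bacteria-DOM model: parameters and ODE right-hand sides.

The model couples three state variables in a well-mixed volume of ocean
water or brine:

* ``N`` — dissolved organic matter (DOM, < 0.2 um), ug mL^-1,
* ``B`` — heterotrophic bacteria, cells mL^-1,
* ``V`` — lytic viruses (bacteriophage analogues), cells mL^-1.

Bacteria take up DOM with Monod (half-saturation) kinetics, grow, die at a
background rate and are lysed by viruses at a mass-action encounter rate.
Lysis releases new virions (burst size ``beta``) and recycles part of the
cell's organic matter back into the DOM pool; a fraction ``g`` of gross
uptake is returned immediately as exudate.  Viruses decay at a fixed
specific rate.  The uptake constant ``alpha`` carries the only temperature
dependence, via the Q10 law.

Two configurations are supported.  The *closed* system (a brine pocket
sealed in an ice shell) has a finite initial DOM pool and always runs down.
The *open* system (a sub-ice biosphere) receives an external DOM flux
``E(t) = f * (alpha/mu) * d * B(t)`` — the "viral elevator" term — which
replaces the organic matter lost to non-viral bacterial death and can
sustain a steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ModelParameters",
    "ModelState",
    "alpha_at_temperature",
    "closed_rhs",
    "open_rhs",
    "elevator_coefficient",
    "rhs",
]

#: Mass of DOM liberated per lysed bacterial cell, ug cell^-1.
LYSIS_MASS_UG = 1e-7

#: Reference temperature for the Q10 scaling of the uptake constant, deg C.
Q10_REFERENCE_T = 23.0


class ParameterError(ValueError):
    """An invalid or inconsistent model parameter."""


def alpha_at_temperature(alpha_ref: float, q10_base: float, T: float) -> float:
    """DOM uptake constant at temperature ``T`` via the Q10 law.

    Parameters
    ----------
    alpha_ref
        Uptake constant at the 23 deg C reference, ug cell^-1 hr^-1.
    q10_base
        Multiplicative factor per 10 deg C (dimensionless, > 0).
    T
        Temperature, deg C.

    Returns
    -------
    float
        ``alpha_ref * q10_base ** ((T - 23) / 10)``.
    """
    if alpha_ref <= 0 or q10_base <= 0:
        raise ParameterError(
            f"alpha_ref and q10_base must be positive, got {alpha_ref}, {q10_base}"
        )
    return alpha_ref * q10_base ** ((T - Q10_REFERENCE_T) / 10.0)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set for a single model run.

    Units: time in hours, DOM in ug mL^-1, populations in cells mL^-1.
    Temperature enters only through the Q10 scaling of ``alpha``.

    Attributes
    ----------
    N_i, B_i, V_i
        Initial DOM (ug mL^-1), bacteria and viruses (cells mL^-1).
    T
        Temperature, deg C.  Default physical range -4..0 deg C
        (sub-ice ocean conditions); widen via ``T_range``.
    alpha_ref, q10_base
        Uptake constant at 23 deg C and its Q10 factor.
    mu
        Maximum bacterial growth rate, hr^-1.
    Q
        Half-saturation (Monod) constant, ug mL^-1.
    d_death
        Non-viral bacterial death rate, hr^-1.
    m_decay
        Viral decay rate, hr^-1.
    g_exudate
        Fraction of gross uptake returned to the DOM pool as exudate.
    n_recycle
        Fraction of lysed cell matter recycled into the DOM pool.
    gamma
        Lytic multiplier in [0, 1]: scales viral production per infection
        (1 = fully lytic dynamics).
    phi
        Adsorption/infection rate, mL cell^-1 hr^-1.
    beta
        Burst size, virions per lysed cell.
    lysis_mass
        DOM mass released per lysed cell, ug.
    f_elevator
        Dimensionless elevator multiplier; required iff ``mode == "open"``.
    mode
        ``"closed"`` (brine pocket) or ``"open"`` (sub-ice biosphere).
    """

    N_i: float = 30.0
    B_i: float = 1e5
    V_i: float = 1e6
    T: float = -2.0
    alpha_ref: float = 1.2e-7
    q10_base: float = 3.0
    mu: float = 0.024
    Q: float = 0.022
    d_death: float = 2e-4
    m_decay: float = 0.015
    g_exudate: float = 0.09
    n_recycle: float = 0.99
    gamma: float = 1.0
    phi: float = 1e-10
    beta: float = 250.0
    lysis_mass: float = LYSIS_MASS_UG
    f_elevator: float | None = None
    mode: Literal["closed", "open"] = "closed"
    T_range: tuple[float, float] = (-4.0, 0.0)

    def __post_init__(self) -> None:
        nonneg = {
            "N_i": self.N_i, "B_i": self.B_i, "V_i": self.V_i,
            "mu": self.mu, "Q": self.Q, "d_death": self.d_death,
            "m_decay": self.m_decay, "phi": self.phi, "beta": self.beta,
            "lysis_mass": self.lysis_mass,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value}")
        for name, value in (("g_exudate", self.g_exudate),
                            ("n_recycle", self.n_recycle),
                            ("gamma", self.gamma)):
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {value}")
        if self.alpha_ref <= 0 or self.q10_base <= 0:
            raise ParameterError("alpha_ref and q10_base must be positive")
        lo, hi = self.T_range
        if not lo <= self.T <= hi:
            raise ParameterError(
                f"T={self.T} outside configured physical range [{lo}, {hi}]"
            )
        if self.mode == "open":
            if self.f_elevator is None:
                raise ParameterError("open mode requires f_elevator")
            if self.f_elevator < 0:
                raise ParameterError("f_elevator must be >= 0")
        elif self.mode == "closed":
            if self.f_elevator is not None:
                raise ParameterError("f_elevator is only meaningful in open mode")
        else:
            raise ParameterError(f"mode must be 'closed' or 'open', got {self.mode!r}")

    @property
    def alpha(self) -> float:
        """Uptake constant at this run's temperature, ug cell^-1 hr^-1."""
        return alpha_at_temperature(self.alpha_ref, self.q10_base, self.T)

    @property
    def initial_state(self) -> "ModelState":
        return ModelState(self.N_i, self.B_i, self.V_i)

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous system state (N in ug mL^-1; B, V in cells mL^-1)."""

    N: float
    B: float
    V: float

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.B, self.V], dtype=float)


def elevator_coefficient(p: ModelParameters) -> float:
    """Coefficient ``f * (alpha/mu) * d`` of the elevator flux E = coeff * B.

    ``alpha/mu`` is the DOM-to-cell conversion factor (ug cell^-1) and
    ``d * B`` the rate of non-viral bacterial death, so the elevator flux
    resupplies, ``f``-fold, the organic matter lost to deaths that would
    otherwise sink out of the sub-ice system as particulate matter.
    """
    if p.mode != "open" or p.f_elevator is None:
        return 0.0
    return p.f_elevator * (p.alpha / p.mu) * p.d_death


def _rhs_terms(y: np.ndarray, p: ModelParameters, alpha: float):
    N, B, V = y
    if min(N, B, V) < 0:
        raise ValueError(f"negative state passed to RHS: N={N}, B={B}, V={V}")
    monod = N / (N + p.Q) if N > 0 else 0.0
    uptake = alpha * monod * B          # gross DOM uptake, ug mL^-1 hr^-1
    infection = p.phi * V * B           # infections, cells mL^-1 hr^-1
    return monod, uptake, infection


def closed_rhs(y, p: ModelParameters, alpha: float | None = None) -> np.ndarray:
    """Time derivative (per hour) of (N, B, V) in the closed configuration.

    dN/dt = -uptake + g*uptake + n*gamma*phi*V*B*lysis_mass
    dB/dt =  mu*N/(Q+N)*B - phi*V*B - d*B
    dV/dt =  gamma*beta*phi*V*B - phi*V*B - m*V
    """
    if alpha is None:
        alpha = p.alpha
    y = np.asarray(y, dtype=float)
    monod, uptake, infection = _rhs_terms(y, p, alpha)
    N, B, V = y
    dN = -uptake + p.g_exudate * uptake + p.n_recycle * p.gamma * infection * p.lysis_mass
    dB = p.mu * monod * B - infection - p.d_death * B
    dV = p.gamma * p.beta * infection - infection - p.m_decay * V
    return np.array([dN, dB, dV])


def open_rhs(y, p: ModelParameters, alpha: float | None = None) -> np.ndarray:
    """Closed-system derivative plus the elevator DOM flux on dN/dt.

    The elevator flux is state dependent, ``E(t) = f*(alpha/mu)*d*B(t)``:
    it scales with the standing bacterial stock, replacing the DOM lost to
    non-viral death.  The per-run reported ``E`` is the time average of
    this term.
    """
    if p.mode != "open":
        raise ParameterError("open_rhs requires mode='open'")
    if alpha is None:
        alpha = p.alpha
    dy = closed_rhs(y, p, alpha)
    dy[0] += elevator_coefficient(p) * float(np.asarray(y, dtype=float)[1])
    return dy


def rhs(y, p: ModelParameters, alpha: float | None = None) -> np.ndarray:
    """Dispatch to :func:`closed_rhs` or :func:`open_rhs` by ``p.mode``."""
    return open_rhs(y, p, alpha) if p.mode == "open" else closed_rhs(y, p, alpha)
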