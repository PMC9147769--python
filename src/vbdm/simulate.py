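"""Single-run integration and per-run metrics.

Integrates the stiff three-species system with an adaptive LSODA solver and
extracts the metrics used to characterise runs: population peak times,
mean inter-peak interval, system longevity, steady-state classification
(for open runs) and the time-averaged virus-to-bacteria ratio (VBR) and
elevator flux E.

Numerical conventions
---------------------
The populations swing over seven or more orders of magnitude per cycle, so
peak detection operates on log10 of the series, and "alive" is defined
against a viability floor of 1 cell mL^-1.  The solver runs at
``rtol=1e-8, atol=1e-12``; tiny negative excursions (below a clamp
tolerance) are zeroed in the output, anything larger aborts the run with a
diagnostic naming the parameter set.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import ModelParameters, closed_rhs, elevator_coefficient, open_rhs

__all__ = [
    "Trajectory",
    "RunSummary",
    "IntegrationError",
    "integrate",
    "detect_peaks",
    "interpeak_interval",
    "system_longevity",
    "classify_steady_state",
    "averaged_metrics",
    "summarize_run",
    "find_steady_f",
]

#: Population density below which a population is considered non-viable,
#: cells mL^-1.
VIABILITY_FLOOR = 1.0

#: Default steady-state averaging window, hours.
STEADY_WINDOW_HR = 20_000.0

#: Default fractional DOM drift limit for steady-state classification.
STEADY_DRIFT_LIMIT = 0.10

#: Default run durations, hours.
CLOSED_DURATION_HR = 25_000.0
OPEN_DURATION_HR = 200_000.0

_RTOL = 1e-8
_ATOL = 1e-12
#: Largest negative excursion (state units) silently clamped to zero.
_CLAMP_TOL = 1e-8


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced an untrustworthy state."""


@dataclass
class Trajectory:
    """Solution of one run sampled on a uniform output grid.

    ``vbr`` is ``V/B`` where ``B > 0`` (NaN elsewhere); ``E`` is the
    instantaneous elevator flux, identically zero for closed runs.
    """

    t: np.ndarray          # hours
    N: np.ndarray          # ug mL^-1
    B: np.ndarray          # cells mL^-1
    V: np.ndarray          # cells mL^-1
    params: ModelParameters

    @property
    def vbr(self) -> np.ndarray:
        out = np.full_like(self.V, np.nan, dtype=float)
        mask = self.B > 0
        out[mask] = self.V[mask] / self.B[mask]
        return out

    @property
    def E(self) -> np.ndarray:
        return elevator_coefficient(self.params) * self.B

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_hr": self.t,
                "N_ug_per_ml": self.N,
                "B_cells_per_ml": self.B,
                "V_cells_per_ml": self.V,
                "VBR": self.vbr,
                "E_ug_per_ml_hr": self.E,
            }
        )

    def write_csv(self, path) -> None:
        """CSV with a commented header embedding the resolved parameters."""
        with open(path, "w") as fh:
            fh.write("# params: " + json.dumps(_params_dict(self.params)) + "\n")
            self.to_frame().to_csv(fh, index=False)


@dataclass
class RunSummary:
    """Per-run metrics; NaN marks undefined metrics (e.g. < 2 peaks)."""

    peak_times_B: list[float]
    peak_times_V: list[float]
    interpeak_interval: float      # hours; NaN if < 2 bacterial peaks
    longevity: float               # hours
    steady_state: bool
    dom_drift: float               # fractional; NaN if run < 2x window
    avg_VBR: float
    avg_E: float                   # ug mL^-1 hr^-1; 0 for closed runs
    params: ModelParameters | None = None

    def to_json(self, path=None) -> str:
        payload = {
            k: v for k, v in dataclasses.asdict(self).items() if k != "params"
        }
        if self.params is not None:
            payload["params"] = _params_dict(self.params)
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {o!r}")


def _params_dict(p: ModelParameters) -> dict:
    d = dataclasses.asdict(p)
    d["T_range"] = list(d["T_range"])
    return d


def integrate(
    p: ModelParameters,
    duration: float | None = None,
    output_step: float = 10.0,
    rtol: float = _RTOL,
    atol: float = _ATOL,
    dom_cap: float | None = None,
) -> Trajectory:
    """Integrate the model from its initial state over ``duration`` hours.

    Parameters
    ----------
    p
        Model parameters (mode selects closed or open dynamics).
    duration
        Run length in hours; defaults to 25,000 h closed / 200,000 h open.
    output_step
        Output grid spacing in hours.  The solution itself is adaptive;
        this only controls sampling.
    dom_cap
        Optional DOM ceiling (ug mL^-1).  An open run whose elevator
        oversupplies DOM grows without bound and only gets stiffer; once
        N crosses the cap the run's fate (non-steady) is already decided,
        so integration stops there and the trajectory ends early.

    Raises
    ------
    IntegrationError
        On solver failure or a negative excursion beyond the clamp
        tolerance.
    """
    if duration is None:
        duration = OPEN_DURATION_HR if p.mode == "open" else CLOSED_DURATION_HR
    if duration <= 0:
        raise ValueError("duration must be positive")

    alpha = p.alpha
    e_coef = elevator_coefficient(p)

    # Local closure: avoids attribute lookups in the hot loop and clips
    # tiny negative excursions so the Monod term stays defined.
    mu, Q, d, m = p.mu, p.Q, p.d_death, p.m_decay
    g, n, gamma, phi, beta = p.g_exudate, p.n_recycle, p.gamma, p.phi, p.beta
    lysis = p.lysis_mass

    def fn(t, y):
        N, B, V = y
        Np = N if N > 0.0 else 0.0
        Bp = B if B > 0.0 else 0.0
        Vp = V if V > 0.0 else 0.0
        monod = Np / (Np + Q)
        uptake = alpha * monod * Bp
        infection = phi * Vp * Bp
        return (
            -uptake + g * uptake + n * gamma * infection * lysis + e_coef * Bp,
            mu * monod * Bp - infection - d * Bp,
            gamma * beta * infection - infection - m * Vp,
        )

    t_eval = np.arange(0.0, duration + 0.5 * output_step, output_step)
    t_eval = t_eval[t_eval <= duration]
    if t_eval[-1] < duration:
        t_eval = np.append(t_eval, duration)

    events = None
    if dom_cap is not None:
        if dom_cap <= p.N_i:
            raise ValueError("dom_cap must exceed the initial DOM")

        def runaway(t, y, cap=dom_cap):
            return y[0] - cap

        runaway.terminal = True
        runaway.direction = 1.0
        events = [runaway]

    sol = solve_ivp(
        fn,
        (0.0, duration),
        [p.N_i, p.B_i, p.V_i],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        events=events,
    )
    if not sol.success:
        raise IntegrationError(
            f"solver failed ({sol.message}) for params {_params_dict(p)}"
        )

    t_out, y = sol.t, sol.y
    if events is not None and sol.t_events[0].size:
        # keep the crossing itself so the truncated run ends on the cap
        t_ev = sol.t_events[0][0]
        if t_ev > t_out[-1]:
            t_out = np.append(t_out, t_ev)
            y = np.hstack([y, sol.y_events[0][0][:, None]])
    worst = y.min()
    if worst < -_CLAMP_TOL:
        raise IntegrationError(
            f"negative state {worst:.3e} beyond clamp tolerance for params "
            f"{_params_dict(p)}"
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(t=t_out, N=y[0], B=y[1], V=y[2], params=p)


def detect_peaks(
    series: np.ndarray,
    t: np.ndarray,
    rel_prominence: float = 10.0,
    height_floor: float = 10.0,
) -> np.ndarray:
    """Times of significant local maxima of a population series.

    Detection runs on log10 of the series: a maximum counts as a peak if
    it stands out from its surroundings by at least a factor
    ``rel_prominence`` and exceeds ``height_floor`` (cells mL^-1).  Both
    guards exist because the boom-bust cycles span many decades and tiny
    numerical ripples near extinction must not register.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.size < 3:
        return np.array([])
    log_s = np.log10(np.clip(series, 1e-30, None))
    idx, _ = find_peaks(
        log_s,
        prominence=math.log10(rel_prominence),
        height=math.log10(height_floor),
    )
    return t[idx]


def interpeak_interval(peak_times: np.ndarray) -> float:
    """Mean spacing between successive peaks, hours; NaN if < 2 peaks."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return float("nan")
    return float(np.diff(peak_times).mean())


def system_longevity(traj: Trajectory, floor: float = VIABILITY_FLOOR) -> float:
    """Last time at which the coupled system is alive, hours.

    Alive means *both* populations exceed the viability floor: the system
    is over once either partner is gone, and in practice the viral
    population collapses first while bacteria then decay only slowly at
    the background death rate.  Populations may legitimately dip below the
    floor during cycling, so this is the *last* crossing, not the first.
    Returns the duration if the system never dies, 0.0 if it is never
    alive.
    """
    alive = (traj.B > floor) & (traj.V > floor)
    if not alive.any():
        return 0.0
    return float(traj.t[alive][-1])


def classify_steady_state(
    traj: Trajectory,
    window: float = STEADY_WINDOW_HR,
    drift_limit: float = STEADY_DRIFT_LIMIT,
    floor: float = VIABILITY_FLOOR,
) -> tuple[bool, float]:
    """Steady-state verdict and fractional DOM drift.

    A run is steady iff the mean DOM over the last ``window`` hours is
    within ``drift_limit`` (fractionally) of the mean over the first
    ``window`` hours, and the bacterial population stays above the
    viability floor throughout the last window (populations persist,
    oscillating about a steady value).
    """
    if traj.duration < 2 * window:
        raise ValueError(
            f"run duration {traj.duration} h shorter than twice the "
            f"averaging window {window} h"
        )
    first = traj.t <= window
    last = traj.t >= traj.duration - window
    mean_first = float(traj.N[first].mean())
    mean_last = float(traj.N[last].mean())
    if mean_first <= 0:
        # DOM already exhausted at the start: nothing steady about it.
        return False, float("inf")
    drift = (mean_last - mean_first) / mean_first
    persists = bool(traj.B[last].min() > floor)
    return (abs(drift) <= drift_limit) and persists, drift


def averaged_metrics(traj: Trajectory) -> tuple[float, float]:
    """Time-averaged (VBR, E) over the full run.

    VBR samples where B = 0 are excluded; if B = 0 everywhere the average
    VBR is NaN.  E is averaged by trapezoidal quadrature of the
    instantaneous elevator flux (zero for closed runs).
    """
    vbr = traj.vbr
    ok = np.isfinite(vbr)
    avg_vbr = float(vbr[ok].mean()) if ok.any() else float("nan")
    span = traj.t[-1] - traj.t[0]
    avg_e = float(np.trapezoid(traj.E, traj.t) / span) if span > 0 else 0.0
    return avg_vbr, avg_e


def summarize_run(
    traj: Trajectory,
    window: float = STEADY_WINDOW_HR,
    drift_limit: float = STEADY_DRIFT_LIMIT,
    floor: float = VIABILITY_FLOOR,
) -> RunSummary:
    """Compute the full per-run metric set for a trajectory."""
    peaks_b = detect_peaks(traj.B, traj.t)
    peaks_v = detect_peaks(traj.V, traj.t)
    if traj.duration >= 2 * window:
        steady, drift = classify_steady_state(traj, window, drift_limit, floor)
    else:
        steady, drift = False, float("nan")
    avg_vbr, avg_e = averaged_metrics(traj)
    return RunSummary(
        peak_times_B=list(peaks_b),
        peak_times_V=list(peaks_v),
        interpeak_interval=interpeak_interval(peaks_b),
        longevity=system_longevity(traj, floor),
        steady_state=steady,
        dom_drift=drift,
        avg_VBR=avg_vbr,
        avg_E=avg_e,
        params=traj.params,
    )


def find_steady_f(
    p: ModelParameters,
    f_lo: float = 10.0,
    f_hi: float = 200.0,
    duration: float = OPEN_DURATION_HR,
    output_step: float = 50.0,
    tol: float = 0.05,
    max_iter: int = 30,
) -> float:
    """Bisection helper: an elevator factor f giving near-zero DOM drift.

    Too-small f lets the DOM pool drain (negative drift, eventual
    extinction); too-large f makes DOM grow without bound (positive
    drift).  Bisect on the sign of the drift until it is within ``tol``.
    The returned f is one steady value, not a unique or canonical one.
    """
    base = p if p.mode == "open" else p.with_(mode="open", f_elevator=f_lo)

    def drift_at(f: float) -> float:
        traj = integrate(base.with_(f_elevator=f), duration, output_step)
        _, drift = classify_steady_state(traj)
        if math.isinf(drift):
            return -1.0  # DOM exhausted: behaves like f too small
        return drift

    d_lo, d_hi = drift_at(f_lo), drift_at(f_hi)
    if d_lo > 0 or d_hi < 0:
        raise ValueError(
            f"drift does not bracket zero on [{f_lo}, {f_hi}]: "
            f"{d_lo:+.3f} .. {d_hi:+.3f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (f_lo + f_hi)
        d_mid = drift_at(mid)
        if abs(d_mid) <= tol:
            return mid
        if d_mid < 0:
            f_lo = mid
        else:
            f_hi = mid
    return 0.5 * (f_lo + f_hi)
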