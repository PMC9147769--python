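"""Monte Carlo parameter ensembles and population statistics.

Each ensemble draws parameter sets from configured ranges (log-uniform for
ranges spanning orders of magnitude, uniform for narrow ones), integrates
every run, filters out failed / extinct / non-steady runs, and reduces the
survivors to the statistics of interest: quartiles of the run-averaged
virus-to-bacteria ratio and a log-normal fit to the run-averaged elevator
flux E.

Reproducibility: every run gets an independent RNG substream derived from
``(master_seed, run_index)``, so results are bit-identical for a given
seed and config regardless of execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelParameters
from .simulate import (
    IntegrationError,
    RunSummary,
    Trajectory,
    integrate,
    summarize_run,
)

__all__ = [
    "ParameterRange",
    "SamplingConfig",
    "EnsembleResult",
    "sample_parameters",
    "run_ensemble",
    "vbr_statistics",
    "fit_lognormal_E",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterRange:
    """Sampling range for one parameter; ``lo == hi`` pins the value."""

    lo: float
    hi: float
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError(f"inverted range [{self.lo}, {self.hi}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be 'linear' or 'log', got {self.scale!r}")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log-scale range requires positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.lo == self.hi:
            return self.lo
        if self.scale == "log":
            return float(10 ** rng.uniform(np.log10(self.lo), np.log10(self.hi)))
        return float(rng.uniform(self.lo, self.hi))


def _default_ranges(mode: str) -> dict[str, ParameterRange]:
    """Study-condition sampling ranges.

    Parameters spanning two or more decades (initial populations, the
    infection rate, the exudate fraction) are sampled log-uniformly so
    every decade is equally represented; narrow ranges are uniform.
    Well-constrained constants (Q, d, m, n) stay fixed.
    """
    ranges = {
        "N_i": ParameterRange(10.0, 50.0),
        "B_i": ParameterRange(1e4, 1e6, "log"),
        "V_i": ParameterRange(1e5, 1e7, "log"),
        "T": ParameterRange(-4.0, 0.0),
        "mu": ParameterRange(0.016, 0.032),
        "g_exudate": ParameterRange(0.02, 0.2, "log"),
        "gamma": ParameterRange(0.0, 1.0),
        "phi": ParameterRange(1e-11, 1e-9, "log"),
        "beta": ParameterRange(10.0, 500.0),
    }
    if mode == "open":
        ranges["f_elevator"] = ParameterRange(70.0, 85.0)
    return ranges


@dataclass(frozen=True)
class SamplingConfig:
    """Ensemble specification: ranges, size, master seed, mode."""

    n_runs: int = 300
    seed: int = 0
    mode: str = "closed"
    ranges: dict[str, ParameterRange] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.mode not in ("closed", "open"):
            raise ValueError(f"mode must be 'closed' or 'open', got {self.mode!r}")

    def resolved_ranges(self) -> dict[str, ParameterRange]:
        out = _default_ranges(self.mode)
        out.update(self.ranges)
        for name, value in self.fixed.items():
            out[name] = ParameterRange(value, value)
        return out

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "seed": self.seed,
            "mode": self.mode,
            "ranges": {
                k: dataclasses.asdict(v) for k, v in self.resolved_ranges().items()
            },
        }


def sample_parameters(cfg: SamplingConfig, rng: np.random.Generator) -> ModelParameters:
    """Draw one parameter set from the configured ranges.

    Draws happen in sorted field order so the stream of variates for a
    given config is well defined.
    """
    ranges = cfg.resolved_ranges()
    drawn = {name: ranges[name].draw(rng) for name in sorted(ranges)}
    drawn["mode"] = cfg.mode
    if cfg.mode == "closed":
        drawn.pop("f_elevator", None)
    return ModelParameters(**drawn)


@dataclass
class EnsembleResult:
    """Retained run summaries plus ensemble-level statistics."""

    config: SamplingConfig
    duration: float
    summaries: list[RunSummary]
    n_retained: int
    n_removed: int
    removal_reasons: dict[str, int]
    vbr_quartiles: tuple[float, float, float] | None  # (q25, median, q75)
    e_fit: dict | None  # log-normal fit of avg_E (open mode)

    @property
    def n_runs(self) -> int:
        return self.n_retained + self.n_removed

    def per_run_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "avg_VBR": [s.avg_VBR for s in self.summaries],
                "avg_E": [s.avg_E for s in self.summaries],
                "longevity_hr": [s.longevity for s in self.summaries],
                "steady_state": [s.steady_state for s in self.summaries],
                "dom_drift": [s.dom_drift for s in self.summaries],
            }
        )

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "duration_hr": self.duration,
            "n_runs": self.n_runs,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "removal_reasons": self.removal_reasons,
            "vbr_quartiles": list(self.vbr_quartiles) if self.vbr_quartiles else None,
            "e_lognormal_fit": self.e_fit,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_ensemble(
    cfg: SamplingConfig,
    duration: float | None = None,
    output_step: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    e_quantile_levels: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
    dom_cap_factor: float = 100.0,
) -> EnsembleResult:
    """Sample, integrate and filter ``cfg.n_runs`` model runs.

    Closed mode removes runs whose integration fails or whose average VBR
    is undefined (bacteria effectively absent from the start); open mode
    additionally retains only steady-state runs — DOM drift within 10%
    between the first and last 20,000 h windows with persistent
    populations.  Open runs whose DOM exceeds ``dom_cap_factor`` times
    its initial value are cut short and removed as runaway (an
    oversupplying elevator grows DOM without bound; no steady state can
    follow).  Individual failures are logged and counted, never
    propagated.
    """
    summaries: list[RunSummary] = []
    reasons = {
        "integration_failed": 0,
        "undefined_vbr": 0,
        "non_steady": 0,
        "dom_runaway": 0,
    }
    full_duration = duration
    if full_duration is None:
        from .simulate import CLOSED_DURATION_HR, OPEN_DURATION_HR

        full_duration = (
            OPEN_DURATION_HR if cfg.mode == "open" else CLOSED_DURATION_HR
        )
    for index in range(cfg.n_runs):
        rng = np.random.default_rng([cfg.seed, index])
        p = sample_parameters(cfg, rng)
        cap = dom_cap_factor * p.N_i if cfg.mode == "open" else None
        try:
            traj = integrate(
                p, full_duration, output_step, rtol=rtol, atol=atol, dom_cap=cap
            )
        except (IntegrationError, ValueError) as exc:
            logger.warning("run %d removed: %s", index, exc)
            reasons["integration_failed"] += 1
            continue
        if traj.duration < full_duration:
            reasons["dom_runaway"] += 1
            continue
        summary = summarize_run(traj)
        if np.isnan(summary.avg_VBR):
            reasons["undefined_vbr"] += 1
            continue
        if cfg.mode == "open" and not summary.steady_state:
            reasons["non_steady"] += 1
            continue
        summaries.append(summary)

    vbr_q = None
    if summaries:
        q25, q50, q75 = np.percentile([s.avg_VBR for s in summaries], [25, 50, 75])
        vbr_q = (float(q25), float(q50), float(q75))

    e_fit = None
    if cfg.mode == "open" and summaries:
        avg_e = np.array([s.avg_E for s in summaries])
        if np.all(avg_e > 0):
            e_fit = fit_lognormal_E(avg_e, e_quantile_levels)

    n_removed = cfg.n_runs - len(summaries)
    return EnsembleResult(
        config=cfg,
        duration=full_duration,
        summaries=summaries,
        n_retained=len(summaries),
        n_removed=n_removed,
        removal_reasons=reasons,
        vbr_quartiles=vbr_q,
        e_fit=e_fit,
    )


def vbr_statistics(summaries: list[RunSummary]) -> tuple[float, float, float]:
    """(lower quartile, median, upper quartile) of run-averaged VBR.

    Returns NaNs for an empty input rather than raising: an ensemble with
    nothing retained is a legitimate (if disappointing) outcome.
    """
    values = [s.avg_VBR for s in summaries if not np.isnan(s.avg_VBR)]
    if not values:
        return (float("nan"),) * 3
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return float(q25), float(q50), float(q75)


def fit_lognormal_E(
    values: np.ndarray,
    quantile_levels: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> dict:
    """Maximum-likelihood log-normal fit to run-averaged elevator fluxes.

    Fits a normal to ``log(E)`` (the MLE of the log-normal with location
    fixed at zero) and evaluates the requested quantiles from the fitted
    distribution.  A degenerate sample (all values identical) is flagged
    via ``"degenerate": True`` with sigma = 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no E values to fit")
    if np.any(values <= 0):
        bad = values[values <= 0]
        raise ValueError(f"E values must be positive for a log-normal fit; got {bad[:5]}")
    log_v = np.log(values)
    mu_star = float(log_v.mean())
    sigma_star = float(log_v.std())  # MLE (ddof=0)
    # identical samples leave only rounding noise in the spread
    degenerate = sigma_star <= 1e-12 * max(1.0, abs(mu_star))
    if degenerate:
        sigma_star = 0.0
    if degenerate:
        quantiles = {str(q): float(np.exp(mu_star)) for q in quantile_levels}
    else:
        dist = stats.lognorm(s=sigma_star, scale=np.exp(mu_star))
        quantiles = {str(q): float(dist.ppf(q)) for q in quantile_levels}
    return {
        "mu_log": mu_star,
        "sigma_log": sigma_star,
        "median": float(np.exp(mu_star)),
        "n": int(values.size),
        "degenerate": bool(degenerate),
        "quantiles": quantiles,
    }
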