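"""Named scenario presets and the artifact-bundle runner.

Each preset bundles the configuration of one of the package's standard
experiments — single closed runs at fixed burst sizes, the closed and open
Monte Carlo ensembles, a worked steady-state open run, and the biofilm
feasibility map — and :func:`run_scenario` executes it into a directory of
CSV/JSON artifacts with a manifest.  Re-running with the same seed
reproduces every numeric output bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .elevator import ElevatorScenario, feasibility_map
from .ensemble import SamplingConfig, run_ensemble
from .model import ModelParameters
from .simulate import integrate, summarize_run

__all__ = ["ScenarioPreset", "PRESETS", "run_scenario"]

#: Fixed single-run settings shared by the worked closed and open runs:
#: mid-range temperature and growth rate, full lytic activity, the
#: observationally derived infection rate.
_WORKED_RUN = dict(
    N_i=30.0, B_i=1e5, V_i=1e6, T=-2.0, g_exudate=0.09,
    mu=0.024, gamma=1.0, phi=1e-10,
)


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    kind: str          # "single_runs" | "ensemble" | "feasibility_map"
    description: str
    options: dict

    def resolved_options(self, **overrides) -> dict:
        out = dict(self.options)
        out.update({k: v for k, v in overrides.items() if v is not None})
        return out


PRESETS: dict[str, ScenarioPreset] = {
    "closed-ensemble": ScenarioPreset(
        "closed-ensemble", "ensemble",
        "Closed-system (brine pocket) Monte Carlo ensemble, 300 runs",
        dict(mode="closed", n_runs=300, duration=25_000.0, output_step=10.0),
    ),
    "closed-burst-runs": ScenarioPreset(
        "closed-burst-runs", "single_runs",
        "Single closed runs at burst sizes 10/100/250 over 15,000 h",
        dict(mode="closed", betas=(10.0, 100.0, 250.0), duration=15_000.0,
             output_step=2.0),
    ),
    "closed-burst-sweep": ScenarioPreset(
        "closed-burst-sweep", "single_runs",
        "Closed-run burst-size sweep 10..500 over 25,000 h",
        dict(mode="closed", betas=(10.0, 50.0, 100.0, 250.0, 500.0),
             duration=25_000.0, output_step=2.0),
    ),
    "open-steady-run": ScenarioPreset(
        "open-steady-run", "single_runs",
        "Single open run at the worked steady elevator factor f=72.416",
        dict(mode="open", betas=(250.0,), f_elevator=72.416,
             duration=200_000.0, output_step=50.0),
    ),
    "open-ensemble": ScenarioPreset(
        "open-ensemble", "ensemble",
        "Open-system (sub-ice biosphere) ensemble, 2500 runs of 200,000 h",
        dict(mode="open", n_runs=2500, duration=200_000.0, output_step=50.0),
    ),
    "feasibility-map": ScenarioPreset(
        "feasibility-map", "feasibility_map",
        "Required elevator flux over benthic biomass rate x biofilm depth",
        dict(n_b_r=25, n_depth=25, depth_lo_mm=1e-3, depth_hi_mm=1e2),
    ),
}

#: Figure-number aliases for the presets above.
_ALIASES = {
    "fig2": "closed-ensemble",
    "fig3": "closed-burst-runs",
    "fig4": "closed-burst-sweep",
    "fig5": "open-ensemble",
    "fig6": "open-steady-run",
    "fig7": "open-ensemble",
    "fig8": "feasibility-map",
}


def get_preset(name: str) -> ScenarioPreset:
    key = _ALIASES.get(name, name)
    if key not in PRESETS:
        known = sorted(set(PRESETS) | set(_ALIASES))
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(known)}")
    return PRESETS[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(
    name: str,
    seed: int = 0,
    output_dir: str | Path = ".",
    plots: bool = False,
    **overrides,
) -> dict:
    """Execute a preset and write its artifact bundle.

    Returns the manifest (also written as ``manifest.json``): preset
    name, seed, resolved options, and the sha256 of every output file.
    Overrides (``n_runs``, ``duration``, ``e_quantiles``, ...) replace
    preset defaults; ``None`` values are ignored.
    """
    preset = get_preset(name)
    opts = preset.resolved_options(**overrides)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    if preset.kind == "single_runs":
        rows = []
        for beta in opts["betas"]:
            fields = dict(_WORKED_RUN, beta=beta, mode=opts["mode"])
            if opts["mode"] == "open":
                fields["f_elevator"] = opts["f_elevator"]
            p = ModelParameters(**fields)
            traj = integrate(p, opts["duration"], opts["output_step"])
            stem = f"trajectory_beta{beta:g}"
            traj.write_csv(outdir / f"{stem}.csv")
            files.append(outdir / f"{stem}.csv")
            summary = summarize_run(traj)
            summary.to_json(outdir / f"{stem}_summary.json")
            files.append(outdir / f"{stem}_summary.json")
            rows.append((beta, summary.interpeak_interval, summary.longevity))
            if plots:
                _plot_trajectory(traj, outdir / f"{stem}.png")
        with open(outdir / "burst_size_comparison.csv", "w") as fh:
            fh.write("beta,interpeak_interval_hr,longevity_hr\n")
            for beta, ipi, lon in rows:
                fh.write(f"{beta:g},{ipi},{lon}\n")
        files.append(outdir / "burst_size_comparison.csv")

    elif preset.kind == "ensemble":
        cfg = SamplingConfig(
            n_runs=opts["n_runs"], seed=seed, mode=opts["mode"],
            fixed=opts.get("fixed", {}),
        )
        result = run_ensemble(
            cfg, opts["duration"], opts["output_step"],
            rtol=opts.get("rtol", 1e-8), atol=opts.get("atol", 1e-12),
        )
        result.write_json(outdir / "ensemble_summary.json")
        files.append(outdir / "ensemble_summary.json")
        with open(outdir / "per_run_metrics.csv", "w") as fh:
            result.per_run_frame().to_csv(fh, index=False)
        files.append(outdir / "per_run_metrics.csv")

    elif preset.kind == "feasibility_map":
        quantiles = opts.get("e_quantiles")
        if quantiles is None:
            # Derive the supply quantiles from an open ensemble.
            ens_opts = PRESETS["open-ensemble"].options
            cfg = SamplingConfig(
                n_runs=opts.get("n_runs", ens_opts["n_runs"]), seed=seed,
                mode="open",
            )
            result = run_ensemble(cfg, ens_opts["duration"], ens_opts["output_step"])
            if result.e_fit is None:
                raise RuntimeError("open ensemble retained no steady runs")
            q = result.e_fit["quantiles"]
            quantiles = {"q25": q["0.25"], "median": q["0.5"], "q75": q["0.75"]}
        scn = ElevatorScenario()
        b_r_grid = np.geomspace(6e7, 6e9, opts["n_b_r"])
        depth_grid = np.geomspace(opts["depth_lo_mm"], opts["depth_hi_mm"],
                                  opts["n_depth"])
        grid, contours = feasibility_map(b_r_grid, depth_grid, quantiles, scn)
        grid.to_csv(outdir / "required_flux_grid.csv")
        files.append(outdir / "required_flux_grid.csv")
        for qname, curve in contours.items():
            path = outdir / f"contour_{qname}.csv"
            curve.to_csv(path, index=False)
            files.append(path)

    manifest = {
        "preset": preset.name,
        "seed": seed,
        "options": _jsonable(opts),
        "files": {f.name: _sha256(f) for f in sorted(files)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _plot_trajectory(traj, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, sharex=True, figsize=(7, 9))
    for ax, (label, series) in zip(
        axes,
        [("DOM (ug/mL)", traj.N), ("B (cells/mL)", traj.B),
         ("V (cells/mL)", traj.V), ("VBR", traj.vbr)],
    ):
        ax.plot(traj.t, series, lw=0.8)
        ax.set_yscale("log")
        ax.set_ylabel(label)
    axes[-1].set_xlabel("time (hr)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
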