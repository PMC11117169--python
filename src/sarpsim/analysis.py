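"""Scenario comparison: washout and redistribution metrics.

Runs simulate + track for each requested scenario on one shared network and
heart/periphery configuration, and reports the quantities behind the
washout hypothesis: the fraction of released indicators cleared into the
cardiac chambers via Thebesian shunts by 600 s (washout_fraction), and the
fraction of ischemic-region capillaries reached by tracer originating at
the femoral retroperfusion source (retro_perfusion_fraction). Stochastic
metrics carry mean +/- SD over seed replicates.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import morphometry as mm
from . import hemodynamics as hd
from . import tracking as tr
from .config import PipelineConfig

log = logging.getLogger("sarpsim")

_SEED_MOD = 2 ** 31 - 1


class AnalysisError(ValueError):
    """Invalid comparison request."""


def _derive_seed(base: int, *streams: int) -> int:
    """Deterministic sub-seed (stays below 2**31)."""
    h = int(base) % _SEED_MOD
    for s in streams:
        h = (h * 1_000_003 + int(s) + 1) % _SEED_MOD
    return h


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def retro_reach(network: mm.NetworkTopology, solution: hd.HemoSolution,
                n: int = 1000, seed: int = 0,
                micro_volume_scale: float = tr.MICRO_VOLUME_SCALE,
                t_end: float = 600.0) -> float:
    """Fraction of ischemic-region capillaries reached by source tracer.

    Tracer is released in the retroperfusion line and advected through the
    solved field; the result is the fraction of region capillaries entered
    by at least one tracer. Returns 0 when the scenario prescribes no
    source (no source tracer exists) and raises when the network carries no
    tagged ischemic region.
    """
    region = network.ischemic_region()
    if not region:
        raise AnalysisError("network has no tagged ischemic region")
    region_caps = {vid for vid in region
                   if network.vessel(vid).kind == mm.CAPILLARY}
    if not region_caps:
        raise AnalysisError("ischemic region contains no capillaries")
    src = network.tags.get("source_line")
    if src is None or src in solution.occluded_ids:
        return 0.0
    cohort = tr.release_indicators(network, [src], n, seed=seed)
    res = tr.advect(cohort, solution, t_end=t_end, mode="steady", seed=seed + 1,
                    micro_volume_scale=micro_volume_scale)
    return len(res.visited_capillaries & region_caps) / len(region_caps)


@dataclass
class ScenarioResult:
    """Per-scenario simulation + tracking summary."""

    name: str
    washout_fraction: list[float]          # cleared_thebesian at t_end, per replicate
    sinus_fraction: list[float]
    retro_perfusion_fraction: list[float]
    curve_times: np.ndarray
    curve_mean: dict                       # fate -> mean cumulative fraction
    periodicity_residual: float
    mass_residual_max: float
    mean_gcv_proximal_flow_ml_s: float
    solution: hd.HemoSolution | None = field(default=None, repr=False)
    cohorts: list = field(default_factory=list, repr=False)

    @property
    def washout_mean(self) -> float:
        return float(np.mean(self.washout_fraction))

    @property
    def washout_sd(self) -> float:
        x = self.washout_fraction
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    @property
    def retro_mean(self) -> float:
        return float(np.mean(self.retro_perfusion_fraction))


@dataclass
class ComparisonReport:
    """Cross-scenario comparison; fully reproducible from (network, config, seeds)."""

    scenarios: dict[str, ScenarioResult]
    deltas: dict[str, float]
    config_digest: str
    base_seed: int
    network_seed: int

    def to_dict(self) -> dict:
        out = {
            "config_digest": self.config_digest,
            "base_seed": self.base_seed,
            "network_seed": self.network_seed,
            "scenarios": {},
            "deltas": self.deltas,
        }
        for name, r in self.scenarios.items():
            out["scenarios"][name] = {
                "washout_fraction_600s": r.washout_fraction,
                "washout_mean": r.washout_mean,
                "washout_sd": r.washout_sd,
                "sinus_fraction": r.sinus_fraction,
                "retro_perfusion_fraction": r.retro_perfusion_fraction,
                "retro_mean": r.retro_mean,
                "periodicity_residual": r.periodicity_residual,
                "mass_residual_max": r.mass_residual_max,
                "mean_gcv_proximal_flow_ml_s": r.mean_gcv_proximal_flow_ml_s,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    def summary_markdown(self) -> str:
        lines = ["# Scenario comparison", "",
                 f"config digest: `{self.config_digest[:12]}`, "
                 f"seed {self.base_seed}", "",
                 "| scenario | washout fraction (600 s) | retro reach | GCV prox flow (mL/s) |",
                 "|---|---|---|---|"]
        for name, r in self.scenarios.items():
            lines.append(
                f"| {name} | {r.washout_mean:.3f} +/- {r.washout_sd:.3f} | "
                f"{r.retro_mean:.3f} | {r.mean_gcv_proximal_flow_ml_s:.3e} |")
        lines.append("")
        for k, v in sorted(self.deltas.items()):
            lines.append(f"- delta {k}: {v:+.3f}")
        lines.append("")
        return "\n".join(lines)


def compare_scenarios(network: mm.NetworkTopology, config: PipelineConfig,
                      scenario_names: list[str] | None = None,
                      base_seed: int | None = None,
                      keep_solutions: bool = False) -> ComparisonReport:
    """Run simulate + track for each scenario and compare washout metrics.

    All scenarios share the network and heart/periphery configuration;
    replicates re-draw release and routing seeds over each scenario's
    (deterministic) flow solution. Deltas are pairwise differences of the
    replicate-mean washout fractions.
    """
    names = scenario_names if scenario_names is not None else config.scenarios.names
    if not names:
        raise AnalysisError("scenario list must not be empty")
    seed = config.seed if base_seed is None else base_seed
    heart = config.heart.build()
    periphery = config.periphery.build()
    elements = hd.build_elements(
        network, _order_table(config),
        viscosity=config.elements.viscosity, beta=config.elements.beta,
        pref_mmhg=config.elements.pref_mmhg,
        c_total_order0_ml_per_mmhg=config.elements.c_total_order0_ml_per_mmhg,
        imp_peak=config.elements.imp_peak,
        imp_zero_order=config.elements.imp_zero_order)
    tk = config.tracking
    sites = tr.sites_by_order(network, tk.release_orders, tk.region_only)
    times = np.linspace(0.0, tk.duration_s, 241)
    results: dict[str, ScenarioResult] = {}
    for si, name in enumerate(names):
        scenario = config.scenarios.build(name)
        log.info("solving scenario %s", name)
        system = hd.assemble_system(network, elements, heart, periphery, scenario)
        sol = hd.solve(system, duration=config.solver.n_beats * heart.period,
                       output_dt=config.solver.output_dt,
                       rtol=config.solver.rtol, atol_rel=config.solver.atol_rel)
        wf, sf, rr, curves, cohorts = [], [], [], [], []
        for rep in range(tk.replicates):
            cohort = tr.release_indicators(
                network, sites, tk.n_indicators, mode=tk.release_mode,
                window=tk.release_window_s,
                seed=_derive_seed(seed, si, rep, 0))
            tr.advect(cohort, sol, t_end=tk.duration_s, mode=tk.mode,
                      seed=_derive_seed(seed, si, rep, 1),
                      micro_volume_scale=tk.micro_volume_scale)
            curve = tr.washout_curve(cohort, times, release_mode=tk.release_mode)
            wf.append(curve.at(tk.duration_s))
            sf.append(curve.at(tk.duration_s, "cleared_sinus"))
            rr.append(retro_reach(network, sol, tk.n_retro,
                                  seed=_derive_seed(seed, si, rep, 2),
                                  micro_volume_scale=tk.micro_volume_scale,
                                  t_end=tk.duration_s))
            curves.append(curve)
            cohorts.append(cohort)
        curve_mean = {f: np.mean([c.fractions[f] for c in curves], axis=0)
                      for f in tr.FATES}
        gcv_ids = network.tags.get("gcv_proximal", [])
        mf = sol.mean_flows()
        gcv_q = float(np.mean([mf[sol.vessel_index(v)] for v in gcv_ids])) \
            if gcv_ids else float("nan")
        results[name] = ScenarioResult(
            name=name, washout_fraction=wf, sinus_fraction=sf,
            retro_perfusion_fraction=rr, curve_times=times,
            curve_mean=curve_mean,
            periodicity_residual=sol.periodicity_residual,
            mass_residual_max=sol.mass_residual_max,
            mean_gcv_proximal_flow_ml_s=gcv_q,
            solution=sol if keep_solutions else None,
            cohorts=cohorts if keep_solutions else [])
        log.info("scenario %s: washout %.3f +/- %.3f, retro reach %.3f",
                 name, results[name].washout_mean, results[name].washout_sd,
                 results[name].retro_mean)
    deltas = {}
    for a in names:
        for b in names:
            if a != b:
                deltas[f"{a}_minus_{b}"] = (results[a].washout_mean
                                            - results[b].washout_mean)
    return ComparisonReport(results, deltas, config.digest(), seed, network.seed)


def _order_table(config: PipelineConfig):
    if config.network.order_table:
        return mm.load_order_table(config.network.order_table)
    return mm.default_order_table()


def build_network_from_config(config: PipelineConfig) -> mm.NetworkTopology:
    nc = config.network
    return mm.build_default_network(
        seed=nc.seed, order_table=_order_table(config), n_shunts=nc.n_shunts,
        shunt_resistance=nc.shunt_resistance, n_equivalent=nc.n_equivalent,
        thebesian_order_limit=nc.thebesian_order_limit,
        thebesian_chamber=nc.thebesian_chamber,
        viscosity=config.elements.viscosity)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | str | Path,
                 out_dir: str | Path) -> ComparisonReport:
    """End-to-end run: build network, compare scenarios, write artifacts.

    Writes network.json, per-scenario washout-curve CSVs and fate tables
    (first replicate), report.json / report.md, the resolved config, and a
    run log. The report JSON is byte-identical across reruns of the same
    config (timestamps go only to the log).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        log.info("sarpsim %s, config digest %s", __version__, config.digest())
        network = build_network_from_config(config)
        network.save(out / "network.json")
        report = compare_scenarios(network, config, keep_solutions=True)
        for name, r in report.scenarios.items():
            curve = pd.DataFrame(
                {"time_s": r.curve_times,
                 "f_thebesian": r.curve_mean["cleared_thebesian"],
                 "f_sinus": r.curve_mean["cleared_sinus"],
                 "f_trapped": r.curve_mean["trapped_stump"],
                 "f_in_network": r.curve_mean["in_network"]})
            curve.to_csv(out / f"washout_{name}.csv", index=False,
                         float_format="%.9g")
            if r.cohorts:
                tr.save_fate_table(r.cohorts[0], out / f"fates_{name}.csv")
            r.solution = None  # drop heavy arrays before report serialization
            r.cohorts = []
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(report.summary_markdown())
        config.to_yaml(out / "config_resolved.yaml")
        log.info("pipeline complete: %s", out)
        return report
    finally:
        log.removeHandler(fh)
        fh.close()


def plot_washout_curves(report: ComparisonReport, path: str | Path) -> None:
    """One panel of cumulative Thebesian washout per scenario."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, r in report.scenarios.items():
        ax.plot(r.curve_times / 60.0, r.curve_mean["cleared_thebesian"],
                label=name)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fraction cleared via Thebesian veins")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
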