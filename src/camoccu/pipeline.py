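"""End-to-end orchestration: ingest -> model selection -> prediction -> activity.

`run_pipeline` sequences the stages from one configuration and a single
root seed (expanded per stage through `numpy.random.SeedSequence`, in the
order: simulation, model fitting, activity bootstraps), writes the
paper-shaped output tables under the output directory, and returns a
`RunReport`. `summarize` renders a compact markdown summary of a report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity as act, camdata
from .camdata import DEFAULT_SPECIES
from .msom import predict_occupancy
from .selection import SelectionReport, multistep_select
from .simulate import SimulationScenario, gen_dataset

PAIRS = (("marten", "human"), ("marten", "cat"))


@dataclass
class RunConfig:
    """Pipeline configuration; paths may be None when simulating."""
    events_csv: str | None = None
    deployments_csv: str | None = None
    site_covariates_csv: str | None = None
    simulate: bool = True
    n_sites: int = 77
    n_occasions: int = 30
    species: tuple[str, ...] = DEFAULT_SPECIES
    truth_label: str = "Mod1"
    min_gap_s: float = 60.0
    max_occasions: int = 30
    lockdown_coding: str = "factor"
    overlap_B: int = 10_000
    activity_B: int = 10_000
    anchor_lat: float = act.DEFAULT_LAT
    anchor_lon: float = act.DEFAULT_LON
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for p in (cfg.events_csv, cfg.deployments_csv, cfg.site_covariates_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input file does not exist: {p}")
        return cfg


@dataclass
class RunReport:
    config: RunConfig
    trap_days: int = 0
    n_sites: int = 0
    correlation: pd.DataFrame | None = None
    selection: SelectionReport | None = None
    predictions: pd.DataFrame | None = None
    activity_levels: dict = field(default_factory=dict)
    overlaps: dict = field(default_factory=dict)
    wald: dict = field(default_factory=dict)
    event_counts: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)


def _stage_seeds(seed: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(3)]


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Run every stage, writing outputs as they are produced.

    A stage failure is recorded in ``report.errors`` under the stage name
    and later stages that do not depend on it still run; partial outputs
    are preserved.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, fit_seed, boot_seed = _stage_seeds(config.seed)
    report = RunReport(config)

    # -- stage 1: ingest / simulate ----------------------------------------
    try:
        if config.simulate:
            scenario = SimulationScenario(n_sites=config.n_sites,
                                          n_occasions=config.n_occasions,
                                          species=config.species,
                                          structure_label=config.truth_label)
            ds = gen_dataset(scenario, seed=sim_seed)
            events_raw = ds.events
            deployments, site_cov = ds.deployments, ds.site_covariates
            ds.truth_frame().to_csv(out / "truth.csv")
        else:
            events_raw = camdata.read_events(config.events_csv)
            deployments = camdata.read_deployments(config.deployments_csv)
            site_cov = camdata.read_site_covariates(config.site_covariates_csv)
        events = camdata.extract_events(events_raw, min_gap_s=config.min_gap_s)
        history = camdata.build_detection_history(
            events, deployments, config.species, max_occasions=config.max_occasions)
        cov = camdata.standardize_covariates(
            camdata.make_covariate_table(site_cov, history))
        report.trap_days = history.total_trap_days
        report.n_sites = len(history.site_order)
        report.correlation = camdata.correlation_screen(cov)
        report.event_counts = events["species"].value_counts().to_dict()
        history.to_long().to_csv(out / "detection_history.csv", index=False)
        history.effort.to_csv(out / "effort.csv")
        report.correlation.to_csv(out / "correlation_screen.csv", index=False)
    except (ValueError, FileNotFoundError, KeyError) as exc:
        report.errors["ingest"] = str(exc)
        _write_log(report, out)
        return report

    # -- stage 2: multistep model selection --------------------------------
    try:
        sel = multistep_select(history, cov, config.species,
                               lockdown_coding=config.lockdown_coding,
                               seed=fit_seed)
        report.selection = sel
        tables = pd.concat([
            sel.detection_table.assign(step="detection"),
            sel.marginal_table.assign(step="marginal"),
            sel.conditional_table.assign(step="conditional"),
        ])
        tables.to_csv(out / "aic_tables.csv", index=False)
        with open(out / "selection_report.json", "w") as fh:
            json.dump(sel.to_dict(), fh, indent=1, default=float)
    except (RuntimeError, ValueError) as exc:
        report.errors["selection"] = str(exc)

    # -- stage 3: occupancy prediction on the sampled sites ----------------
    if report.selection is not None:
        try:
            fit = report.selection.best_fit
            conds = [(0, 1, True), (0, 1, False), (0, 2, True), (0, 2, False)]
            pred = predict_occupancy(fit, cov.site, standardized=True,
                                     conditionals=conds)
            report.predictions = pred
            pred.to_csv(out / "occupancy_predictions.csv")
        except (RuntimeError, ValueError) as exc:
            report.errors["prediction"] = str(exc)

    # -- stage 4: activity analysis ----------------------------------------
    try:
        samples = {}
        for sp in config.species:
            ts = events.loc[events["species"] == sp, "timestamp"]
            if len(ts) >= 2:
                samples[sp] = act.solar_anchor(ts, config.anchor_lat,
                                               config.anchor_lon, species=sp)
        lvl_rows = []
        for k, (sp, sample) in enumerate(samples.items()):
            lv = act.activity_level(sample, B=config.activity_B, seed=boot_seed + k)
            report.activity_levels[sp] = lv
            lvl_rows.append((sp, sample.n, lv.level, lv.se, *lv.ci))
        pd.DataFrame(lvl_rows, columns=["species", "n", "level", "se",
                                        "ci_low", "ci_high"]
                     ).to_csv(out / "activity_report.csv", index=False)
        grid_rows = []
        for sp, sample in samples.items():
            dens = act.fit_kde(sample)
            grid_rows.append(pd.DataFrame({"species": sp, "angle_rad": dens.grid,
                                           "density": dens.values}))
        if grid_rows:
            pd.concat(grid_rows).to_csv(out / "density_grids.csv", index=False)
        ov_rows = []
        for k, (a, b) in enumerate(PAIRS):
            if a not in samples or b not in samples:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ov = act.bootstrap_overlap(samples[a], samples[b],
                                           B=config.overlap_B,
                                           seed=boot_seed + 100 + k)
            report.overlaps[(a, b)] = ov
            w = act.wald_compare(report.activity_levels[a], report.activity_levels[b])
            report.wald[(a, b)] = w
            lo, hi = ov.cis[ov.selected_ci]
            ov_rows.append((f"{a}-{b}", ov.estimator, ov.value, lo, hi, ov.B,
                            ov.bias, ov.selected_ci, w["W"], w["p"]))
        pd.DataFrame(ov_rows, columns=["pair", "estimator", "delta", "ci_low",
                                       "ci_high", "B", "bias", "ci_variant",
                                       "W", "p"]
                     ).to_csv(out / "overlap_report.csv", index=False)
    except (RuntimeError, ValueError) as exc:
        report.errors["activity"] = str(exc)

    _write_log(report, out)
    return report


def _write_log(report: RunReport, out: Path) -> None:
    log = {
        "camoccu_version": __version__,
        "seed": report.config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(report.config).items()},
        "trap_days": report.trap_days,
        "n_sites": report.n_sites,
        "errors": report.errors,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)


def summarize(report: RunReport) -> str:
    """Markdown summary of a completed run (pure function of the report)."""
    lines = [f"# camoccu run summary", "",
             f"Sites: {report.n_sites}; active trap days: {report.trap_days}."]
    if report.event_counts:
        counts = ", ".join(f"{sp}: {n}" for sp, n in sorted(report.event_counts.items()))
        lines.append(f"Independent events — {counts}.")
    if report.selection is not None:
        sel = report.selection
        for name, tab in (("Detection structures", sel.detection_table),
                          ("Marginal occupancy", sel.marginal_table),
                          ("Conditional occupancy", sel.conditional_table)):
            lines += ["", f"## {name}", "", "| model | K | dAIC | weight |",
                      "|---|---|---|---|"]
            for r in tab.itertuples():
                lines.append(f"| {r.label} | {r.K} | {r.dAIC:.2f} | {r.weight:.3f} |")
        if sel.uninformative:
            u = sel.uninformative
            lines.append(f"\nDeviance gain {u['smaller']} -> {u['larger']}: "
                         f"{u['deviance_diff']:.2f}"
                         + (" (uninformative)" if u["uninformative"] else ""))
        lines += ["", "## Top model coefficients", ""]
        ct = sel.best_fit.coef_table()
        lines += ["| term | estimate | se |", "|---|---|---|"]
        lines += [f"| {ix} | {r.estimate:.3f} | {r.se:.3f} |"
                  for ix, r in ct.iterrows()]
    if report.predictions is not None:
        lines += ["", "## Marginal occupancy (across sampled sites)", ""]
        for sp in report.config.species:
            col = report.predictions[f"marginal_{sp}"]
            lines.append(f"- {sp}: mean {col.mean():.3f} "
                         f"(range {col.min():.3f}-{col.max():.3f})")
    if report.overlaps:
        lines += ["", "## Activity overlap", "",
                  "| pair | estimator | delta | 95% CI | W | p |", "|---|---|---|---|---|---|"]
        for (a, b), ov in report.overlaps.items():
            lo, hi = ov.cis[ov.selected_ci]
            w = report.wald[(a, b)]
            lines.append(f"| {a}-{b} | {ov.estimator} | {ov.value:.2f} | "
                         f"[{lo:.2f}, {hi:.2f}] | {w['W']:.2f} | {w['p']:.2f} |")
    if report.errors:
        lines += ["", "## Stage errors", ""]
        lines += [f"- {stage}: {msg}" for stage, msg in report.errors.items()]
    return "\n".join(lines) + "\n"
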