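"""End-to-end analysis workflows with config files and logged outputs.

Three workflows mirror the package's main analyses:

* ``mutational_comparison`` — single-mutant effect predictions (epistatic
  Potts versus non-epistatic profile) against an external measured-effect
  table, reported as rank correlations and TSV heat-map exports;
* ``forecast`` — calibrate (T, N_MC) to a reference library if provided,
  then simulate libraries over a requested protocol grid and emit
  energy/distance, frequency-spectrum and PPV tables;
* ``emergence_scan`` — the PPV emergence grid over (T, divergence, depth),
  with cells marked when indistinguishable from the permutation null.

Configs are TOML files (flat sections mirroring module options); every
report directory embeds the fully resolved config including the master
seed, so identical configs give identical reports.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import PROTEIN
from .calibrate import CalibrationBudget
from .codons import assign_codons, translate
from .contactmap import ContactMap, contact_map_from_distances
from .contacts import parameter_scan, ppv_null
from .io import read_dna_fasta, read_msa, write_mutant_scan
from .landscape import ProfileModel, mutant_scan, profile_from_msa, read_params
from .libstats import energy_distance_profile, site_frequencies
from .model import SequenceEvolutionModel

__all__ = ["RunConfig", "PipelineReport", "run", "run_mutational_comparison",
           "run_forecast", "run_emergence_scan"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run."""

    workflow: str
    out_dir: Path
    seed: int = 0
    options: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        run = raw.pop("run", {})
        return cls(workflow=run["workflow"], out_dir=Path(run["out_dir"]),
                   seed=int(run.get("seed", 0)), options=raw)

    def resolved(self) -> dict:
        return {"workflow": self.workflow, "out_dir": str(self.out_dir),
                "seed": self.seed, "options": self.options}


@dataclass
class PipelineReport:
    """Tables and headline metrics of a completed workflow."""

    config: RunConfig
    tables: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def write(self) -> Path:
        out = Path(self.config.out_dir)
        (out / "tables").mkdir(parents=True, exist_ok=True)
        (out / "logs").mkdir(exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / "tables" / f"{name}.tsv", sep="\t", index=False)
        with open(out / "config.resolved", "w") as fh:
            json.dump(self.config.resolved(), fh, indent=2, sort_keys=True)
        with open(out / "metrics.json", "w") as fh:
            json.dump(self.metrics, fh, indent=2, sort_keys=True)
        return out


def _load_inputs(cfg: RunConfig):
    opt = cfg.options.get("inputs", {})
    landscape = read_params(opt["model"])
    if "wildtype_dna" in opt:
        dna = read_dna_fasta(opt["wildtype_dna"])
        wt = assign_codons(translate(dna), mode="given_dna", dna=dna)
    else:
        _, msa = read_msa(opt["wildtype_protein"])
        wt = assign_codons(msa[0], mode="random_synonymous", seed=cfg.seed)
    return landscape, wt, opt


def run_mutational_comparison(cfg: RunConfig) -> PipelineReport:
    """Compare predicted single-mutant effects with a measured-effect table.

    The effect table is a TSV with columns site, mutant_aa, effect (0-based
    sites over the model alignment).  Rank correlations are reported for
    the epistatic Potts model and for the profile baseline (fitted from a
    natural alignment if given, else the fields of the Potts model).
    """
    landscape, wt, opt = _load_inputs(cfg)
    effects = pd.read_csv(opt["effects"], sep="\t")
    scan_potts = mutant_scan(landscape, wt.aa.astype(np.intp))
    if "natural_msa" in opt:
        _, nat = read_msa(opt["natural_msa"])
        profile = profile_from_msa(nat)
    else:
        profile = ProfileModel(landscape.h.copy(), landscape.alphabet)
    scan_prof = mutant_scan(profile, wt.aa.astype(np.intp))

    targets = [s for s in PROTEIN.symbols if s != PROTEIN.gap]
    col = {b: k for k, b in enumerate(targets)}
    rows = []
    for site, aa, eff in effects[["site", "mutant_aa", "effect"]].itertuples(index=False):
        site = int(site)
        if site >= landscape.L or aa not in col:
            raise ValueError(f"effect table position ({site},{aa}) does not "
                             f"match the model")
        rows.append((site, aa, eff, scan_potts[site, col[aa]], scan_prof[site, col[aa]]))
    tab = pd.DataFrame(rows, columns=["site", "mutant_aa", "effect",
                                      "dE_potts", "dE_profile"])
    tab = tab.dropna()
    rho_potts = float(stats.spearmanr(tab["dE_potts"], tab["effect"]).statistic)
    rho_prof = float(stats.spearmanr(tab["dE_profile"], tab["effect"]).statistic)
    logger.info("mutational comparison: Spearman potts=%.3f profile=%.3f",
                rho_potts, rho_prof)
    report = PipelineReport(cfg, tables={"mutational_effects": tab},
                            metrics={"spearman_potts": rho_potts,
                                     "spearman_profile": rho_prof})
    out = report.write()
    write_mutant_scan(out / "tables" / "mutant_scan_potts.tsv", scan_potts, wt.aa)
    return report


def run_forecast(cfg: RunConfig) -> PipelineReport:
    """Calibrate to a reference library (optional) and forecast protocols."""
    landscape, wt, opt = _load_inputs(cfg)
    sim = cfg.options.get("simulate", {})
    reference = None
    if "reference" in opt:
        _, reference = read_msa(opt["reference"])
    model = SequenceEvolutionModel(landscape, wt, reference)
    metrics: dict = {}
    tables: dict = {}
    if reference is not None:
        budget = CalibrationBudget(
            n_pilot=int(sim.get("n_pilot", 500)),
            max_steps=int(sim.get("max_steps", 400)),
            seed=cfg.seed)
        res = model.fit(T_grid=tuple(sim.get("t_grid", (0.25, 0.5, 1.0, 2.0, 4.0))),
                        budget=budget)
        metrics["fitted_T"] = res.calibration.fitted_T
        metrics["fitted_steps"] = res.calibration.fitted_steps
        tables["calibration"] = res.diagnostics
        T_values = [res.calibration.fitted_T]
        steps = [res.calibration.fitted_steps]
    else:
        T_values = list(sim.get("t_values", [1.0]))
        steps = list(sim.get("snapshot_steps", [100]))
    sizes = [int(m) for m in sim.get("library_sizes", [500])]
    lib = model.simulate(T_values[0], max(steps), max(sizes),
                         snapshot_steps=steps, seed=cfg.seed)
    prof = energy_distance_profile(lib.msa(), landscape, wt)
    tables["energy_distance"] = prof
    freq = site_frequencies(lib.msa(), q=landscape.q)
    tables["site_frequencies"] = freq.to_frame()
    metrics["mean_hamming"] = float(lib.distances[lib.steps[-1]].mean())
    if "distances" in opt or "contact_map" in opt:
        cmap = _load_contact_map(opt, landscape.L)
        scan_cfg = cfg.options.get("scan", {})
        grid = parameter_scan(landscape, wt, T_values, steps, sizes,
                              int(scan_cfg.get("n_replicates", 1)), cmap,
                              seed=cfg.seed,
                              n_predictions=int(scan_cfg.get("n_predictions", 100)),
                              pseudocount=float(scan_cfg.get("pseudocount", 0.6)))
        tables["ppv_grid"] = grid
        metrics["max_ppv"] = float(grid["mean_ppv"].max())
    report = PipelineReport(cfg, tables=tables, metrics=metrics)
    report.write()
    return report


def _load_contact_map(opt, L) -> ContactMap:
    if "contact_map" in opt:
        pairs = pd.read_csv(opt["contact_map"], sep="\t")
        return ContactMap(L=L, contacts={(int(i), int(j)) for i, j in
                                         pairs[["i", "j"]].itertuples(index=False)})
    return contact_map_from_distances(opt["distances"], L)


def run_emergence_scan(cfg: RunConfig) -> PipelineReport:
    """PPV emergence grid annotated with the permutation-null baseline."""
    landscape, wt, opt = _load_inputs(cfg)
    scan_cfg = cfg.options.get("scan", {})
    cmap = _load_contact_map(opt, landscape.L)
    n_pred = int(scan_cfg.get("n_predictions", 100))
    grid = parameter_scan(
        landscape, wt,
        T_values=list(scan_cfg.get("t_values", [1.0])),
        snapshot_steps=list(scan_cfg.get("snapshot_steps", [50, 100])),
        library_sizes=[int(m) for m in scan_cfg.get("library_sizes", [100, 500])],
        n_replicates=int(scan_cfg.get("n_replicates", 5)),
        contact_map=cmap, seed=cfg.seed, n_predictions=n_pred,
        pseudocount=float(scan_cfg.get("pseudocount", 0.6)))
    null_mean, null_sd = ppv_null(cmap, n_pred, seed=cfg.seed)
    se = grid["sd_ppv"] / np.sqrt(grid["n_replicates"])
    grid["null_mean"] = null_mean
    grid["above_null"] = grid["mean_ppv"] - 2 * se > null_mean + 2 * null_sd / np.sqrt(
        grid["n_replicates"])
    report = PipelineReport(cfg, tables={"ppv_grid": grid},
                            metrics={"null_ppv": null_mean,
                                     "max_ppv": float(grid["mean_ppv"].max())})
    report.write()
    return report


_WORKFLOWS = {
    "mutational_comparison": run_mutational_comparison,
    "forecast": run_forecast,
    "emergence_scan": run_emergence_scan,
}


def run(config) -> PipelineReport:
    """Run a workflow from a RunConfig or a TOML config path."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_toml(config)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.out_dir / "run.log")
    logging.getLogger("evoscape").addHandler(handler)
    try:
        if cfg.workflow not in _WORKFLOWS:
            raise ValueError(f"unknown workflow {cfg.workflow!r}")
        return _WORKFLOWS[cfg.workflow](cfg)
    finally:
        logging.getLogger("evoscape").removeHandler(handler)
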