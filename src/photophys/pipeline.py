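"""End-to-end orchestration: simulate -> analyze -> report.

``run_scenario`` generates every input dataset of a scenario, writes them
as plain CSV/TSV, re-reads them and runs the full analysis, mirroring the
study's shape: fluorescence parameters and light-curve fits, ECS
stoichiometry and electron flow, pigment / growth phenotypes, the
photodamage-repair decomposition, proteomics differential abundance and
the ANOVA/Dunnett comparisons.  Because the analysis stage always works
from the serialised inputs, re-running ``analyze`` on a saved simulation
is bit-identical to the in-memory pipeline.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .simulate import (
    SimScenario, load_scenario,
    gen_npq_trace, gen_rapid_light_curve, gen_ecs_experiment,
    gen_pigment_timecourse, gen_count_series, gen_hl_linc_timecourse,
    gen_abundance_matrix,
)
from .fluorescence import npq_timecourse, fit_light_curve
from .ecs import deconvolute_wavelengths, flash_amplitude, \
    psii_psi_stoichiometry, electron_flow_rate
from .phenotype import des_index, division_rates
from .photoinhibition import normalize_to_initial, photodamage_rate, \
    repair_recovery_metrics
from .proteomics import preprocess_abundances, log2_group_ratio, rots_test, \
    select_regulated, fold_conversions
from .inference import two_way_anova, dunnett_vs_control

__all__ = ["RunConfig", "ReportBundle", "run_scenario", "simulate_inputs",
           "analyze_inputs", "write_report"]

ALL_STAGES = ("fluorescence", "ecs", "phenotype", "photoinhibition",
              "proteomics", "inference")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario: str | Path | SimScenario = "cpftsy_study"
    seed: int = 0
    outdir: str | Path = "photophys_run"
    stages: Sequence[str] = ALL_STAGES
    p_max: float = 0.05
    fdr_max: float = 0.05
    log2_min: float = 0.5
    min_peptides: int = 2
    n_ecs_replicates: int = 20
    rots_B: int = 1000
    rots_n_perm: int = 1000
    dunnett_mc_draws: int = 100_000

    def __post_init__(self) -> None:
        for name, v in (("p_max", self.p_max), ("fdr_max", self.fdr_max),
                        ("log2_min", self.log2_min)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def resolve_scenario(self) -> SimScenario:
        if isinstance(self.scenario, SimScenario):
            return self.scenario
        return load_scenario(self.scenario)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the run seed."""
        state = np.random.SeedSequence(self.seed).generate_state(16)
        names = ["npq", "rlc", "ecs", "pigments", "growth", "hl_linc",
                 "proteomics", "rots", "dunnett"]
        return {nm: int(state[i] % (2**31)) for i, nm in enumerate(names)}

    def digest(self) -> str:
        d = asdict(self)
        d["scenario"] = (self.scenario.name
                         if isinstance(self.scenario, SimScenario)
                         else str(self.scenario))
        d["outdir"] = str(self.outdir)
        d["stages"] = list(self.stages)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Tidy result tables, the machine-readable summary and a manifest."""

    tables: dict[str, pd.DataFrame]
    summary: dict[str, dict[str, float]]
    manifest: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_inputs(config: RunConfig) -> Path:
    """Generate and serialise every enabled input dataset; returns inputs dir."""
    sc = config.resolve_scenario()
    seeds = config.stage_seeds()
    inputs = Path(config.outdir) / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)

    if "fluorescence" in stages:
        traces = [gen_npq_trace(sc, seeds["npq"] + i, line=ln)
                  for i, ln in enumerate(sc.lines)]
        pio.write_npq_traces(traces, inputs / "npq_traces.csv")
        rlc = []
        for i, ln in enumerate(sc.lines):
            df = gen_rapid_light_curve(sc, seeds["rlc"] + i, line=ln)
            df.insert(0, "line", ln)
            rlc.append(df)
        pio.write_table(pd.concat(rlc, ignore_index=True), inputs / "rlc.csv")

    if "ecs" in stages:
        lines = sc.ecs.get("lines_measured", sc.lines)
        exps = []
        k = 0
        for light in ("LL", "ML"):
            for ln in lines:
                for _ in range(config.n_ecs_replicates):
                    exps.append(gen_ecs_experiment(sc, seeds["ecs"] + k,
                                                   line=ln, light=light))
                    k += 1
        pio.write_ecs_experiments(exps, inputs / "ecs.csv")

    if "phenotype" in stages or "inference" in stages:
        pio.write_table(gen_pigment_timecourse(sc, seeds["pigments"]),
                        inputs / "pigments.csv")
    if "phenotype" in stages:
        counts = []
        k = 0
        for light in ("LL", "ML"):
            for ln in sc.lines:
                df = gen_count_series(sc, seeds["growth"] + k, line=ln, light=light)
                df.insert(1, "light", light)
                counts.append(df)
                k += 1
        pio.write_table(pd.concat(counts, ignore_index=True), inputs / "counts.csv")

    if "photoinhibition" in stages:
        pio.write_table(gen_hl_linc_timecourse(sc, seeds["hl_linc"]),
                        inputs / "fvfm.csv")

    if "proteomics" in stages:
        groups = sc.proteomics.get("groups_measured",
                                   [sc.wild_type] + sc.mutants[:2])
        matrix, _truth = gen_abundance_matrix(sc, seeds["proteomics"], groups=groups)
        pio.write_abundance_matrix(matrix, inputs / "proteome")
    return inputs


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def _analyze_fluorescence(sc: SimScenario, inputs: Path) -> dict[str, pd.DataFrame]:
    rows = []
    traces = {tr.line: tr for tr in pio.read_npq_traces(inputs / "npq_traces.csv")}
    rlc = pio.read_table(inputs / "rlc.csv")
    for ln in sc.lines:
        tc = npq_timecourse(traces[ln])
        fit = fit_light_curve(rlc[rlc["line"] == ln])
        rows.append({
            "line": ln,
            "fv_fm": (traces[ln].Fm - traces[ln].F0) / traces[ln].Fm,
            "alpha": fit.alpha, "retr_max": fit.retr_max, "ek": fit.ek,
            "converged": fit.converged, "unsaturated": fit.unsaturated,
            "npq_end_induction": tc.npq_end_induction,
            "npq_end_relaxation": tc.npq_end_relaxation,
        })
    return {"fluorescence_params": pd.DataFrame(rows)}


def _analyze_ecs(sc: SimScenario, inputs: Path) -> dict[str, pd.DataFrame]:
    rows = []
    for ex in pio.read_ecs_experiments(inputs / "ecs.csv"):
        amp_c = flash_amplitude(deconvolute_wavelengths(ex.flash_control))
        amp_i = flash_amplitude(deconvolute_wavelengths(ex.flash_inhibited))
        stoich = psii_psi_stoichiometry(amp_c.amplitude, amp_i.amplitude)
        flow = electron_flow_rate(deconvolute_wavelengths(ex.light_off),
                                  a_single_charge=amp_i.amplitude)
        rows.append({
            "line": ex.line, "light": ex.light,
            "amp_control": stoich.amp_total,
            "amp_insensitive": stoich.amp_insensitive,
            "psii_psi_ratio": stoich.psii_psi_ratio,
            "flow_e_per_s": flow.flow,
        })
    return {"ecs_results": pd.DataFrame(rows)}


def _analyze_phenotype(sc: SimScenario, inputs: Path) -> dict[str, pd.DataFrame]:
    pig = pio.read_table(inputs / "pigments.csv")
    pig["des"] = des_index(pig["ddx_fmol_per_cell"], pig["dtx_fmol_per_cell"])
    for k in ("fx", "ddx", "dtx"):
        pig[f"{k}_per_chla"] = pig[f"{k}_fmol_per_cell"] / pig["chla_fmol_per_cell"]
    counts = pio.read_table(inputs / "counts.csv")
    rows = []
    for (ln, light), sub in counts.groupby(["line", "light"], sort=False):
        res = division_rates(sub)
        rows.append({"line": ln, "light": light, "mu_max": res.mu_max,
                     "sd": res.sd, "flagged": res.flagged})
    return {"pigments_des": pig, "growth_rates": pd.DataFrame(rows)}


def _pool_mutants(df: pd.DataFrame, mutants: Sequence[str]) -> pd.DataFrame:
    """Treat each (line, replicate) pair of the mutant lines as a replicate."""
    sub = df[df["line"].isin(mutants)].copy()
    sub["replicate"] = sub["line"].astype(str) + "|" + sub["replicate"].astype(str)
    return sub


def _analyze_photoinhibition(sc: SimScenario, inputs: Path) -> dict[str, pd.DataFrame]:
    tc = pio.read_table(inputs / "fvfm.csv")
    wt, mutants = sc.wild_type, sc.mutants
    t_hl = float(sc.photoinhibition.get("t_hl_min", 60.0))
    t_rec = t_hl + float(sc.photoinhibition.get("t_recovery_min", 30.0))
    rows = []
    for name, sub in (("WT", tc[tc["line"] == wt]),
                      ("mutant", _pool_mutants(tc, mutants))):
        hl = normalize_to_initial(sub[sub["arm"] == "HL"])
        linc = normalize_to_initial(sub[sub["arm"] == "HL_LINC"])
        met = repair_recovery_metrics(hl, linc, t_hl=t_hl, t_recovery=t_rec)
        n_rep = sub[sub["arm"] == "HL"].groupby(["line", "replicate"]).ngroups
        rows.append({
            "group": name, "n": n_rep,
            "decline_hl_pct": met.decline_hl_pct,
            "decline_linc_pct": met.decline_linc_pct,
            "repair_protection_pct": met.repair_protection,
            "recovery_pct": met.recovery_pct,
            "recovery_deficit_pct": met.recovery_deficit,
            "k_damage_per_min": photodamage_rate(linc, t_end=t_hl),
        })
    return {"photoinhibition": pd.DataFrame(rows)}


def _analyze_proteomics(sc: SimScenario, inputs: Path,
                        config: RunConfig) -> dict[str, pd.DataFrame]:
    seeds = config.stage_seeds()
    matrix = pio.read_abundance_matrix(inputs / "proteome")
    groups = sc.proteomics.get("groups_measured",
                               [sc.wild_type] + sc.mutants[:2])
    wt, muts = groups[0], list(groups[1:])
    out: dict[str, pd.DataFrame] = {}
    diffs = {}
    for i, g in enumerate(muts):
        prep = preprocess_abundances(matrix, groups=(wt, g))
        res = rots_test(prep.matrix, (g, wt), B=config.rots_B,
                        n_perm=config.rots_n_perm, seed=seeds["rots"] + i)
        tab = res.table.copy()
        tab["log2_ratio"] = log2_group_ratio(prep.matrix, g, wt)
        tab.insert(0, "protein_id", tab.index)
        out[f"proteomics_diff_{i + 1}"] = tab.reset_index(drop=True)
        diffs[g] = tab.set_index("protein_id")
    if len(muts) == 2:
        shared = diffs[muts[0]].index.intersection(diffs[muts[1]].index)
        sel = select_regulated(
            diffs[muts[0]].loc[shared], diffs[muts[1]].loc[shared],
            matrix.annotations, fdr_max=config.fdr_max,
            log2_min=config.log2_min, min_peptides=config.min_peptides)
        sel = sel.copy()
        sel["fold_line1"] = [fold_conversions(x).fold
                             for x in sel["log2_ratio_line1"]]
        sel["percent_of_wt_line1"] = [fold_conversions(x).percent_of_reference
                                      for x in sel["log2_ratio_line1"]]
        sel.insert(0, "protein_id", sel.index)
        out["proteomics_selected"] = sel.reset_index(drop=True)
    return out


def _analyze_inference(sc: SimScenario, inputs: Path,
                       config: RunConfig) -> dict[str, pd.DataFrame]:
    seeds = config.stage_seeds()
    pig = pio.read_table(inputs / "pigments.csv")
    pig["value"] = des_index(pig["ddx_fmol_per_cell"], pig["dtx_fmol_per_cell"])
    pig = pig.rename(columns={"time_h": "time_point"})
    aov = two_way_anova(pig, response="value")
    dun = dunnett_vs_control(
        aov.cell_means, aov.n_per_cell, aov.mse, aov.df_resid,
        control=sc.wild_type, alpha=config.p_max,
        mc_draws=config.dunnett_mc_draws, seed=seeds["dunnett"])
    aov_tab = aov.table.copy()
    aov_tab.insert(0, "factor", aov_tab.index)
    return {"anova_des": aov_tab.reset_index(drop=True), "dunnett_des": dun}


def analyze_inputs(config: RunConfig, inputs: str | Path) -> ReportBundle:
    """Run every enabled analysis stage on serialised inputs."""
    sc = config.resolve_scenario()
    inputs = Path(inputs)
    stages = set(config.stages)
    tables: dict[str, pd.DataFrame] = {}
    if "fluorescence" in stages:
        tables.update(_analyze_fluorescence(sc, inputs))
    if "ecs" in stages:
        tables.update(_analyze_ecs(sc, inputs))
    if "phenotype" in stages:
        tables.update(_analyze_phenotype(sc, inputs))
    if "photoinhibition" in stages:
        tables.update(_analyze_photoinhibition(sc, inputs))
    if "proteomics" in stages:
        tables.update(_analyze_proteomics(sc, inputs, config))
    if "inference" in stages:
        tables.update(_analyze_inference(sc, inputs, config))
    summary = _build_summary(sc, tables)
    manifest = {
        "scenario": sc.name,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": sorted(stages),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return ReportBundle(tables=tables, summary=summary, manifest=manifest)


# ---------------------------------------------------------------------------
# summary & report
# ---------------------------------------------------------------------------


def _build_summary(sc: SimScenario, tables: dict[str, pd.DataFrame]
                   ) -> dict[str, dict[str, float]]:
    """Machine-readable summary keyed by the study's headline quantities."""
    summary: dict[str, dict[str, float]] = {}
    ref = sc.proteomics.get("reference_log2_ratios", {})
    if "PsaC" in ref and "APE1" in ref:
        psac = [fold_conversions(x) for x in ref["PsaC"]]
        ape1 = [fold_conversions(x) for x in ref["APE1"]]
        summary["t1"] = {"value": float(psac[0].percent_floored), "n": 1}
        summary["t2"] = {"value": float(psac[1].percent_floored), "n": 1}
        summary["t3"] = {"value": float(ape1[0].fold_rounded), "n": 1}
        summary["t4"] = {"value": float(ape1[1].fold_rounded), "n": 1}
    if "photoinhibition" in tables:
        pi = tables["photoinhibition"].set_index("group")
        wt_n = int(pi.loc["WT", "n"]); mut_n = int(pi.loc["mutant", "n"])
        summary["t5"] = {"value": float(pi.loc["mutant", "decline_linc_pct"]),
                         "n": mut_n}
        summary["t6"] = {"value": float(pi.loc["WT", "decline_hl_pct"]), "n": wt_n}
        summary["t7"] = {"value": float(pi.loc["mutant", "decline_hl_pct"]),
                         "n": mut_n}
        summary["t8"] = {"value": float(pi.loc["WT", "recovery_pct"]), "n": wt_n}
        summary["t9"] = {"value": float(pi.loc["mutant", "recovery_pct"]),
                         "n": mut_n}
    if "ecs_results" in tables:
        ecs = tables["ecs_results"]
        ml = ecs[ecs["light"] == "ML"]
        wt_flow = ml.loc[ml["line"] == sc.wild_type, "flow_e_per_s"]
        mut_flow = ml.loc[ml["line"] != sc.wild_type, "flow_e_per_s"]
        if len(wt_flow) and len(mut_flow):
            red = 100.0 * (1.0 - mut_flow.mean() / wt_flow.mean())
            summary["t10"] = {"value": float(red),
                              "n": int(len(wt_flow) + len(mut_flow))}
    if "growth_rates" in tables:
        gr = tables["growth_rates"].set_index(["line", "light"])
        for tid, light in (("t11", "LL"), ("t12", "ML")):
            if (sc.wild_type, light) in gr.index:
                summary[tid] = {
                    "value": float(gr.loc[(sc.wild_type, light), "mu_max"]),
                    "n": 3}
    return summary


def write_report(bundle: ReportBundle, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(results / f"{name}.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(bundle.summary, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return outdir


def run_scenario(config: RunConfig) -> ReportBundle:
    """Simulate, analyze and report a full scenario run."""
    inputs = simulate_inputs(config)
    bundle = analyze_inputs(config, inputs)
    write_report(bundle, config.outdir)
    return bundle
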