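"""Synthetic-data generators with known ground truth.

Every dataset the analysis modules consume can be generated here from a
:class:`SimScenario`, together with a truth record holding the exact
noise-free parameter values, so that each estimator in the package can be
validated by parameter recovery.  Generation is deterministic: the same
(scenario, seed) pair yields byte-identical output on any platform
(NumPy ``default_rng`` / PCG64).

The packaged ``cpftsy_study`` scenario encodes the study conditions of a
diatom CpSRP-receptor knockout experiment: per-line growth rates under two
light levels, high-light photoinhibition endpoints with and without a
chloroplast translation inhibitor, a 50 % mutant reduction of the
ML-acclimated photosynthetic electron flow, and reference log2 protein
effects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "SimScenario",
    "TruthRecord",
    "NPQTrace",
    "ECSTraceSet",
    "ECSExperiment",
    "AbundanceMatrix",
    "available_scenarios",
    "load_scenario",
    "line_param",
    "gen_npq_trace",
    "gen_rapid_light_curve",
    "gen_ecs_experiment",
    "gen_pigment_timecourse",
    "gen_count_series",
    "gen_hl_linc_timecourse",
    "gen_abundance_matrix",
]

# Spectral mixing weights used by the forward model.  They are chosen so the
# three-wavelength deconvolution (Cyt c = [554] - 0.4*[520] - 0.4*[563];
# ECS_lin = [520] - 0.25*Cyt c) is their exact inverse.
_W563_ECS = 0.1


class ScenarioError(ValueError):
    """Raised for invalid or unknown simulation scenarios."""


# ---------------------------------------------------------------------------
# scenario handling
# ---------------------------------------------------------------------------


@dataclass
class SimScenario:
    """Complete description of a simulated study: truths, noise, design.

    Sections mirror the assays: ``fluor`` (NPQ protocol), ``rlc`` (rapid
    light curve), ``ecs`` (electrochromic shift), ``pigments``, ``growth``,
    ``photoinhibition`` and ``proteomics``.  Parameters that differ between
    cell lines (or light acclimation states) are nested mappings keyed by
    line name with a ``default`` fallback; :func:`line_param` resolves them.
    """

    name: str
    seed: int
    lines: list[str]
    wild_type: str
    fluor: dict[str, Any]
    rlc: dict[str, Any]
    ecs: dict[str, Any]
    pigments: dict[str, Any]
    growth: dict[str, Any]
    photoinhibition: dict[str, Any]
    proteomics: dict[str, Any]
    mutant_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def mutants(self) -> list[str]:
        if self.mutant_lines:
            return list(self.mutant_lines)
        return [ln for ln in self.lines if ln != self.wild_type]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        def _all_values(x):
            if isinstance(x, Mapping):
                for v in x.values():
                    yield from _all_values(v)
            else:
                yield x

        for section, key in [
            ("fluor", "k_ind"), ("fluor", "k_rel"),
            ("ecs", "k_decay"), ("growth", "mu"),
            ("photoinhibition", "k_damage"), ("photoinhibition", "k_repair"),
            ("photoinhibition", "k_qrelax"),
        ]:
            for v in _all_values(getattr(self, section).get(key, 0.0)):
                if v < 0:
                    raise ScenarioError(
                        f"{section}.{key} must be >= 0, got {v}")
        for section in ("fluor", "rlc", "pigments", "growth", "photoinhibition"):
            for v in _all_values(getattr(self, section).get("noise_cv", 0.0)):
                if not 0.0 <= v < 1.0:
                    raise ScenarioError(
                        f"{section}.noise_cv must be in [0, 1), got {v}")
        steps = np.asarray(self.rlc.get("E_steps", []), dtype=float)
        if steps.size and not np.all(np.diff(steps) > 0):
            raise ScenarioError("rlc.E_steps must be strictly increasing")
        if steps.size and np.any(steps <= 0):
            raise ScenarioError("rlc.E_steps must be positive")
        a1 = self.ecs.get("a1", 1.0)
        if a1 <= 0:
            raise ScenarioError(f"ecs.a1 must be positive, got {a1}")
        pi = self.proteomics.get("pi_diff", 0.0)
        if not 0.0 <= pi <= 1.0:
            raise ScenarioError(f"proteomics.pi_diff must be in [0, 1], got {pi}")
        for line, table in self.pigments.get("means", {}).items():
            for pig, vals in table.items():
                if np.any(np.asarray(vals, dtype=float) < 0):
                    raise ScenarioError(
                        f"pigments.means[{line}][{pig}] has negative entries")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "seed": self.seed,
            "lines": list(self.lines),
            "wild_type": self.wild_type,
            "mutant_lines": list(self.mutant_lines),
            "fluor": copy.deepcopy(self.fluor),
            "rlc": copy.deepcopy(self.rlc),
            "ecs": copy.deepcopy(self.ecs),
            "pigments": copy.deepcopy(self.pigments),
            "growth": copy.deepcopy(self.growth),
            "photoinhibition": copy.deepcopy(self.photoinhibition),
            "proteomics": copy.deepcopy(self.proteomics),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimScenario":
        d = dict(d)
        return cls(
            name=d["name"],
            seed=int(d["seed"]),
            lines=list(d["lines"]),
            wild_type=d["wild_type"],
            mutant_lines=list(d.get("mutant_lines", [])),
            fluor=dict(d.get("fluor", {})),
            rlc=dict(d.get("rlc", {})),
            ecs=dict(d.get("ecs", {})),
            pigments=dict(d.get("pigments", {})),
            growth=dict(d.get("growth", {})),
            photoinhibition=dict(d.get("photoinhibition", {})),
            proteomics=dict(d.get("proteomics", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimScenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def available_scenarios() -> list[str]:
    pkg = resources.files(__package__) / "scenarios"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str | Path) -> SimScenario:
    """Load a packaged scenario by name, or any scenario file by path."""
    path = Path(name)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        return SimScenario.load(path)
    pkg = resources.files(__package__) / "scenarios" / f"{name}.yaml"
    if not pkg.is_file():
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {available_scenarios()}")
    return SimScenario.from_dict(yaml.safe_load(pkg.read_text()))


def line_param(value: Any, line: str, light: str | None = None) -> Any:
    """Resolve a possibly line/light-keyed scenario parameter.

    Scalars pass through; mappings are looked up by line name with a
    ``default`` fallback, then (if still a mapping) by light level.
    """
    if isinstance(value, Mapping):
        if line in value:
            value = value[line]
        elif "default" in value:
            value = value["default"]
        else:
            raise ScenarioError(f"no entry for line {line!r} and no default")
    if isinstance(value, Mapping):
        if light is None or light not in value:
            raise ScenarioError(f"parameter requires a light level, got {light!r}")
        value = value[light]
    return value


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class TruthRecord:
    """Noise-free parameter values emitted alongside a generated dataset."""

    dataset: str
    params: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {"dataset": self.dataset, "params": _plain(self.params)}


def _plain(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays for YAML/JSON sidecars."""
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


@dataclass(eq=False)
class NPQTrace:
    """A saturating-pulse fluorescence trace for one sample.

    ``pulses`` has columns ``time_s, F, Fm_prime, phase, actinic_e`` with
    phases ``dark``/``induction``/``relaxation``; ``F0``/``Fm`` are the
    dark-adapted reference levels.
    """

    F0: float
    Fm: float
    pulses: pd.DataFrame
    line: str = ""
    truth: TruthRecord | None = None


@dataclass(eq=False)
class ECSTraceSet:
    """Aligned absorbance-difference traces at 520/554/563 nm."""

    time_s: np.ndarray
    a520: np.ndarray
    a554: np.ndarray
    a563: np.ndarray
    condition: str  # "control" | "dcmu_ha"
    regime: str     # "flash" | "light_off"
    event_time_s: float
    truth: TruthRecord | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (len(self.a520) == len(self.a554) == len(self.a563) == n):
            raise ValueError("ECS trace series must share one time grid")
        if not (self.time_s[0] <= self.event_time_s <= self.time_s[-1]):
            raise ValueError("event_time_s outside the time grid")


@dataclass(eq=False)
class ECSExperiment:
    """The four trace sets of one ECS session (condition x regime)."""

    line: str
    light: str
    flash_control: ECSTraceSet
    flash_inhibited: ECSTraceSet
    light_off: ECSTraceSet
    truth: TruthRecord | None = None


@dataclass(eq=False)
class AbundanceMatrix:
    """Label-free proteomics abundances with sample groups and annotations.

    ``abundances`` is proteins x samples (non-negative, NaN = missing);
    ``groups`` maps sample id -> group label; ``annotations`` carries
    peptide counts, predicted location and encoding compartment.
    """

    abundances: pd.DataFrame
    groups: pd.Series
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be non-negative where present")
        if not self.abundances.columns.equals(self.groups.index):
            raise ValueError("groups index must match abundance columns")

    def group_columns(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _rng(scenario: SimScenario, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(scenario.seed if seed is None else seed)


def gen_npq_trace(
    scenario: SimScenario, seed: int | None = None, line: str | None = None
) -> NPQTrace:
    """Simulate a dark / induction / relaxation saturating-pulse protocol.

    3 min darkness, 6 min actinic induction and 6 min dim-light relaxation
    with a pulse every 30 s.  The quenching truth is
    ``NPQ(t) = NPQ_max (1 - exp(-k_ind t))`` during induction and
    ``NPQ_end (f_fast exp(-k_rel t) + 1 - f_fast)`` during relaxation, so
    ``Fm'(t) = Fm / (1 + NPQ(t))``.  Multiplicative Gaussian noise with the
    configured CV is applied to F and Fm'.
    """
    p = scenario.fluor
    line = line or scenario.wild_type
    for key in ("k_ind", "k_rel"):
        if line_param(p[key], line) < 0:
            raise ScenarioError(f"fluor.{key} must be >= 0")
    npq_max = float(line_param(p["NPQ_max"], line))
    if npq_max < 0:
        raise ScenarioError("fluor.NPQ_max must be >= 0")
    f0, fm = float(p["F0"]), float(p["Fm"])
    k_ind = float(line_param(p["k_ind"], line))
    k_rel = float(line_param(p["k_rel"], line))
    f_fast = float(line_param(p["f_fast"], line))
    cv = float(p.get("noise_cv", 0.0))
    e_ind = float(p.get("E_induction", 470.0))
    e_rel = float(p.get("E_relaxation", 8.0))

    interval, t_dark, t_ind, t_rel = 30.0, 180.0, 360.0, 360.0
    rows = []
    # dark pre-phase: pulses at -180, -150, ..., 0 s (induction starts at 0)
    for t in np.arange(-t_dark, 0.5, interval):
        rows.append((t, "dark", 0.0, 0.0))
    # induction 0..360 s inclusive
    for t in np.arange(interval, t_ind + 0.5, interval):
        npq = npq_max * (1.0 - np.exp(-k_ind * t))
        rows.append((t, "induction", npq, e_ind))
    npq_end = npq_max * (1.0 - np.exp(-k_ind * t_ind))
    # relaxation 360..720 s
    for t in np.arange(interval, t_rel + 0.5, interval):
        npq = npq_end * (f_fast * np.exp(-k_rel * t) + (1.0 - f_fast))
        rows.append((t_ind + t, "relaxation", npq, e_rel))

    df = pd.DataFrame(rows, columns=["time_s", "phase", "npq_true", "actinic_e"])
    fm_prime = fm / (1.0 + df["npq_true"].to_numpy())
    # a plausible steady-state yield so that F' < Fm' everywhere
    phi = np.where(df["phase"] == "dark", (fm - f0) / fm, 0.3)
    f_prime = fm_prime * (1.0 - phi)
    rng = _rng(scenario, seed)
    if cv > 0:
        fm_prime = fm_prime * (1.0 + cv * rng.standard_normal(len(df)))
        f_prime = f_prime * (1.0 + cv * rng.standard_normal(len(df)))
    out = pd.DataFrame({
        "time_s": df["time_s"],
        "F": f_prime,
        "Fm_prime": fm_prime,
        "phase": df["phase"],
        "actinic_e": df["actinic_e"],
    })
    truth = TruthRecord("npq_trace", {
        "line": line, "F0": f0, "Fm": fm, "NPQ_max": npq_max, "k_ind": k_ind,
        "f_fast": f_fast, "k_rel": k_rel, "noise_cv": cv,
        "npq_end_induction": float(npq_end),
        "npq_end_relaxation": float(
            npq_end * (f_fast * np.exp(-k_rel * t_rel) + 1.0 - f_fast)),
        "npq_series_true": df["npq_true"].to_numpy(),
    })
    return NPQTrace(F0=f0, Fm=fm, pulses=out, line=line, truth=truth)


def webb_retr(e: np.ndarray, alpha: float, retr_max: float) -> np.ndarray:
    """Webb saturating-exponential photosynthesis-irradiance model."""
    e = np.asarray(e, dtype=float)
    return retr_max * (1.0 - np.exp(-alpha * e / retr_max))


def gen_rapid_light_curve(
    scenario: SimScenario, seed: int | None = None, line: str | None = None
) -> pd.DataFrame:
    """Simulate PSII quantum yields along a stepwise irradiance ladder.

    The default 13-step grid spans 4 to 1088 umol photons m-2 s-1.  The
    noise-free yield is ``phi(E) = rETR(E)/E`` under the Webb model, capped
    at the dark-adapted Fv/Fm; noise is multiplicative on phi.  Returns a
    DataFrame with columns ``e_umol_m2_s, phi_psii`` (truth in ``attrs``).
    """
    p = scenario.rlc
    line = line or scenario.wild_type
    steps = np.asarray(p["E_steps"], dtype=float)
    if np.any(steps <= 0):
        raise ScenarioError("E_steps must be positive")
    alpha = float(line_param(p["alpha"], line))
    retr_max = float(line_param(p["rETRmax"], line))
    fvfm = float(line_param(p["FvFm"], line))
    cv = float(p.get("noise_cv", 0.0))
    phi = np.minimum(fvfm, webb_retr(steps, alpha, retr_max) / steps)
    rng = _rng(scenario, seed)
    if cv > 0:
        phi = phi * (1.0 + cv * rng.standard_normal(len(steps)))
    df = pd.DataFrame({"e_umol_m2_s": steps, "phi_psii": phi})
    df.attrs["truth"] = TruthRecord("rapid_light_curve", {
        "line": line, "alpha": alpha, "rETRmax": retr_max, "FvFm": fvfm,
        "Ek": retr_max / alpha, "noise_cv": cv,
    })
    return df


def _mix_wavelengths(
    e: np.ndarray, c: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward spectral mixing whose exact inverse is the deconvolution."""
    n = len(e)
    noise = (noise_sd * rng.standard_normal((3, n))) if noise_sd > 0 else np.zeros((3, n))
    a563 = _W563_ECS * e + noise[0]
    a520 = e + 0.25 * c + noise[1]
    a554 = c + 0.4 * a520 + 0.4 * a563 + noise[2]
    return a520, a554, a563


def gen_ecs_experiment(
    scenario: SimScenario,
    seed: int | None = None,
    line: str | None = None,
    light: str = "ML",
) -> ECSExperiment:
    """Simulate one electrochromic-shift session for a line.

    Produces saturating-flash traces with and without PSII inhibitors
    (DCMU + hydroxylamine) and a continuous-light-to-dark transition:

    * control flash: the field jumps by ``a1 * (1 + PSII:PSI)`` (both
      photosystems fire), then decays exponentially;
    * inhibited flash: the jump is ``a1`` alone (one charge per chain,
      PSI only) -- the single-charge calibration;
    * light off: the linear-ECS component is piecewise linear with slope
      ``drift`` in the light and ``drift - J a1`` after the switch.

    The three wavelengths are mixed so the published deconvolution recovers
    the true (Cyt c, ECS_lin) components exactly in the noise-free limit.
    """
    p = scenario.ecs
    line = line or scenario.wild_type
    a1 = float(p["a1"])
    if a1 <= 0:
        raise ScenarioError("ecs.a1 must be positive")
    ratio = float(line_param(p["psii_psi_ratio"], line, light))
    j_flow = float(line_param(p["J"], line, light))
    k_decay = float(p["k_decay"])
    drift = float(p.get("drift", 0.0))
    noise_sd = float(p.get("noise_sd", 0.0))
    cytc_amp = float(p.get("cytc_amp", 0.0))
    rng = _rng(scenario, seed)

    # flash regime: 50 ms baseline, 300 ms decay, 0.5 ms sampling
    t_flash = np.round(np.arange(-0.050, 0.300, 0.0005), 7)
    def _flash(amp: float) -> ECSTraceSet:
        e = np.where(t_flash >= 0.0, amp * np.exp(-k_decay * np.maximum(t_flash, 0.0)), 0.0)
        c = np.where(t_flash >= 0.0, cytc_amp * np.exp(-2.0 * np.maximum(t_flash, 0.0)), 0.0)
        a520, a554, a563 = _mix_wavelengths(e, c, rng, noise_sd)
        return ECSTraceSet(t_flash, a520, a554, a563,
                           condition="", regime="flash", event_time_s=0.0)

    fc = _flash(a1 * (1.0 + ratio)); fc.condition = "control"
    fi = _flash(a1); fi.condition = "dcmu_ha"

    # light-off regime: 0.5 s each side of the switch, 1 ms sampling
    t_off = np.round(np.arange(-0.500, 0.500, 0.001), 7)
    e_off = np.where(
        t_off < 0.0, drift * t_off,
        (drift - j_flow * a1) * t_off)
    c_off = np.zeros_like(t_off)
    a520, a554, a563 = _mix_wavelengths(e_off, c_off, rng, noise_sd)
    lo = ECSTraceSet(t_off, a520, a554, a563,
                     condition="control", regime="light_off", event_time_s=0.0)

    truth = TruthRecord("ecs_experiment", {
        "line": line, "light": light, "a1": a1, "psii_psi_ratio": ratio,
        "J": j_flow, "k_decay": k_decay, "drift": drift, "noise_sd": noise_sd,
        "cytc_amp": cytc_amp,
        "flash_amp_control": a1 * (1.0 + ratio),
        "flash_amp_inhibited": a1,
        "slope_light": drift, "slope_dark": drift - j_flow * a1,
    })
    for ts in (fc, fi, lo):
        ts.truth = truth
    return ECSExperiment(line=line, light=light, flash_control=fc,
                         flash_inhibited=fi, light_off=lo, truth=truth)


def gen_pigment_timecourse(
    scenario: SimScenario, seed: int | None = None
) -> pd.DataFrame:
    """Simulate per-cell pigment amounts over the low-to-medium light shift.

    Three replicates per line x time (0, 0.5, 6, 24, 168 h; 0 h =
    LL-acclimated) with lognormal multiplicative noise at the configured CV.
    Returns a tidy DataFrame (line, time_h, replicate, four pigments in
    fmol per cell) with the truth table in ``attrs``.
    """
    p = scenario.pigments
    times = np.asarray(p["times_h"], dtype=float)
    cv = float(p.get("noise_cv", 0.0))
    n_rep = int(p.get("n_replicates", 3))
    rng = _rng(scenario, seed)
    sigma = np.sqrt(np.log1p(cv**2))  # lognormal with unit mean, sd ~ cv
    rows = []
    for line, table in p["means"].items():
        for j, t in enumerate(times):
            for r in range(1, n_rep + 1):
                row = {"line": line, "time_h": t, "replicate": r}
                for pig in ("chla", "fx", "ddx", "dtx"):
                    mean = float(table[pig][j])
                    if mean < 0:
                        raise ScenarioError("pigment means must be >= 0")
                    noise = (np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                             if cv > 0 else 1.0)
                    row[f"{pig}_fmol_per_cell"] = mean * noise
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["truth"] = TruthRecord("pigment_timecourse", {
        "times_h": times, "noise_cv": cv, "n_replicates": n_rep,
        "means": copy.deepcopy(p["means"]),
    })
    return df


def gen_count_series(
    scenario: SimScenario,
    seed: int | None = None,
    line: str | None = None,
    light: str = "LL",
) -> pd.DataFrame:
    """Simulate replicate cell-count series for one line and light level.

    ``N(t) = N0 * 2**(mu (t - lag))`` inside the exponential window, with an
    optional lag phase and a logistic cap at the carrying capacity, and
    lognormal multiplicative noise.  Returns a tidy DataFrame
    (line, replicate, time_d, cells_per_ml) with truth in ``attrs``.
    """
    p = scenario.growth
    line = line or scenario.wild_type
    mu = float(line_param(p["mu"], line, light))
    if mu < 0:
        raise ScenarioError("growth.mu must be >= 0")
    n0 = float(p.get("N0", 1e5))
    days = int(p.get("days", 3))
    cv = float(p.get("noise_cv", 0.0))
    n_rep = int(p.get("n_replicates", 3))
    lag = float(p.get("lag_days", 0.0))
    cap = float(p.get("carrying_capacity", np.inf))
    rng = _rng(scenario, seed)
    t = np.arange(0.0, days + 0.5, 1.0)
    growth_t = np.maximum(t - lag, 0.0)
    n_true = n0 * 2.0 ** (mu * growth_t)
    if np.isfinite(cap):  # ceiling at the carrying capacity; the window
        n_true = np.minimum(n_true, cap)  # below it stays purely exponential
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for r in range(1, n_rep + 1):
        noise = (np.exp(sigma * rng.standard_normal(len(t)) - sigma**2 / 2)
                 if cv > 0 else np.ones(len(t)))
        for ti, ni in zip(t, n_true * noise):
            rows.append({"line": line, "replicate": r,
                         "time_d": ti, "cells_per_ml": ni})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = TruthRecord("count_series", {
        "line": line, "light": light, "mu": mu, "N0": n0, "lag_days": lag,
        "carrying_capacity": cap, "noise_cv": cv, "n_true": n_true,
    })
    return df


def _damage_fraction(t: np.ndarray, kd: float, kr: float) -> np.ndarray:
    """Two-state (intact/damaged) first-order balance during the HL phase."""
    k = kd + kr
    if k == 0:
        return np.zeros_like(t)
    return (kd / k) * (1.0 - np.exp(-k * t))


def gen_hl_linc_timecourse(
    scenario: SimScenario,
    seed: int | None = None,
    lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate the high-light +/- lincomycin Fv/Fm time courses.

    Two arms per line: ``HL`` (repair active) and ``HL_LINC`` (chloroplast
    translation blocked, so no repair).  During the 60-min HL phase the
    damaged fraction follows ``dD/dt = k_damage (1 - D) - k_repair D``; in
    the 30-min dim recovery ``k_damage = 0`` and repair continues in the
    no-inhibitor arm only.  Measured relative Fv/Fm is ``(1 - D)(1 - q)``
    where q is a sustained-quenching term that builds during HL and relaxes
    toward ``q_res`` in dim light.  In the +LINC arm q is folded into the
    damage constant so the decline is the pure exponential
    ``exp(-k_damage t)`` (see docs/methods.md).
    """
    p = scenario.photoinhibition
    lines = list(lines) if lines is not None else list(scenario.lines)
    kd = float(p["k_damage"])
    k_qind = float(p.get("k_qind", 0.2))
    k_qrelax = float(p["k_qrelax"])
    for v in (kd, k_qind, k_qrelax):
        if v < 0:
            raise ScenarioError("photoinhibition rate constants must be >= 0")
    cv = float(p.get("noise_cv", 0.0))
    n_rep = int(p.get("n_replicates", 3))
    t_hl = float(p.get("t_hl_min", 60.0))
    t_rec = float(p.get("t_recovery_min", 30.0))
    dt = float(p.get("dt_min", 10.0))
    fvfm0 = float(p.get("fvfm_initial", 0.65))
    t_grid = np.round(np.arange(0.0, t_hl + t_rec + dt / 2, dt), 9)
    rng = _rng(scenario, seed)

    rows, truth_curves = [], {}
    for line in lines:
        kr = float(line_param(p["k_repair"], line))
        q_hl = float(line_param(p["q_hl"], line))
        q_res = float(line_param(p["q_res"], line))
        if kr < 0:
            raise ScenarioError("photoinhibition.k_repair must be >= 0")
        for arm in ("HL", "HL_LINC"):
            kr_arm = 0.0 if arm == "HL_LINC" else kr
            rel = np.empty_like(t_grid)
            hl_mask = t_grid <= t_hl
            t1 = t_grid[hl_mask]
            d1 = _damage_fraction(t1, kd, kr_arm)
            if arm == "HL_LINC":
                q1 = np.zeros_like(t1)
            else:
                scale = 1.0 - np.exp(-k_qind * t_hl)
                q1 = q_hl * (1.0 - np.exp(-k_qind * t1)) / scale
            rel[hl_mask] = (1.0 - d1) * (1.0 - q1)
            t2 = t_grid[~hl_mask] - t_hl
            d_end = _damage_fraction(np.array([t_hl]), kd, kr_arm)[0]
            q_end = 0.0 if arm == "HL_LINC" else q_hl
            d2 = d_end * np.exp(-kr_arm * t2)  # damage stays put under LINC
            q2 = q_res + (q_end - q_res) * np.exp(-k_qrelax * t2)
            if arm == "HL_LINC":
                q2 = np.zeros_like(t2)
            rel[~hl_mask] = (1.0 - d2) * (1.0 - q2)
            truth_curves[(line, arm)] = rel.copy()
            for r in range(1, n_rep + 1):
                noise = (1.0 + cv * rng.standard_normal(len(t_grid))
                         if cv > 0 else np.ones(len(t_grid)))
                for ti, vi in zip(t_grid, fvfm0 * rel * noise):
                    rows.append({"line": line, "arm": arm, "replicate": r,
                                 "time_min": ti, "fv_fm": vi})
    df = pd.DataFrame(rows)
    df.attrs["truth"] = TruthRecord("hl_linc_timecourse", {
        "k_damage": kd, "k_qind": k_qind, "k_qrelax": k_qrelax,
        "noise_cv": cv, "n_replicates": n_rep, "fvfm_initial": fvfm0,
        "t_grid_min": t_grid,
        "relative_curves": {f"{ln}|{arm}": v for (ln, arm), v in truth_curves.items()},
    })
    return df


def gen_abundance_matrix(
    scenario: SimScenario,
    seed: int | None = None,
    groups: Sequence[str] | None = None,
) -> tuple[AbundanceMatrix, TruthRecord]:
    """Simulate a label-free protein abundance matrix with known effects.

    Per-protein baseline log2 abundances are Normal(mu0, sigma_protein); a
    fraction ``pi_diff`` of proteins carry a log2 group effect (uniform
    magnitude in [effect_min, effect_max], sign up with probability
    ``p_up``, same sign in every mutant group with probability
    ``concordance``).  Replicate noise is Normal(0, sigma_rep) on the log2
    scale.  Missingness combines MCAR (probability ``mcar_p``) with
    intensity-dependent MNAR via a logistic in the true log2 abundance.
    Peptide counts are ``1 + Poisson(lambda)``.
    """
    p = scenario.proteomics
    pi_diff = float(p.get("pi_diff", 0.0))
    if not 0.0 <= pi_diff <= 1.0:
        raise ScenarioError("proteomics.pi_diff must be in [0, 1]")
    n_prot = int(p.get("n_prot", 1000))
    n_rep = int(p.get("n_rep", 5))
    sigma_p = float(p.get("sigma_protein", 1.5))
    sigma_r = float(p.get("sigma_rep", 0.25))
    mu0 = float(p.get("mu0", 20.0))
    mcar = float(p.get("mcar_p", 0.0))
    mnar_mid = float(p.get("mnar_mid", -np.inf))
    mnar_slope = float(p.get("mnar_slope", 1.0))
    lam = float(p.get("peptide_lambda", 6.0))
    eff_lo = float(p.get("effect_min", 0.5))
    eff_hi = float(p.get("effect_max", 2.5))
    p_up = float(p.get("p_up", 0.5))
    concord = float(p.get("concordance", 1.0))
    if groups is None:
        groups = [scenario.wild_type] + scenario.mutants[:2]
    groups = list(groups)
    wt = groups[0]
    rng = _rng(scenario, seed)

    ids = [f"P{i:05d}" for i in range(1, n_prot + 1)]
    baseline = mu0 + sigma_p * rng.standard_normal(n_prot)
    is_diff = rng.random(n_prot) < pi_diff
    magnitude = rng.uniform(eff_lo, eff_hi, n_prot)
    sign = np.where(rng.random(n_prot) < p_up, 1.0, -1.0)
    effects = {wt: np.zeros(n_prot)}
    for g in groups[1:]:
        flip = np.where(rng.random(n_prot) < concord, 1.0, -1.0)
        jitter = rng.uniform(0.8, 1.2, n_prot)  # per-line magnitude wobble
        effects[g] = np.where(is_diff, sign * flip * magnitude * jitter, 0.0)

    cols, data, grp_labels = [], [], []
    for g in groups:
        for r in range(1, n_rep + 1):
            cols.append(f"{g}_r{r}")
            grp_labels.append(g)
            log2_true = baseline + effects[g]
            obs = log2_true + sigma_r * rng.standard_normal(n_prot)
            miss = rng.random(n_prot) < mcar
            if np.isfinite(mnar_mid):
                p_mnar = expit(mnar_slope * (mnar_mid - log2_true))
                miss |= rng.random(n_prot) < p_mnar
            vals = np.where(miss, np.nan, 2.0 ** obs)
            data.append(vals)
    abund = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    peptides = 1 + rng.poisson(lam, n_prot)
    annotations = pd.DataFrame({
        "description": [f"synthetic protein {i}" for i in ids],
        "location": rng.choice(["Cp", "TM", "S", "CpM", "other"], n_prot),
        "encoded": rng.choice(["N", "Cp"], n_prot, p=[0.9, 0.1]),
        "peptides": peptides,
        "unique_peptides": np.maximum(1, peptides - rng.poisson(0.5, n_prot)),
    }, index=ids)
    matrix = AbundanceMatrix(
        abundances=abund,
        groups=pd.Series(grp_labels, index=cols, name="group"),
        annotations=annotations,
    )
    truth = TruthRecord("abundance_matrix", {
        "groups": groups, "n_prot": n_prot, "n_rep": n_rep,
        "pi_diff": pi_diff, "sigma_protein": sigma_p, "sigma_rep": sigma_r,
        "is_diff": is_diff,
        "true_log2_effects": {g: effects[g] for g in groups[1:]},
    })
    return matrix, truth
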