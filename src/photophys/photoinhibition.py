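"""Photodamage / repair decomposition of high-light Fv/Fm time courses.

Cells are exposed to high light (HL) for an hour and then allowed to relax
in very dim light for 30 min, with and without lincomycin (LINC), an
inhibitor of chloroplast translation.  Because PSII repair requires de novo
chloroplast protein synthesis, the +LINC arm isolates photodamage: its
Fv/Fm decline follows a first-order (Kok-type) loss of intact centres, and
the rate constant is estimated from a log-linear fit through the origin.
Comparing the two arms at the end of HL quantifies how much decline repair
prevented, and the dim-light endpoint quantifies recovery once fast
quenching has relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_to_initial",
    "photodamage_rate",
    "RepairRecoveryMetrics",
    "repair_recovery_metrics",
]

_COLS = {"replicate", "time_min", "fv_fm"}


def normalize_to_initial(tc: pd.DataFrame) -> pd.DataFrame:
    """Express each replicate's Fv/Fm as percent of its t = 0 value.

    Returns the input with an added ``rel_pct`` column.  Raises if any
    replicate lacks a pre-treatment (t = 0) measurement.
    """
    if not _COLS.issubset(tc.columns):
        raise ValueError(f"time course needs columns {sorted(_COLS)}")
    keys = [c for c in ("line", "arm", "replicate") if c in tc.columns]
    out = []
    for key, sub in tc.groupby(keys, sort=False):
        sub = sub.sort_values("time_min").copy()
        at0 = sub.loc[sub["time_min"] == 0.0, "fv_fm"]
        if at0.empty:
            raise ValueError(f"replicate {key}: missing t = 0 measurement")
        v0 = float(at0.iloc[0])
        if v0 <= 0:
            raise ValueError(f"replicate {key}: non-positive initial Fv/Fm")
        sub["rel_pct"] = 100.0 * sub["fv_fm"] / v0
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def photodamage_rate(linc_norm: pd.DataFrame, t_end: float = 60.0) -> float:
    """Photodamage rate constant (per minute) from the +LINC arm.

    Fits ``ln(rel(t)) = -k t`` through the origin by least squares over the
    HL phase (0 < t <= ``t_end``), pooling replicates; with a single time
    point this reduces to ``k = -ln(rel(t_end)) / t_end``.
    """
    if "arm" in linc_norm.columns:
        arms = set(linc_norm["arm"].unique())
        if arms - {"HL_LINC"}:
            raise ValueError(f"expected only the HL_LINC arm, got {sorted(arms)}")
    if "rel_pct" not in linc_norm.columns:
        linc_norm = normalize_to_initial(linc_norm)
    sub = linc_norm[(linc_norm["time_min"] > 0) & (linc_norm["time_min"] <= t_end)]
    if sub.empty:
        raise ValueError("no time points in (0, t_end]")
    rel = sub["rel_pct"].to_numpy(dtype=float) / 100.0
    if np.any(rel <= 0):
        raise ValueError("relative Fv/Fm must stay positive for a log fit")
    t = sub["time_min"].to_numpy(dtype=float)
    # least squares through the origin: ln(rel) = -k t
    return float(-np.dot(t, np.log(rel)) / np.dot(t, t))


@dataclass
class RepairRecoveryMetrics:
    """End-point percentages separating photodamage from repair.

    All values are percent of the initial Fv/Fm (replicate means; ``sd_*``
    give replicate dispersion).  ``repair_protection`` is the percentage-
    point gap at the end of HL between the repair-competent and the
    translation-blocked arm -- the decline repair prevented.
    """

    decline_hl_pct: float     # -LINC arm at the end of HL
    decline_linc_pct: float   # +LINC arm at the end of HL
    recovery_pct: float       # -LINC arm after dim-light recovery
    sd_hl: float
    sd_linc: float
    sd_recovery: float

    @property
    def repair_protection(self) -> float:
        return self.decline_hl_pct - self.decline_linc_pct

    @property
    def recovery_deficit(self) -> float:
        return 100.0 - self.recovery_pct


def _endpoint(norm: pd.DataFrame, t: float) -> tuple[float, float]:
    at = norm[np.isclose(norm["time_min"].to_numpy(dtype=float), t)]
    if at.empty:
        raise ValueError(f"missing measurement at t = {t:g} min")
    vals = at.groupby("replicate")["rel_pct"].mean()
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def repair_recovery_metrics(
    hl_norm: pd.DataFrame,
    linc_norm: pd.DataFrame,
    t_hl: float = 60.0,
    t_recovery: float = 90.0,
) -> RepairRecoveryMetrics:
    """End-point comparison of the HL and HL+LINC arms.

    Requires both normalised arms to contain the end-of-HL point; the
    recovery point is needed in the no-inhibitor arm only.
    """
    for df, name in ((hl_norm, "HL arm"), (linc_norm, "HL_LINC arm")):
        if "rel_pct" not in df.columns:
            raise ValueError(f"{name}: normalise with normalize_to_initial first")
    hl60, sd_hl = _endpoint(hl_norm, t_hl)
    linc60, sd_linc = _endpoint(linc_norm, t_hl)
    rec, sd_rec = _endpoint(hl_norm, t_recovery)
    return RepairRecoveryMetrics(
        decline_hl_pct=hl60, decline_linc_pct=linc60, recovery_pct=rec,
        sd_hl=sd_hl, sd_linc=sd_linc, sd_recovery=sd_rec,
    )
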