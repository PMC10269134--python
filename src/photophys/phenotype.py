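"""Pigment metrics and growth-rate estimation.

Pigment amounts arrive as femtomoles per cell; the de-epoxidation state of
the diatom xanthophyll cycle is ``DES = Dtx / (Dtx + Ddx)`` and pigment
ratios are reported per chlorophyll a.  Cell-count series are reduced to
maximum cell divisions per day (log2 units) by detecting the exponential
phase with a sliding log-linear fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "pigment_per_cell",
    "des_index",
    "pigment_ratio_per_chla",
    "DivisionRates",
    "division_rates",
]


def pigment_per_cell(pigment_amount_fmol, cell_count):
    """Per-cell pigment amount (fmol per cell)."""
    amount = np.asarray(pigment_amount_fmol, dtype=float)
    cells = np.asarray(cell_count, dtype=float)
    if np.any(cells <= 0):
        raise ValueError("cell_count must be positive")
    out = amount / cells
    return float(out) if out.ndim == 0 else out


def des_index(ddx, dtx):
    """Xanthophyll-cycle de-epoxidation state, ``Dtx / (Dtx + Ddx)``.

    Returns NaN with a warning where both pigments are zero (undefined).
    """
    ddx = np.asarray(ddx, dtype=float)
    dtx = np.asarray(dtx, dtype=float)
    if np.any(ddx < 0) or np.any(dtx < 0):
        raise ValueError("pigment amounts must be >= 0")
    total = ddx + dtx
    zero = total == 0
    if np.any(zero):
        warnings.warn("DES undefined where Ddx + Dtx == 0; returning NaN",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, np.nan, dtx / np.where(zero, np.nan, total))
    return float(out) if out.ndim == 0 else out


def pigment_ratio_per_chla(record) -> dict[str, float]:
    """Fx, Ddx and Dtx per chlorophyll a for one pigment record.

    Accepts a mapping or DataFrame row with keys ``chla, fx, ddx, dtx``
    (``*_fmol_per_cell`` suffixes also accepted).
    """
    def _get(key):
        for k in (key, f"{key}_fmol_per_cell"):
            if k in record:
                return float(record[k])
        raise KeyError(key)
    chla = _get("chla")
    if chla <= 0:
        raise ValueError("chla must be positive")
    return {f"{k}_per_chla": _get(k) / chla for k in ("fx", "ddx", "dtx")}


@dataclass
class DivisionRates:
    """Division-rate estimates for one line's count series."""

    mu_max: float                       # divisions per day, mean over replicates
    per_replicate: pd.DataFrame         # replicate, mu_max, r2, t_start, t_end, flagged
    per_interval: pd.DataFrame          # replicate, t_start, t_end, rate
    window_min_points: int = 3
    r2_min: float = 0.99
    flagged: bool = False               # True if any replicate missed r2_min

    @property
    def sd(self) -> float:
        return float(self.per_replicate["mu_max"].std(ddof=1))


def _window_fit(t: np.ndarray, log2n: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of a log2-linear fit (R^2 := 1 for a 2-point window)."""
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    slope = float(np.dot(tc, log2n - log2n.mean()) / denom)
    pred = log2n.mean() + slope * tc
    ss_tot = float(np.sum((log2n - log2n.mean()) ** 2))
    if ss_tot == 0 or len(t) == 2:
        return slope, 1.0
    ss_res = float(np.sum((log2n - pred) ** 2))
    return slope, 1.0 - ss_res / ss_tot


def division_rates(
    series: pd.DataFrame,
    window_min_points: int = 3,
    r2_min: float = 0.99,
) -> DivisionRates:
    """Maximum cell divisions per day from replicate count series.

    The exponential phase is detected per replicate as the contiguous
    sliding window (length >= ``window_min_points``) that maximises the
    slope of log2(counts) versus time subject to fit R^2 >= ``r2_min``;
    that slope, in log2 units, is divisions per day.  The line-level value
    is the mean over replicates.  If no window of a replicate reaches the
    R^2 floor, the best-R^2 window is used and the result flagged.

    Successive-interval rates ``log2(N_{i+1}/N_i) / dt`` are also reported.
    """
    df = series
    need = {"replicate", "time_d", "cells_per_ml"}
    if not need.issubset(df.columns):
        raise ValueError(f"count series needs columns {sorted(need)}")
    if np.any(df["cells_per_ml"].to_numpy(dtype=float) <= 0):
        raise ValueError("cells_per_ml must be positive")

    rep_rows, int_rows = [], []
    for rep, sub in df.groupby("replicate"):
        sub = sub.sort_values("time_d")
        t = sub["time_d"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"replicate {rep}: time must be strictly increasing")
        if len(t) < window_min_points:
            raise ValueError(
                f"replicate {rep}: fewer than {window_min_points} samples")
        y = np.log2(sub["cells_per_ml"].to_numpy(dtype=float))
        for i in range(len(t) - 1):
            int_rows.append({
                "replicate": rep, "t_start": t[i], "t_end": t[i + 1],
                "rate": (y[i + 1] - y[i]) / (t[i + 1] - t[i]),
            })
        best = None          # best admissible (max slope among R2 >= floor)
        best_any = None      # fallback: best R2 overall
        for w in range(window_min_points, len(t) + 1):
            for i in range(len(t) - w + 1):
                slope, r2 = _window_fit(t[i:i + w], y[i:i + w])
                cand = (slope, r2, t[i], t[i + w - 1])
                if r2 >= r2_min and (best is None or slope > best[0]):
                    best = cand
                if best_any is None or r2 > best_any[1]:
                    best_any = cand
        flagged = best is None
        slope, r2, t0, t1 = best if best is not None else best_any
        rep_rows.append({"replicate": rep, "mu_max": slope, "r2": r2,
                         "t_start": t0, "t_end": t1, "flagged": flagged})

    per_rep = pd.DataFrame(rep_rows)
    return DivisionRates(
        mu_max=float(per_rep["mu_max"].mean()),
        per_replicate=per_rep,
        per_interval=pd.DataFrame(int_rows),
        window_min_points=window_min_points,
        r2_min=r2_min,
        flagged=bool(per_rep["flagged"].any()),
    )
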