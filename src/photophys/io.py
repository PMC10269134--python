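"""Plain-text tabular I/O for every dataset the pipeline consumes.

All schemas are CSV/TSV with header rows and units baked into the column
names (``time_s``, ``e_umol_m2_s``, ``delta_a``, ``*_fmol_per_cell``,
``time_d``, ``time_min``).  Time conventions are fixed per schema: seconds
for optical traces, minutes for photoinhibition, hours for pigment time
courses, days for growth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import AbundanceMatrix, ECSTraceSet, NPQTrace

__all__ = [
    "write_npq_traces", "read_npq_traces",
    "write_ecs_experiments", "read_ecs_experiments",
    "write_abundance_matrix", "read_abundance_matrix",
    "write_table", "read_table",
]

FLUOR_COLUMNS = ["line", "time_s", "F", "Fm_prime", "phase", "actinic_e", "f0", "fm"]
ECS_COLUMNS = ["sample_id", "line", "light", "condition", "regime",
               "event_time_s", "time_s", "wavelength_nm", "delta_a"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips IEEE doubles exactly, keeping analyze-on-disk
    # bit-identical to the in-memory pipeline
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    return pd.read_csv(path, float_precision="round_trip")


# -- fluorescence ----------------------------------------------------------


def write_npq_traces(traces: list[NPQTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        df = tr.pulses.copy()
        df.insert(0, "line", tr.line)
        df["f0"] = tr.F0
        df["fm"] = tr.Fm
        frames.append(df[FLUOR_COLUMNS])
    write_table(pd.concat(frames, ignore_index=True), path)


def read_npq_traces(path: str | Path) -> list[NPQTrace]:
    df = read_table(path)
    for col in ("time_s", "F", "Fm_prime", "actinic_e"):
        df[col] = df[col].astype(float)
    traces = []
    for line, sub in df.groupby("line", sort=False):
        traces.append(NPQTrace(
            F0=float(sub["f0"].iloc[0]),
            Fm=float(sub["fm"].iloc[0]),
            pulses=sub[["time_s", "F", "Fm_prime", "phase", "actinic_e"]]
            .reset_index(drop=True),
            line=str(line),
        ))
    return traces


# -- electrochromic shift --------------------------------------------------


def _traceset_rows(ts: ECSTraceSet, sample_id: str, line: str, light: str):
    for wl, series in ((520, ts.a520), (554, ts.a554), (563, ts.a563)):
        yield pd.DataFrame({
            "sample_id": sample_id, "line": line, "light": light,
            "condition": ts.condition, "regime": ts.regime,
            "event_time_s": ts.event_time_s,
            "time_s": ts.time_s, "wavelength_nm": wl, "delta_a": series,
        })


def write_ecs_experiments(experiments: list, path: str | Path) -> None:
    """Long-format ECS CSV: one row per (sample, wavelength, time)."""
    frames = []
    for i, ex in enumerate(experiments):
        sid = f"{ex.line}|{ex.light}|{i}"
        for ts in (ex.flash_control, ex.flash_inhibited, ex.light_off):
            frames.extend(_traceset_rows(ts, sid, ex.line, ex.light))
    write_table(pd.concat(frames, ignore_index=True)[ECS_COLUMNS], path)


def read_ecs_experiments(path: str | Path) -> list:
    """Reconstruct :class:`~photophys.simulate.ECSExperiment` objects."""
    from .simulate import ECSExperiment

    df = read_table(path)
    for col in ("time_s", "delta_a", "event_time_s"):
        df[col] = df[col].astype(float)
    out = []
    for sid, sub in df.groupby("sample_id", sort=False):
        parts = {}
        for (cond, regime), block in sub.groupby(["condition", "regime"], sort=False):
            wide = block.pivot_table(index="time_s", columns="wavelength_nm",
                                     values="delta_a", sort=True)
            parts[(cond, regime)] = ECSTraceSet(
                time_s=wide.index.to_numpy(dtype=float),
                a520=wide[520].to_numpy(), a554=wide[554].to_numpy(),
                a563=wide[563].to_numpy(),
                condition=cond, regime=regime,
                event_time_s=float(block["event_time_s"].iloc[0]),
            )
        out.append(ECSExperiment(
            line=str(sub["line"].iloc[0]), light=str(sub["light"].iloc[0]),
            flash_control=parts[("control", "flash")],
            flash_inhibited=parts[("dcmu_ha", "flash")],
            light_off=parts[("control", "light_off")],
        ))
    return out


# -- proteomics ------------------------------------------------------------


def write_abundance_matrix(matrix: AbundanceMatrix, prefix: str | Path) -> None:
    """Write the TSV trio: abundances, sample sheet, protein annotations."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    matrix.abundances.rename_axis("protein_id").to_csv(
        f"{prefix}_abundances.tsv", sep="\t", float_format="%.17g")
    matrix.groups.rename_axis("sample_id").to_frame().to_csv(
        f"{prefix}_samples.tsv", sep="\t")
    matrix.annotations.rename_axis("protein_id").to_csv(
        f"{prefix}_annotations.tsv", sep="\t")


def read_abundance_matrix(prefix: str | Path) -> AbundanceMatrix:
    prefix = Path(prefix)
    for suffix in ("abundances", "samples", "annotations"):
        if not Path(f"{prefix}_{suffix}.tsv").exists():
            raise FileNotFoundError(f"missing input file: {prefix}_{suffix}.tsv")
    ab = pd.read_csv(f"{prefix}_abundances.tsv", sep="\t", index_col="protein_id",
                     float_precision="round_trip").rename_axis(None)
    samples = pd.read_csv(f"{prefix}_samples.tsv", sep="\t",
                          index_col="sample_id").rename_axis(None)
    ann = pd.read_csv(f"{prefix}_annotations.tsv", sep="\t",
                      index_col="protein_id").rename_axis(None)
    return AbundanceMatrix(abundances=ab, groups=samples["group"], annotations=ann)
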