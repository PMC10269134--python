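"""Label-free proteomics differential abundance with a reproducibility-
optimised test statistic (ROTS).

The workflow mirrors a two-group (mutant versus wild type) comparison of
normalised protein abundances:

1. :func:`preprocess_abundances` -- drop proteins missing in two or more
   replicates of either comparison group, then scale sample columns so
   their totals over commonly observed proteins agree;
2. :func:`log2_group_ratio` -- per-protein log2 ratio of group means;
3. :class:`ROTSModel` / :func:`rots_test` -- the ROTS statistic
   ``d = |x1 - x2| / (a1 + a2 * s)`` on log2 abundances, where ``s`` is the
   pooled-variance standard error (so ``(a1, a2) = (0, 1)`` is the ordinary
   t statistic and ``(1, 0)`` the plain mean difference).  The
   regularisation ``(a1, a2)`` and a top-list size ``k`` are chosen to
   maximise the reproducibility Z-score: the bootstrap overlap of top-k
   lists, in excess of the same overlap under group-label permutation,
   scaled by its bootstrap spread.  P-values and false discovery rates come
   from a pooled permutation null of the selected statistic;
4. :func:`select_regulated` -- the table filter requiring concordant
   significant regulation in two mutant lines;
5. :func:`fold_conversions` -- log2 ratio to fold change / percent of the
   reference, with the floored / rounded presentation forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import AbundanceMatrix

__all__ = [
    "PreprocessResult",
    "preprocess_abundances",
    "log2_group_ratio",
    "ROTSModel",
    "ROTSResults",
    "rots_test",
    "select_regulated",
    "FoldConversion",
    "fold_conversions",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass
class PreprocessResult:
    matrix: AbundanceMatrix
    dropped: list[str]
    scale_factors: pd.Series


def preprocess_abundances(
    matrix: AbundanceMatrix,
    groups: Sequence[str] | None = None,
    na_rule: str = "per_group",
    max_missing: int = 1,
) -> PreprocessResult:
    """Missingness filtering and total-abundance column normalisation.

    With ``na_rule="per_group"`` (the strict reading, default) a protein is
    dropped when more than ``max_missing`` replicates are missing in either
    group of the comparison; ``na_rule="total"`` applies the threshold of
    two-or-more missing to the row across all retained samples.  After
    filtering, each sample column is scaled so that its total over the
    commonly observed proteins (rows complete in every sample) equals the
    grand mean of those raw totals; the operation is idempotent.
    """
    ab = matrix.abundances
    grp = matrix.groups
    if groups is not None:
        cols = [c for c in ab.columns if grp[c] in set(groups)]
        if not cols:
            raise ValueError(f"no samples for groups {list(groups)}")
        ab = ab[cols]
        grp = grp[cols]
    for g, sub in ab.T.groupby(grp):
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if ab.isna().all(axis=0).any():
        bad = list(ab.columns[ab.isna().all(axis=0)])
        raise ValueError(f"all-missing sample column(s): {bad}")

    if na_rule == "per_group":
        keep = pd.Series(True, index=ab.index)
        for g in grp.unique():
            n_miss = ab[grp.index[grp == g]].isna().sum(axis=1)
            keep &= n_miss <= max_missing
    elif na_rule == "total":
        keep = ab.isna().sum(axis=1) <= max_missing
    else:
        raise ValueError(f"unknown na_rule {na_rule!r}")
    dropped = list(ab.index[~keep])
    ab = ab.loc[keep]

    common = ab.dropna().index  # proteins observed in every retained sample
    if len(common) == 0:
        raise ValueError("no commonly observed proteins to normalise on")
    totals = ab.loc[common].sum(axis=0)
    target = float(totals.mean())
    factors = target / totals
    ab = ab * factors
    out = AbundanceMatrix(
        abundances=ab,
        groups=grp.copy(),
        annotations=matrix.annotations.loc[ab.index].copy(),
    )
    return PreprocessResult(matrix=out, dropped=dropped, scale_factors=factors)


def log2_group_ratio(
    matrix: AbundanceMatrix,
    mutant_group: str,
    wt_group: str,
    method: str = "ratio_of_means",
) -> pd.Series:
    """Per-protein log2 ratio of mutant over wild-type abundance.

    Default is the log2 of the ratio of arithmetic group means over
    observed values (how proteome-platform ratio tables are typically
    produced); ``method="mean_of_logs"`` averages per-sample log2 values
    instead.  A zero reference mean yields NaN with a warning.
    """
    mut = matrix.abundances[matrix.group_columns(mutant_group)]
    wt = matrix.abundances[matrix.group_columns(wt_group)]
    if method == "ratio_of_means":
        m_mut = mut.mean(axis=1, skipna=True)
        m_wt = wt.mean(axis=1, skipna=True)
        zero = (m_wt == 0) | m_wt.isna()
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} protein(s) have zero/absent reference mean; "
                "returning NaN", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(m_mut / m_wt.where(~zero))
    elif method == "mean_of_logs":
        with np.errstate(divide="ignore"):
            out = (np.log2(mut).mean(axis=1, skipna=True)
                   - np.log2(wt).mean(axis=1, skipna=True))
    else:
        raise ValueError(f"unknown method {method!r}")
    out.name = f"log2_{mutant_group}_vs_{wt_group}"
    return out


# ---------------------------------------------------------------------------
# ROTS
# ---------------------------------------------------------------------------


def _masked_group_stats(
    values: np.ndarray, mask: np.ndarray, counts_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean / variance / n for datasets given as column-multiplicity counts.

    ``values`` is proteins x samples with NaN replaced by 0, ``mask`` the
    0/1 observation indicator, ``counts_mat`` samples x datasets with the
    multiplicity of each column in each (bootstrap or permutation) dataset.
    """
    n_obs = mask @ counts_mat
    sums = values @ counts_mat
    sumsq = (values * values) @ counts_mat
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / n_obs
        var = (sumsq - n_obs * mean * mean) / (n_obs - 1.0)
    mean = np.where(n_obs > 0, mean, 0.0)
    var = np.where(n_obs > 1, np.maximum(var, 0.0), np.nan)
    return mean, var, n_obs


def _pooled_se(v1, n1, v2, n2) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1.0) * v1 + (n2 - 1.0) * v2) / (n1 + n2 - 2.0)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return se


@dataclass
class ROTSResults:
    """Differential-abundance results of a reproducibility-optimised run."""

    table: pd.DataFrame           # d, p, fdr per protein (index = protein id)
    a1: float
    a2: float
    k: int
    z_score: float
    B: int
    n_perm: int
    seed: int
    optimisation: pd.DataFrame = field(repr=False, default=None)

    def significant(self, fdr_max: float = 0.05, p_max: float = 0.05) -> pd.DataFrame:
        return self.table[(self.table["fdr"] < fdr_max) & (self.table["p"] < p_max)]

    def summary(self) -> str:
        n_sig = int((self.table["fdr"] < 0.05).sum())
        return (
            "ROTS differential abundance\n"
            "===========================\n"
            f"proteins:            {len(self.table)}\n"
            f"bootstraps (B):      {self.B}\n"
            f"permutations:        {self.n_perm}\n"
            f"selected statistic:  d = |x1-x2| / ({self.a1:g} + {self.a2:g} * s)\n"
            f"selected top list:   k = {self.k}\n"
            f"reproducibility Z:   {self.z_score:.2f}\n"
            f"FDR < 0.05:          {n_sig} proteins\n"
        )


class ROTSModel:
    """Two-group reproducibility-optimised test on log2 abundances.

    Parameters
    ----------
    data:
        ``AbundanceMatrix`` (values are abundances; log2 is taken here,
        zeros treated as missing) or a proteins x samples DataFrame of
        log2 abundances when ``log2_input=True``.
    groups:
        For an ``AbundanceMatrix``: the two group labels to compare.  For a
        DataFrame: a label per column (exactly two distinct labels).
    """

    def __init__(self, data, groups, log2_input: bool = False):
        if isinstance(data, AbundanceMatrix):
            g1, g2 = groups
            # seed semantics fixed on sorted sample ids within each group
            cols = sorted(data.group_columns(g1)) + sorted(data.group_columns(g2))
            vals = data.abundances[cols].to_numpy(dtype=float)
            vals = np.where(vals == 0, np.nan, vals)
            with np.errstate(divide="ignore", invalid="ignore"):
                self.x = np.log2(vals)
            self.labels = np.array([data.groups[c] for c in cols])
            self.index = data.abundances.index
            self.group_names = (g1, g2)
        else:
            df = pd.DataFrame(data)
            self.x = df.to_numpy(dtype=float)
            if not log2_input:
                with np.errstate(divide="ignore", invalid="ignore"):
                    self.x = np.log2(np.where(self.x == 0, np.nan, self.x))
            self.labels = np.asarray(list(groups))
            self.index = df.index
            names = pd.unique(self.labels)
            if len(names) != 2:
                raise ValueError("exactly two groups are required")
            self.group_names = tuple(names)
        # deterministic seed semantics: rows sorted by protein id
        order = np.argsort(np.asarray(self.index.astype(str)), kind="stable")
        self._row_order = order
        self._inv_order = np.argsort(order, kind="stable")
        self.x = self.x[order]
        self.g1_cols = np.flatnonzero(self.labels == self.group_names[0])
        self.g2_cols = np.flatnonzero(self.labels == self.group_names[1])
        if len(self.g1_cols) < 2 or len(self.g2_cols) < 2:
            raise ValueError("each group needs at least 2 replicates")

    # -- statistic ---------------------------------------------------------

    def _observed_stats(self) -> tuple[np.ndarray, np.ndarray]:
        m = ~np.isnan(self.x)
        v = np.nan_to_num(self.x)
        e1 = np.zeros((self.x.shape[1], 1)); e1[self.g1_cols, 0] = 1.0
        e2 = np.zeros((self.x.shape[1], 1)); e2[self.g2_cols, 0] = 1.0
        m1, v1, n1 = _masked_group_stats(v, m, e1)
        m2, v2, n2 = _masked_group_stats(v, m, e2)
        diff = np.abs(m1 - m2)[:, 0]
        se = _pooled_se(v1, n1, v2, n2)[:, 0]
        return diff, se

    @staticmethod
    def _d(diff, se, a1, a2):
        denom = a1 + a2 * se
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / denom
        return np.where(np.isfinite(d), d, 0.0)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        B: int = 1000,
        param_grid: Sequence[tuple[float, float]] | None = None,
        topk_grid: Sequence[int] | None = None,
        n_perm: int = 1000,
        seed: int = 0,
    ) -> ROTSResults:
        """Optimise (a1, a2, k) by bootstrap reproducibility, then test.

        ``B`` bootstrap pairs (within-group resampling) give observed top-k
        overlaps; the same construction on group-label-permuted data gives
        null overlaps; the (a1, a2, k) maximising
        ``Z = (overlap - null overlap) / sd(overlap)`` is selected.
        P-values and FDR come from ``n_perm`` label permutations of the
        selected statistic, pooled over proteins, with the FDR monotonised
        over the ranking by d.
        """
        if B < 2:
            raise ValueError("B must be >= 2")
        n, m = self.x.shape
        rng = np.random.default_rng(seed)
        diff_obs, se_obs = self._observed_stats()
        if param_grid is None:
            a1_grid = [0.0, 0.01, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75,
                       1.0, 1.5, 2.0, 3.0, 5.0]
            param_grid = [(a1, 1.0) for a1 in a1_grid] + [(1.0, 0.0)]
        param_grid = list(param_grid)
        if not param_grid:
            raise ValueError("empty parameter grid")
        if np.any(se_obs == 0):
            # grid floor: a degenerate spread makes a1 = 0 ill-defined
            param_grid = [p for p in param_grid if p[0] > 0]
            if not param_grid:
                raise ValueError("zero pooled SD and no a1 > 0 in the grid")
        if topk_grid is None:
            kmax = max(2, n // 2)
            ks, k = [], 25
            while k < kmax:
                ks.append(k)
                k *= 2
            topk_grid = ks or [max(2, n // 4)]
        topk_grid = sorted(int(k) for k in topk_grid)
        if topk_grid[-1] >= n:
            raise ValueError("top-k sizes must be smaller than the protein count")

        mask = (~np.isnan(self.x)).astype(float)
        vals = np.nan_to_num(self.x)

        def _bootstrap_counts(columns: np.ndarray, n_sets: int) -> np.ndarray:
            """samples x n_sets multiplicity matrix of within-group resamples."""
            c = np.zeros((m, n_sets))
            draws = rng.choice(columns, size=(n_sets, len(columns)))
            for j in range(n_sets):
                np.add.at(c[:, j], draws[j], 1.0)
            return c

        def _pair_stats(c1: np.ndarray, c2: np.ndarray):
            m1, v1, n1 = _masked_group_stats(vals, mask, c1)
            m2, v2, n2 = _masked_group_stats(vals, mask, c2)
            return np.abs(m1 - m2), _pooled_se(v1, n1, v2, n2)

        n_sets = 2 * B
        # observed bootstrap: resample replicates within the true groups
        diff_b, se_b = _pair_stats(
            _bootstrap_counts(self.g1_cols, n_sets),
            _bootstrap_counts(self.g2_cols, n_sets))
        # null bootstrap: permute group labels per pair, then resample
        c1n = np.zeros((m, n_sets))
        c2n = np.zeros((m, n_sets))
        n1_, n2_ = len(self.g1_cols), len(self.g2_cols)
        for pair in range(B):
            perm = rng.permutation(m)
            p1, p2 = perm[:n1_], perm[n1_:n1_ + n2_]
            for j in (2 * pair, 2 * pair + 1):
                np.add.at(c1n[:, j], rng.choice(p1, size=n1_), 1.0)
                np.add.at(c2n[:, j], rng.choice(p2, size=n2_), 1.0)
        diff_n, se_n = _pair_stats(c1n, c2n)

        ks = np.asarray(topk_grid)
        kth = np.sort(n - ks)
        rows = []
        for a1, a2 in param_grid:
            db = self._d(diff_b, se_b, a1, a2)
            dn = self._d(diff_n, se_n, a1, a2)
            thr_b = np.partition(db, kth, axis=0)
            thr_n = np.partition(dn, kth, axis=0)
            for k in topk_grid:
                tb = thr_b[n - k]
                tn = thr_n[n - k]
                memb_b = db >= tb
                memb_n = dn >= tn
                ov_b = (memb_b[:, ::2] & memb_b[:, 1::2]).sum(axis=0) / k
                ov_n = (memb_n[:, ::2] & memb_n[:, 1::2]).sum(axis=0) / k
                sd = float(np.std(ov_b, ddof=1))
                z = ((float(np.mean(ov_b)) - float(np.mean(ov_n))) / sd
                     if sd > 0 else -np.inf)
                rows.append({"a1": a1, "a2": a2, "k": k,
                             "overlap": float(np.mean(ov_b)),
                             "null_overlap": float(np.mean(ov_n)),
                             "sd": sd, "z": z})
        opt = pd.DataFrame(rows)
        best = opt.loc[opt["z"].idxmax()]
        a1, a2, k_sel = float(best["a1"]), float(best["a2"]), int(best["k"])

        d_obs = self._d(diff_obs, se_obs, a1, a2)

        # permutation null of the selected statistic, pooled over proteins
        c1p = np.zeros((m, n_perm))
        c2p = np.zeros((m, n_perm))
        for j in range(n_perm):
            perm = rng.permutation(m)
            c1p[perm[:n1_], j] = 1.0
            c2p[perm[n1_:n1_ + n2_], j] = 1.0
        diff_p, se_p = _pair_stats(c1p, c2p)
        d_null = self._d(diff_p, se_p, a1, a2).ravel()
        d_null_sorted = np.sort(d_null)
        n_null = d_null_sorted.size
        # count of null d >= observed d, per protein
        ge = n_null - np.searchsorted(d_null_sorted, d_obs, side="left")
        p = (1.0 + ge) / (1.0 + n_null)

        order = np.argsort(-d_obs, kind="stable")
        rank = np.empty(n, dtype=float)
        rank[order] = np.arange(1, n + 1)
        raw_fdr = (ge / n_perm) / rank
        fdr = np.empty(n)
        fdr_sorted = np.minimum.accumulate(raw_fdr[order][::-1])[::-1]
        fdr[order] = np.minimum(fdr_sorted, 1.0)

        table = pd.DataFrame({"d": d_obs, "p": p, "fdr": fdr})
        table.index = np.asarray(self.index.astype(str))[self._row_order]
        table = table.iloc[self._inv_order]
        table.index = self.index
        return ROTSResults(
            table=table, a1=a1, a2=a2, k=k_sel, z_score=float(best["z"]),
            B=B, n_perm=n_perm, seed=seed, optimisation=opt,
        )


def rots_test(
    matrix,
    groups,
    B: int = 1000,
    param_grid=None,
    topk_grid=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ROTSResults:
    """Convenience wrapper: ``ROTSModel(matrix, groups).fit(...)``."""
    return ROTSModel(matrix, groups).fit(
        B=B, param_grid=param_grid, topk_grid=topk_grid,
        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# selection and conversions
# ---------------------------------------------------------------------------


def select_regulated(
    diff_line1: pd.DataFrame,
    diff_line2: pd.DataFrame,
    annotations: pd.DataFrame,
    fdr_max: float = 0.05,
    log2_min: float = 0.5,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Concordant-regulation table filter across two mutant lines.

    Keeps proteins that are significant (FDR below ``fdr_max``) in BOTH
    lines, with the same ratio sign in both, ``|log2| >= log2_min`` in at
    least one line (the boundary included), and at least ``min_peptides``
    detected peptides.  Inputs are per-line frames with ``log2_ratio`` and
    ``fdr`` columns sharing a protein-id index.
    """
    ids1, ids2 = set(diff_line1.index), set(diff_line2.index)
    if ids1 != ids2:
        raise ValueError(
            "protein id sets differ between lines: "
            f"only-in-1={sorted(ids1 - ids2)[:5]}, only-in-2={sorted(ids2 - ids1)[:5]}")
    d1 = diff_line1
    d2 = diff_line2.loc[d1.index]
    pep = annotations.loc[d1.index, "peptides"]
    sig = (d1["fdr"] < fdr_max) & (d2["fdr"] < fdr_max)
    same_sign = np.sign(d1["log2_ratio"]) * np.sign(d2["log2_ratio"]) > 0
    big = (d1["log2_ratio"].abs() >= log2_min) | (d2["log2_ratio"].abs() >= log2_min)
    enough = pep >= min_peptides
    keep = sig & same_sign & big & enough
    out = pd.DataFrame({
        "log2_ratio_line1": d1["log2_ratio"],
        "log2_ratio_line2": d2["log2_ratio"],
        "fdr_line1": d1["fdr"],
        "fdr_line2": d2["fdr"],
        "peptides": pep,
    })[keep]
    return out


@dataclass
class FoldConversion:
    """A log2 ratio as fold change and percent of the reference."""

    log2_ratio: float
    fold: float                 # 2**x
    percent_of_reference: float  # 100 * 2**x

    @property
    def fold_rounded(self) -> int:
        return int(round(self.fold))

    @property
    def percent_floored(self) -> int:
        return int(np.floor(self.percent_of_reference))


def fold_conversions(log2_ratio: float) -> FoldConversion:
    """Exact fold / percent conversion of a log2 abundance ratio."""
    x = float(log2_ratio)
    if not np.isfinite(x):
        raise ValueError("log2 ratio must be finite")
    fold = 2.0 ** x
    return FoldConversion(log2_ratio=x, fold=fold, percent_of_reference=100.0 * fold)
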