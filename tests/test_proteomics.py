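"""Preprocessing, ROTS behaviour and the concordant-regulation filter."""

import numpy as np
import pandas as pd
import pytest

import photophys as pp
from photophys.simulate import AbundanceMatrix
from photophys.proteomics import fold_conversions, select_regulated


def _matrix(values: dict[str, list], groups: dict[str, str],
            peptides: dict[str, int] | None = None) -> AbundanceMatrix:
    ab = pd.DataFrame(values).T
    ab.columns = list(groups)
    ann = pd.DataFrame({
        "description": "x", "location": "Cp", "encoded": "N",
        "peptides": pd.Series(peptides or {p: 5 for p in ab.index}),
        "unique_peptides": 2,
    }, index=ab.index)
    return AbundanceMatrix(ab, pd.Series(groups, name="group"), ann)


SAMPLES = {f"WT_r{i}": "WT" for i in range(1, 6)} | \
          {f"M_r{i}": "M" for i in range(1, 6)}


class TestPreprocess:
    def test_missingness_rule_brute_force(self):
        nan = np.nan
        mat = _matrix({
            "P1": [1, 1, 1, 1, 1, 2, 2, 2, 2, 2],
            "P2": [nan, nan, 1, 1, 1, 2, 2, 2, 2, 2],   # 2 NA in WT -> drop
            "P3": [nan, 1, 1, 1, 1, 2, 2, 2, 2, nan],   # 1 NA per group -> keep
            "P4": [1, 1, 1, 1, 1, nan, nan, nan, 2, 2],  # 3 NA in M -> drop
        }, SAMPLES)
        prep = pp.preprocess_abundances(mat, groups=("WT", "M"))
        assert sorted(prep.dropped) == ["P2", "P4"]
        assert sorted(prep.matrix.abundances.index) == ["P1", "P3"]

    def test_column_totals_equal_after_normalisation(self, scenario):
        mat, _ = pp.gen_abundance_matrix(scenario, 7)
        prep = pp.preprocess_abundances(mat, groups=("WT", "cpftsy.1-25.7"))
        ab = prep.matrix.abundances
        totals = ab.loc[ab.dropna().index].sum(axis=0)
        assert np.allclose(totals, totals.iloc[0], rtol=1e-12)

    def test_idempotence(self, scenario):
        mat, _ = pp.gen_abundance_matrix(scenario, 7)
        once = pp.preprocess_abundances(mat, groups=("WT", "cpftsy.1-25.7"))
        twice = pp.preprocess_abundances(once.matrix)
        pd.testing.assert_frame_equal(once.matrix.abundances,
                                      twice.matrix.abundances)
        assert twice.dropped == []

    def test_all_missing_column_errors(self):
        vals = {"P1": [np.nan, 1, 1, 1, 1, 2, 2, 2, 2, 2],
                "P2": [np.nan, 1, 1, 1, 1, 2, 2, 2, 2, 2]}
        with pytest.raises(ValueError, match="all-missing"):
            pp.preprocess_abundances(_matrix(vals, SAMPLES), groups=("WT", "M"))


class TestLog2GroupRatio:
    def test_identities(self):
        mat = _matrix({"P1": [3, 3, 3, 3, 3, 3, 3, 3, 3, 3],
                       "P2": [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]}, SAMPLES)
        lr = pp.log2_group_ratio(mat, "M", "WT")
        assert lr["P1"] == pytest.approx(0.0)
        assert lr["P2"] == pytest.approx(1.0)

    def test_zero_reference_warns_nan(self):
        mat = _matrix({"P1": [0, 0, 0, 0, 0, 2, 2, 2, 2, 2]}, SAMPLES)
        with pytest.warns(UserWarning, match="reference"):
            lr = pp.log2_group_ratio(mat, "M", "WT")
        assert np.isnan(lr["P1"])


class TestROTS:
    def test_degenerate_grid_orders_by_mean_difference(self, scenario):
        d = scenario.to_dict()
        d["proteomics"].update(dict(n_prot=120, mcar_p=0.0, mnar_mid=-1e6,
                                    pi_diff=0.3))
        sc = pp.SimScenario.from_dict(d)
        mat, _ = pp.gen_abundance_matrix(sc, 5, groups=["WT", "cpftsy.1-25.7"])
        res = pp.rots_test(mat, ("cpftsy.1-25.7", "WT"), B=50, n_perm=50,
                           param_grid=[(1.0, 0.0)], topk_grid=[10, 20], seed=1)
        x = np.log2(mat.abundances)
        md = (x[mat.group_columns("cpftsy.1-25.7")].mean(axis=1)
              - x[mat.group_columns("WT")].mean(axis=1)).abs()
        assert list(res.table.sort_values("d", ascending=False).index) == \
            list(md.sort_values(ascending=False).index)

    def test_row_and_sample_order_invariance(self, scenario):
        d = scenario.to_dict()
        d["proteomics"].update(dict(n_prot=80, pi_diff=0.2))
        sc = pp.SimScenario.from_dict(d)
        mat, _ = pp.gen_abundance_matrix(sc, 6, groups=["WT", "cpftsy.1-25.7"])
        res1 = pp.rots_test(mat, ("cpftsy.1-25.7", "WT"), B=50, n_perm=50, seed=2)
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(mat.abundances.index)
        perm_cols = rng.permutation(mat.abundances.columns)
        mat2 = AbundanceMatrix(mat.abundances.loc[perm_rows, perm_cols],
                               mat.groups[perm_cols],
                               mat.annotations.loc[perm_rows])
        res2 = pp.rots_test(mat2, ("cpftsy.1-25.7", "WT"), B=50, n_perm=50, seed=2)
        pd.testing.assert_frame_equal(res1.table.sort_index(),
                                      res2.table.sort_index())

    def test_fdr_monotone_in_rank(self, scenario):
        d = scenario.to_dict()
        d["proteomics"].update(dict(n_prot=300, pi_diff=0.1))
        sc = pp.SimScenario.from_dict(d)
        mat, _ = pp.gen_abundance_matrix(sc, 9, groups=["WT", "cpftsy.1-25.7"])
        res = pp.rots_test(mat, ("cpftsy.1-25.7", "WT"), B=60, n_perm=60, seed=3)
        tab = res.table.sort_values("d", ascending=False)
        assert (np.diff(tab["fdr"].to_numpy()) >= -1e-12).all()

    def test_bad_inputs(self, scenario):
        mat, _ = pp.gen_abundance_matrix(scenario, 1)
        with pytest.raises(ValueError, match="B"):
            pp.rots_test(mat, ("cpftsy.1-25.7", "WT"), B=1)
        with pytest.raises(ValueError, match="grid"):
            pp.rots_test(mat, ("cpftsy.1-25.7", "WT"), B=10, param_grid=[])


class TestSelectRegulated:
    def _diff(self, rows):
        return pd.DataFrame(rows, columns=["log2_ratio", "fdr"],
                            index=[f"P{i}" for i in range(1, len(rows) + 1)])

    def _ann(self, peptides):
        return pd.DataFrame({"peptides": peptides},
                            index=[f"P{i}" for i in range(1, len(peptides) + 1)])

    def test_each_clause_exercised(self):
        # P1 passes all clauses; P2 boundary |log2| = 0.5 in one line: passes
        # P3 fails FDR in line 2; P4 fails sign concordance;
        # P5 fails |log2| in both; P6 fails peptide count.
        d1 = self._diff([(1.0, 0.01), (0.5, 0.01), (0.8, 0.01),
                         (0.6, 0.01), (0.3, 0.01), (1.2, 0.01)])
        d2 = self._diff([(0.9, 0.01), (0.2, 0.01), (0.8, 0.30),
                         (-0.6, 0.01), (0.4, 0.01), (1.1, 0.01)])
        ann = self._ann([5, 5, 5, 5, 5, 1])
        out = select_regulated(d1, d2, ann)
        assert sorted(out.index) == ["P1", "P2"]
        # independent brute-force clause evaluation
        brute = [p for p in d1.index
                 if d1.loc[p, "fdr"] < 0.05 and d2.loc[p, "fdr"] < 0.05
                 and np.sign(d1.loc[p, "log2_ratio"]) ==
                     np.sign(d2.loc[p, "log2_ratio"])
                 and max(abs(d1.loc[p, "log2_ratio"]),
                         abs(d2.loc[p, "log2_ratio"])) >= 0.5
                 and ann.loc[p, "peptides"] >= 2]
        assert sorted(out.index) == sorted(brute)

    def test_empty_input(self):
        out = select_regulated(self._diff([]), self._diff([]), self._ann([]))
        assert out.empty

    def test_sign_disagreement_excluded(self):
        d1 = self._diff([(0.6, 0.01)])
        d2 = self._diff([(-0.6, 0.01)])
        assert select_regulated(d1, d2, self._ann([5])).empty

    def test_mismatched_ids_error(self):
        d1 = self._diff([(0.6, 0.01), (0.7, 0.01)])
        d2 = self._diff([(0.6, 0.01)])
        with pytest.raises(ValueError, match="differ"):
            select_regulated(d1, d2, self._ann([5, 5]))


class TestFoldConversions:
    @pytest.mark.parametrize("x,percent,floored", [
        (-1.96, 25.70, 25),
        (-1.35, 39.23, 39),
    ])
    def test_percent_of_reference(self, x, percent, floored):
        fc = fold_conversions(x)
        assert fc.percent_of_reference == pytest.approx(percent, abs=0.005)
        assert fc.percent_floored == floored

    @pytest.mark.parametrize("x,fold,rounded", [
        (1.16, 2.234, 2),
        (1.58, 2.990, 3),
    ])
    def test_fold(self, x, fold, rounded):
        fc = fold_conversions(x)
        assert fc.fold == pytest.approx(fold, abs=0.005)
        assert fc.fold_rounded == rounded

    def test_identity_and_inverse(self):
        assert fold_conversions(0.0).fold == 1.0
        assert fold_conversions(0.0).percent_of_reference == 100.0
        for x in (-2.3, -0.5, 0.1, 3.7):
            assert np.log2(fold_conversions(x).fold) == pytest.approx(x)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fold_conversions(np.inf)
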