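"""Phenotype association: correlation matrix, flagging, FDR screen, PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from mircascade.association import (
    correlation_matrix,
    cross_model_mir_screen,
    flag_significant,
    per_model_tests,
    pooled_group_test,
    run_pca,
)
from mircascade.errors import DegenerateInputError
from mircascade.normalization import DeltaCtMatrix, compute_delta_ct
from mircascade.simulate import SimulationConfig, simulate_validation_cohorts
from mircascade.stats import benjamini_hochberg

from conftest import make_burden, make_ct, make_meta


def as_delta(ctm):
    return DeltaCtMatrix(dct=ctm.ct, card=ctm.card, is_control=ctm.is_control)


@pytest.fixture
def assoc_data(rng):
    samples = [f"s{i}" for i in range(8)]
    ctm = make_ct(
        {f"m{i}": rng.uniform(20, 30, 8) for i in range(3)}, samples
    )
    pheno = pd.DataFrame(
        {"weight_gain": np.arange(8.0), "BDNF": rng.uniform(300, 700, 8)},
        index=pd.Index(samples, name="sample_id"),
    )
    return as_delta(ctm), pheno


class TestCorrelationMatrix:
    def test_cardinality(self, assoc_data):
        d, pheno = assoc_data
        tab = correlation_matrix(d, pheno)
        assert len(tab) == 3 * 2

    def test_identical_ordering_gives_r_one(self, assoc_data):
        d, pheno = assoc_data
        d.dct.loc["m0"] = np.arange(8.0)
        tab = correlation_matrix(d, pheno).set_index(["x_name", "y_name"])
        assert tab.at[("m0", "weight_gain"), "r"] == pytest.approx(1.0)

    def test_missing_value_reduces_n_pairs(self, assoc_data):
        d, pheno = assoc_data
        pheno.iloc[0, 0] = np.nan
        tab = correlation_matrix(d, pheno).set_index(["x_name", "y_name"])
        assert tab.at[("m0", "weight_gain"), "n_pairs"] == 7
        assert tab.at[("m0", "BDNF"), "n_pairs"] == 8

    def test_burden_covariates_included(self, assoc_data):
        d, pheno = assoc_data
        burden = make_burden({"s0": 3, "s1": 5, "s2": 8, "s3": 1})
        tab = correlation_matrix(d, pheno, burden)
        assert set(tab["y_name"]) == {
            "weight_gain", "BDNF", "Seizures_n", "Seizures_duration"
        }
        sub = tab[tab["y_name"] == "Seizures_n"]
        assert (sub["n_pairs"] == 4).all()

    def test_role_symmetry(self, rng):
        # swapping the two vectors of a pair leaves r and p unchanged
        from mircascade.stats import spearman
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = spearman(x, y), spearman(y, x)
        assert a.r == pytest.approx(b.r) and a.p_value == pytest.approx(b.p_value)

    def test_no_overlap_is_undefined(self, assoc_data):
        d, pheno = assoc_data
        pheno["sparse"] = np.nan
        tab = correlation_matrix(d, pheno).set_index(["x_name", "y_name"])
        assert math.isnan(tab.at[("m0", "sparse"), "r"])


class TestFlagSignificant:
    def test_rule_on_examples(self):
        tab = pd.DataFrame(
            {"x_name": "m", "y_name": list("abc"),
             "n_pairs": 16, "r": [0.6, 0.4, -0.7], "p": [0.01, 0.001, 0.2],
             "q": np.nan, "flagged": False}
        )
        out = flag_significant(tab)
        assert out["flagged"].tolist() == [True, False, False]

    def test_degenerate_thresholds(self, assoc_data):
        d, pheno = assoc_data
        tab = correlation_matrix(d, pheno)
        all_on = flag_significant(tab, r_threshold=0.0, alpha=1.0)
        defined = tab["r"].notna()
        assert all_on.loc[defined, "flagged"].all()
        none_on = flag_significant(tab, r_threshold=1.0, alpha=1.0)
        assert not none_on.loc[tab["r"].abs() < 1, "flagged"].any()


class TestCrossModelScreen:
    def test_family_of_one_has_q_equal_p(self, assoc_data):
        d, pheno = assoc_data
        out = cross_model_mir_screen(d, "m0", pheno[["BDNF"]])
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_q_matches_hand_step_up(self, assoc_data):
        d, pheno = assoc_data
        pheno["extra"] = [3, 1, 4, 1, 5, 9, 2, 6]
        out = cross_model_mir_screen(d, "m0", pheno)
        expected = benjamini_hochberg(out["p"].to_numpy())
        assert out["q"].to_numpy() == pytest.approx(expected)

    def test_shuffled_null_flag_rate(self):
        # permuted phenotypes: q < 0.05 flags stay within binomial bounds of 0.05
        rng = np.random.default_rng(11)
        n_flag = n_tot = 0
        base = np.arange(16.0)
        for _ in range(300):
            ctm = make_ct({"m": rng.normal(size=16) + 25}, [f"s{i}" for i in range(16)])
            pheno = pd.DataFrame(
                {f"p{j}": rng.permutation(base) for j in range(8)},
                index=pd.Index([f"s{i}" for i in range(16)], name="sample_id"),
            )
            out = cross_model_mir_screen(as_delta(ctm), "m", pheno)
            n_flag += int((out["q"] < 0.05).sum())
            n_tot += len(out)
        rate = n_flag / n_tot
        # BH under the null controls FDR at <= 0.05; 99% upper binomial bound
        assert rate < 0.05 + 2.58 * math.sqrt(0.05 * 0.95 / n_tot)


class TestModelTests:
    @pytest.fixture
    def cohorts(self):
        cfg = SimulationConfig(seed=9, n_validation_candidates=5)
        return cfg, simulate_validation_cohorts(cfg)

    def _pooled(self, cohorts):
        ctms, metas = [], []
        for ctm, meta, _, _ in cohorts.values():
            ctms.append(ctm.ct)
            metas.append(meta)
        ct = pd.concat(ctms, axis=1)
        first = next(iter(cohorts.values()))[0]
        return (
            DeltaCtMatrix(dct=ct, card=first.card, is_control=first.is_control),
            pd.concat(metas),
        )

    def test_per_model_record_per_model(self, cohorts):
        _, sims = cohorts
        d, meta = self._pooled(sims)
        out = per_model_tests(d, meta, "cand-01")
        assert len(out) == 4
        assert set(out.index) == set(m for m, *_ in SimulationConfig().validation_sizes)

    def test_pooled_invariant_to_sample_order(self, cohorts):
        _, sims = cohorts
        d, meta = self._pooled(sims)
        rec = pooled_group_test(d, meta, "cand-01")
        rng = np.random.default_rng(4)
        perm = rng.permutation(d.dct.columns)
        d2 = DeltaCtMatrix(dct=d.dct[perm], card=d.card, is_control=d.is_control)
        rec2 = pooled_group_test(d2, meta, "cand-01")
        assert rec["t_stat"] == pytest.approx(rec2["t_stat"])

    def test_identical_pooled_groups_p_one(self):
        samples = ["e1", "e2", "e3", "r1", "r2", "r3"]
        meta = make_meta({s: ("experimental" if s[0] == "e" else "sham") for s in samples})
        d = as_delta(make_ct({"m": [1.0, 2, 3, 1, 2, 3]}, samples))
        rec = pooled_group_test(d, meta, "m")
        assert rec["p_value"] == 1.0


class TestPca:
    def test_single_direction_explains_everything(self):
        data = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [5.0, 5, 5, 5]})
        res = run_pca(data, standardize=False)
        assert res.explained[0] == pytest.approx(1.0)

    def test_two_variable_toy_loadings(self):
        data = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [0.0, 1, 2, 3]})
        res = run_pca(data, standardize=True)
        assert res.explained[0] == pytest.approx(1.0)
        assert res.loadings[:, 0] == pytest.approx([math.sqrt(2) / 2] * 2)

    def test_reconstruction_with_all_components(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        res = run_pca(data, standardize=True)
        proc = (data - data.mean()) / data.std(ddof=1)
        assert np.allclose(res.scores @ res.loadings.T, proc.to_numpy(), atol=1e-8)
        assert res.explained.sum() == pytest.approx(1.0)

    def test_explained_fractions_non_increasing_scores_uncorrelated(self, rng):
        data = pd.DataFrame(rng.normal(size=(12, 5)))
        res = run_pca(data)
        assert np.all(np.diff(res.explained) <= 1e-12)
        cov = np.cov(res.scores, rowvar=False)
        assert np.allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-8)

    def test_sign_convention_is_deterministic(self, rng):
        data = pd.DataFrame(rng.normal(size=(9, 3)))
        a, b = run_pca(data), run_pca(data.copy())
        assert np.allclose(a.loadings, b.loadings)
        for j in range(a.loadings.shape[1]):
            i = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[i, j] > 0

    def test_mean_imputation_and_zero_variance_drop(self, rng):
        data = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        data.loc[0, "a"] = np.nan
        data["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = run_pca(data, standardize=True)
        assert res.variables == ["a", "b", "c"]

    def test_too_few_variables_raises(self):
        with pytest.raises(DegenerateInputError):
            run_pca(pd.DataFrame({"x": [1.0, 2, 3]}))
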