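"""Filter cascade: stage rules, boundaries, provenance, conservation."""

import numpy as np
import pandas as pd
import pytest

from mircascade.cascade import (
    CascadeConfig,
    filter_effect_size,
    filter_min_ct,
    filter_missingness,
    filter_not_expressed,
    filter_seizure_correlation,
    run_cascade,
    screening_hits,
)
from mircascade.errors import ConfigurationError, ValidationError
from mircascade.normalization import DeltaCtMatrix, compute_delta_ct, differential_expression
from mircascade.simulate import SimulationConfig, simulate_screening_dataset

from conftest import make_burden, make_ct, make_meta

CFG = CascadeConfig()


def as_delta(ctm):
    return DeltaCtMatrix(dct=ctm.ct, card=ctm.card, is_control=ctm.is_control)


class TestStageRules:
    def test_not_expressed(self):
        ctm = make_ct({"gone": [None, None], "weak": [39.0, None]}, ["s1", "s2"])
        assert filter_not_expressed(ctm, CFG) == {"gone"}

    def test_not_expressed_median_rule(self):
        # median with missing-at-LOD convention: {39, 40, 40} -> 40 >= LOD
        ctm = make_ct({"m": [39.0, None, None]}, ["s1", "s2", "s3"])
        cfg = CascadeConfig(presence_rule="median_below_lod")
        assert filter_not_expressed(ctm, cfg) == {"m"}
        assert filter_not_expressed(ctm, CFG) == set()

    def test_missingness_per_group(self):
        meta = make_meta(
            {"e1": "experimental", "e2": "experimental",
             "r1": "sham", "r2": "sham", "r3": "sham"}
        )
        ctm = make_ct(
            {"thin": [20.0, None, 20, 21, 22], "ok": [20, 21, 20, 21, 22]},
            ["e1", "e2", "r1", "r2", "r3"],
        )
        assert filter_missingness(ctm, meta, CFG) == {"thin"}

    def test_t_boundary_strict(self):
        # p == alpha must be removed, p just below retained
        diff = pd.DataFrame(
            {"p_value": [0.049, 0.05], "testable": [True, True],
             "log2fc": [2.0, 2.0]},
            index=["keep", "drop"],
        )
        removed = set(diff.index[~(diff["p_value"] < CFG.alpha)])
        assert removed == {"drop"}

    @pytest.mark.parametrize(
        "lfc,removed", [(0.5, True), (1.5, False), (-1.0, False), (1.0, False)]
    )
    def test_fold_change_open_band(self, lfc, removed):
        diff = pd.DataFrame({"log2fc": [lfc]}, index=["m"])
        assert (("m" in filter_effect_size(diff, CFG)) is removed)

    def test_min_ct_modes(self):
        ctm = make_ct({"a": [28.0, 31, 35], "b": [31.0, 32, 33]}, ["s1", "s2", "s3"])
        assert filter_min_ct(ctm, CFG) == {"b"}
        all_mode = CascadeConfig(ct_ceiling_mode="all_samples")
        assert filter_min_ct(ctm, all_mode) == {"a", "b"}


class TestConfoundStage:
    def _fixture(self):
        samples = ["e1", "e2", "e3", "e4", "e5"]
        meta = make_meta({s: "experimental" for s in samples})
        burden = make_burden({s: 2 * (i + 1) for i, s in enumerate(samples)})
        return samples, meta, burden

    def test_perfect_positive_correlation_removed(self):
        samples, meta, burden = self._fixture()
        d = as_delta(make_ct({"m": [1.0, 2, 3, 4, 5]}, samples))
        removed, table = filter_seizure_correlation(d, burden, meta, CFG)
        assert removed == {"m"}
        assert table.at["m", "r_seizfreq"] == pytest.approx(1.0)

    def test_negative_correlation_retained_in_positive_only_mode(self):
        samples, meta, burden = self._fixture()
        d = as_delta(make_ct({"m": [5.0, 4, 3, 2, 1]}, samples))
        removed, _ = filter_seizure_correlation(d, burden, meta, CFG)
        assert removed == set()
        abs_cfg = CascadeConfig(confound_mode="absolute")
        removed_abs, _ = filter_seizure_correlation(d, burden, meta, abs_cfg)
        assert removed_abs == {"m"}

    def test_high_r_without_significance_retained(self):
        # n = 3 pairs: r can be 1 but exact p = 2/6 > alpha
        samples = ["e1", "e2", "e3"]
        meta = make_meta({s: "experimental" for s in samples})
        burden = make_burden({s: i + 1 for i, s in enumerate(samples)})
        d = as_delta(make_ct({"m": [1.0, 2, 3]}, samples))
        removed, table = filter_seizure_correlation(d, burden, meta, CFG)
        assert removed == set() and table.at["m", "p_seizfreq"] > CFG.alpha

    def test_missing_burden_is_configuration_error(self):
        samples, meta, _ = self._fixture()
        d = as_delta(make_ct({"m": [1.0, 2, 3, 4, 5]}, samples))
        with pytest.raises(ConfigurationError):
            filter_seizure_correlation(d, None, meta, CFG)


class TestRunCascade:
    def test_tiny_screen_trace(self, tiny_screen):
        ctm, meta, burden = tiny_screen
        trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
        t = trace.table
        assert t.at["m-none", "removed_at"] == "NOT_EXPRESSED"
        assert t.at["m-missing", "removed_at"] == "MISSINGNESS"
        assert t.at["m-var", "removed_at"] == "T_TEST"
        assert t.at["m-up", "removed_at"] == "RETAINED"
        assert "ctrl" not in t.index
        assert trace.check_conservation()

    def test_attribution_follows_stage_order(self):
        # an assay failing both the t-test and the Ct ceiling is counted at T_TEST
        samples = ["e1", "e2", "e3", "r1", "r2", "r3"]
        meta = make_meta({s: ("experimental" if s[0] == "e" else "sham") for s in samples})
        burden = make_burden({f"e{i}": 3 * i for i in (1, 2, 3)})
        ctm = make_ct(
            {"dim-null": [32.0, 33, 31.5, 32.5, 31, 33.5],
             "anchor": [25.0, 25, 25, 25.1, 25.1, 25.1],
             "anchor2": [20.0, 21, 20.5, 20.2, 20.8, 20.4]},
            samples,
        )
        trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
        assert trace.table.at["dim-null", "removed_at"] == "T_TEST"
        # min-Ct statistic is only recorded for assays that reached stage 6
        assert np.isnan(trace.table.at["dim-null", "min_ct"])

    def test_stats_recorded_only_up_to_removal_stage(self, tiny_screen):
        ctm, meta, burden = tiny_screen
        trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
        row = trace.table.loc["m-none"]
        assert row[["p_ttest", "log2fc", "r_seizfreq", "min_ct"]].isna().all()

    def test_empty_matrix_gives_empty_trace(self):
        samples = ["e1", "e2", "r1", "r2"]
        meta = make_meta({s: ("experimental" if s[0] == "e" else "sham") for s in samples})
        ctm = make_ct({"ctrl": [20.0] * 4}, samples, controls=("ctrl",))
        burden = make_burden({"e1": 1, "e2": 2})
        trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
        assert trace.n_input == 0 and trace.retained == []

    def test_conservation_and_nesting_on_random_data(self):
        root = np.random.default_rng(77)
        for _ in range(25):
            cfg = SimulationConfig(
                n_mirs=int(root.integers(10, 40)),
                n_controls=2,
                n_de=int(root.integers(0, 4)),
                n_confounded=int(root.integers(0, 3)),
                fraction_not_expressed=float(root.uniform(0, 0.4)),
                missing_rate=float(root.uniform(0, 0.15)),
                seed=int(root.integers(2**31)),
            )
            ctm, meta, burden, _ = simulate_screening_dataset(cfg)
            trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
            assert trace.check_conservation()
            order = list(trace.stage_counts)
            assert order == ["NOT_EXPRESSED", "MISSINGNESS", "T_TEST",
                             "FOLD_CHANGE", "CONFOUND_CORR", "MIN_CT"]
            # nesting: survivors shrink monotonically stage by stage
            alive = trace.n_input
            for stage in order:
                nxt = alive - trace.stage_counts[stage]
                assert 0 <= nxt <= alive
                alive = nxt
            assert alive == len(trace.retained)

    def test_candidates_ordered_by_ascending_p(self, tiny_screen):
        ctm, meta, burden = tiny_screen
        trace = run_cascade(ctm, compute_delta_ct(ctm), meta, burden)
        ps = trace.table.loc[trace.retained, "p_ttest"].to_numpy()
        assert np.all(np.diff(ps) >= 0)


class TestScreeningHits:
    def test_hit_rule(self, tiny_screen):
        ctm, meta, burden = tiny_screen
        diff = differential_expression(compute_delta_ct(ctm), meta)
        hits = screening_hits(diff, ctm)
        assert "m-up" in hits          # p < alpha, min Ct ~23
        assert "m-flat" not in hits    # no effect
        assert "m-weak" not in hits or ctm.ct.loc["m-weak"].min() <= 30

    def test_ct_condition_modes(self):
        samples = ["e1", "e2", "e3", "r1", "r2", "r3"]
        meta = make_meta({s: ("experimental" if s[0] == "e" else "sham") for s in samples})
        # strong effect but one sample above the ceiling
        ctm = make_ct({"m": [24.0, 24.2, 23.8, 29.0, 29.2, 31.0],
                       "anchor": [25.0, 26, 25.5, 25.2, 25.8, 25.4]}, samples)
        diff = differential_expression(as_delta(ctm), meta)
        assert "m" in screening_hits(diff, ctm, CascadeConfig())
        assert "m" not in screening_hits(
            diff, ctm, CascadeConfig(ct_ceiling_mode="all_samples")
        )


def test_config_validation():
    with pytest.raises(ValidationError):
        CascadeConfig(alpha=1.5)
    with pytest.raises(ValidationError):
        CascadeConfig(confound_mode="sideways")
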