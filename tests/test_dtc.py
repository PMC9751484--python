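"""CRITIC weighting and drought tolerance coefficient tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import teadtc as t
from teadtc.dtc import (
    DroughtToleranceScorer,
    OrientationSpec,
    _round_half_up,
    compute_dtc,
    critic_weights,
    orient_and_normalize,
    rank_varieties,
    relative_difference,
    summarize_physiology,
)


def _physio(values, varieties=None, stages=None):
    n = len(values)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "variety": varieties or ["v"] * n,
        "stage": stages or ["d1"] * n,
        "mda": [v[0] for v in values],
        "ss": [v[1] for v in values],
        "tp": [v[2] for v in values],
    })


class TestSummaries:
    def test_equal_replicates(self):
        table = _physio([(8, 8, 8)] * 3)
        out = summarize_physiology(table)
        assert out.loc[0, "mda_mean"] == 8.0
        assert out.loc[0, "mda_sem"] == 0.0

    def test_hand_sem(self):
        table = _physio([(7.5, 1, 1), (8.0, 1, 1), (8.5, 1, 1)])
        out = summarize_physiology(table)
        assert out.loc[0, "mda_mean"] == pytest.approx(8.0)
        assert out.loc[0, "mda_sem"] == pytest.approx(0.5 / np.sqrt(3), abs=1e-10)

    def test_single_replicate_flagged(self):
        out = summarize_physiology(_physio([(5, 5, 5)]))
        assert not out.loc[0, "sem_defined"]
        assert out.loc[0, "ss_sem"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_physiology(_physio([]))


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "a,b,basis,expected",
        [
            (10.65, 7.77, "smaller", 37.07),  # MDA day-1 extremes
            (5.01, 2.22, "larger", 55.69),    # TP day-17 extremes
            (8.57, 3.76, "larger", 56.12),    # TP day-1 extremes
            (40.51, 28.63, "larger", 29.32),  # SS day-17 extremes
            (4.2, 4.2, "smaller", 0.0),
        ],
    )
    def test_values(self, a, b, basis, expected):
        # published values truncate the percentage, so allow one unit in the
        # last printed digit
        assert relative_difference(a, b, basis) == pytest.approx(expected, abs=0.01)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            relative_difference(-1.0, 2.0)
        with pytest.raises(ValueError):
            relative_difference(2.0, 5.0)  # first argument must be larger
        with pytest.raises(ValueError):
            relative_difference(5.0, 2.0, basis="median")


class TestNormalization:
    def test_positive_and_negative_orientation(self):
        table = _physio([(0, 0, 0), (5, 5, 5), (10, 10, 10)])
        out = orient_and_normalize(table)
        assert np.allclose(out["mda"], [0.0, 0.5, 1.0])   # positive
        assert np.allclose(out["tp"], [1.0, 0.5, 0.0])    # negative

    def test_constant_column_rejected(self):
        table = _physio([(1, 2, 5), (2, 3, 5), (3, 4, 5)])
        with pytest.raises(ValueError, match="tp"):
            orient_and_normalize(table)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_output_spans_unit_interval(self, vals):
        table = _physio([(v, v + 1, v + 2) for v in vals])
        out = orient_and_normalize(table)
        for col in out.columns:
            assert out[col].min() == pytest.approx(0.0, abs=1e-12)
            assert out[col].max() == pytest.approx(1.0, abs=1e-12)


class TestCritic:
    def test_uncorrelated_equal_sd_columns_split_evenly(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        res = critic_weights(X)
        assert np.allclose(res.weights, [0.5, 0.5], atol=1e-12)

    def test_duplicate_column_matches_formula_oracle(self, rng):
        X = rng.random((30, 2))
        X = np.column_stack([X, X[:, 1]])  # column 3 duplicates column 2
        res = critic_weights(X)
        # independent brute-force evaluation of the definition
        sd = np.array([np.std(X[:, j], ddof=1) for j in range(3)])
        r = np.ones((3, 3))
        for j in range(3):
            for k in range(3):
                r[j, k] = np.corrcoef(X[:, j], X[:, k])[0, 1]
        C = np.array([sd[j] * sum(1 - r[j, k] for k in range(3)) for j in range(3)])
        assert np.allclose(res.info_content, C, atol=1e-10)
        assert np.allclose(res.weights, C / C.sum(), atol=1e-10)
        assert res.correlation[1, 2] == pytest.approx(1.0)

    def test_weight_invariants(self, rng):
        res = critic_weights(rng.random((50, 3)))
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.info_content >= 0)
        assert np.allclose(res.correlation, res.correlation.T)
        assert np.allclose(np.diag(res.correlation), 1.0)

    def test_zero_variance_column_rejected(self):
        X = np.array([[1.0, 0.0], [1.0, 0.5], [1.0, 1.0]])
        with pytest.raises(ValueError, match="zero variance"):
            critic_weights(X)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance_through_normalization(self, scale):
        rng = np.random.default_rng(0)
        table = _physio([tuple(v) for v in rng.random((20, 3)) + 0.1])
        base = critic_weights(orient_and_normalize(table))
        scaled = table.copy()
        scaled["ss"] = scaled["ss"] * scale
        res = critic_weights(orient_and_normalize(scaled))
        assert np.allclose(res.weights, base.weights, atol=1e-9)


class TestDTC:
    def test_corner_rows(self):
        norm = pd.DataFrame({"mda": [1.0, 0.0], "ss": [1.0, 0.0], "tp": [1.0, 0.0]})
        critic = critic_weights(
            pd.DataFrame(np.random.default_rng(1).random((20, 3)),
                         columns=["mda", "ss", "tp"])
        )
        out = compute_dtc(norm, critic)
        assert out.table["dtc"].iloc[0] == pytest.approx(1.0)
        assert out.table["dtc"].iloc[1] == pytest.approx(0.0)

    def test_hand_weighted_sum(self):
        norm = pd.DataFrame({"mda": [0.2], "ss": [0.4], "tp": [0.6]})
        critic = critic_weights(
            pd.DataFrame(np.random.default_rng(1).random((20, 3)),
                         columns=["mda", "ss", "tp"])
        )
        critic.weights = np.array([0.3, 0.3, 0.4])
        out = compute_dtc(norm, critic)
        assert out.table["dtc"].iloc[0] == pytest.approx(0.42, abs=1e-12)

    def test_monotone_in_each_indicator(self):
        rng = np.random.default_rng(3)
        critic = critic_weights(pd.DataFrame(rng.random((20, 3)),
                                             columns=["mda", "ss", "tp"]))
        base = pd.DataFrame({"mda": [0.5], "ss": [0.5], "tp": [0.5]})
        d0 = compute_dtc(base, critic).table["dtc"].iloc[0]
        for col in ("mda", "ss", "tp"):
            bumped = base.copy()
            bumped[col] += 0.2
            assert compute_dtc(bumped, critic).table["dtc"].iloc[0] >= d0


class TestRanking:
    def _scored(self, dtc_values, varieties):
        table = pd.DataFrame({"variety": varieties, "dtc": dtc_values})
        from teadtc.dtc import DTCTable
        return DTCTable(table, float(np.mean(dtc_values)), float(np.median(dtc_values)))

    @pytest.mark.parametrize("count,total,expected", [(18, 280, 6.43), (0, 280, 0.0),
                                                      (280, 280, 100.0)])
    def test_percentage_arithmetic(self, count, total, expected):
        assert _round_half_up(count / total * 100.0) == pytest.approx(expected)

    def test_counts_partition_above_mean_samples(self, default_dtc):
        ranking = rank_varieties(default_dtc)
        total_above = (default_dtc.table["dtc"] > default_dtc.mean).sum()
        assert ranking.table["n_beyond_mean"].sum() == total_above
        assert (ranking.table["n_beyond_mean"]
                <= default_dtc.table.groupby("variety")["dtc"].count().max()).all()

    def test_rank_order_and_ties(self):
        scored = self._scored([0.9, 0.9, 0.1, 0.9, 0.1, 0.1],
                              ["a", "a", "a", "b", "b", "b"])
        ranking = rank_varieties(scored)
        assert list(ranking.table["variety"]) == ["a", "b"]
        assert list(ranking.table["rank"]) == [1, 2]

    def test_invalid_total(self, default_dtc):
        with pytest.raises(ValueError):
            rank_varieties(default_dtc, total_n=0)


class TestScorer:
    def test_matches_function_pipeline(self, default_experiment, default_dtc):
        _, physio, _ = default_experiment
        scorer = DroughtToleranceScorer().fit(physio[["mda", "ss", "tp"]])
        scores = scorer.transform(physio[["mda", "ss", "tp"]])
        assert np.allclose(scores, default_dtc.table["dtc"].to_numpy(), atol=1e-12)

    def test_tolerance_oriented_is_complement(self, default_experiment):
        _, physio, _ = default_experiment
        X = physio[["mda", "ss", "tp"]]
        stress = DroughtToleranceScorer().fit_transform(X)
        tol = DroughtToleranceScorer(tolerance_oriented=True).fit_transform(X)
        assert np.allclose(stress + tol, 1.0, atol=1e-12)

    def test_sklearn_param_protocol(self):
        scorer = DroughtToleranceScorer()
        params = scorer.get_params()
        assert "orientation" in params and "tolerance_oriented" in params
        scorer.set_params(tolerance_oriented=True)
        assert scorer.tolerance_oriented
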