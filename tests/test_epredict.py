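import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import fibroscore as fs
from fibroscore.exceptions import ConfigurationError, OptimizationError, ValidationError


def _index(drugs, e_values, model="CCl4_treatment"):
    return fs.InVivoIndex(
        pd.DataFrame(
            {
                "drug_id": drugs,
                "model": model,
                "e_invivo": e_values,
                "sc_scaled": 3.0,
                "st_scaled": 1.0,
                "study_id": "synthetic",
            }
        )
    )


class TestEnumeration:
    @pytest.mark.parametrize("n, expected", [(1, 3), (2, 9), (10, 59049)])
    def test_lattice_size(self, n, expected):
        W = fs.enumerate_weight_vectors(n)
        assert W.shape == (expected, n)
        assert len(np.unique(W, axis=0)) == expected

    def test_lexicographic_order(self):
        W = fs.enumerate_weight_vectors(2)
        assert W[0].tolist() == [0, 0]
        assert W[-1].tolist() == [2, 2]
        assert W[1].tolist() == [0, 1]


class TestSpearmanWithOutlier:
    def test_concordant_ranks_need_no_outlier(self):
        rho, idx = fs.spearman_with_outlier([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == 1.0 and idx is None

    def test_single_discordant_point_is_removed(self):
        rho, idx = fs.spearman_with_outlier([1, 2, 3, 4, 5], [1, 2, 3, 4, 0])
        assert rho == 1.0 and idx == 4

    def test_reversed_ranks_stay_at_minus_one(self):
        rho, idx = fs.spearman_with_outlier([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == -1.0

    def test_outlier_search_matches_scipy_brute_force(self, rng):
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            rho, _ = fs.spearman_with_outlier(x, y)
            candidates = [spearmanr(x, y).statistic]
            for drop in range(6):
                keep = np.arange(6) != drop
                candidates.append(spearmanr(x[keep], y[keep]).statistic)
            assert rho == pytest.approx(max(candidates))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=4,
            max_size=10,
        )
    )
    def test_outlier_allowance_never_hurts(self, pairs):
        x, y = zip(*pairs)
        with_outlier, _ = fs.spearman_with_outlier(x, y, max_outliers=1)
        plain, _ = fs.spearman_with_outlier(x, y, max_outliers=0)
        if not (np.isnan(plain) or np.isnan(with_outlier)):
            assert with_outlier >= plain - 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            fs.spearman_with_outlier([1, 2, 3], [1, 2, 3], max_outliers=1)


class TestComputeEPredict:
    def test_all_zero_weights_annihilate(self, rng):
        assert fs.compute_epredict(rng.normal(size=10) * 1000, np.zeros(10)) == 0.0

    def test_hand_arithmetic(self):
        sauc = [100, 50, 999] + [0] * 7
        weights = [2, 1, 0] + [0] * 7
        assert fs.compute_epredict(sauc, weights) == 250.0

    def test_negative_sum_clipped_to_zero(self):
        assert fs.compute_epredict([-500.0], [1]) == 0.0

    def test_nonspecific_flag_forces_zero(self):
        assert fs.compute_epredict([1000.0], [2], nonspecific=True) == 0.0

    def test_positively_homogeneous_before_clipping(self, rng):
        sauc = rng.normal(size=10) * 100
        w = rng.integers(0, 3, 10)
        base = float(w @ sauc)
        assert float(w @ (3 * sauc)) == pytest.approx(3 * base)


def _naive_optimize(S, y, markers):
    """Independent brute-force reimplementation: itertools + scipy only."""
    hits = []
    for w in itertools.product((0, 1, 2), repeat=S.shape[1]):
        e = np.maximum(S @ np.array(w, dtype=float), 0.0)
        rhos = []
        r = spearmanr(e, y).statistic
        if not np.isnan(r):
            rhos.append(r)
        for drop in range(len(y)):
            keep = np.arange(len(y)) != drop
            r = spearmanr(e[keep], y[keep]).statistic
            if not np.isnan(r):
                rhos.append(r)
        if rhos and max(rhos) >= 1 - 1e-9:
            hits.append(w)
    if not hits:
        return None
    hits = np.array(hits)
    weights = []
    for m in range(S.shape[1]):
        counts = [(hits[:, m] == lvl).sum() for lvl in (0, 1, 2)]
        weights.append(int(np.argmax(counts)))
    return len(hits), weights


class TestOptimizeWeights:
    def test_matches_naive_bruteforce_on_small_problems(self, rng):
        """Implementation agrees with an independent itertools+scipy
        enumeration for <= 3 markers x <= 6 drugs."""
        for trial in range(8):
            n_drugs = int(rng.integers(4, 7))
            n_markers = int(rng.integers(1, 4))
            S = rng.normal(size=(n_drugs, n_markers)) * 100
            y = rng.normal(size=n_drugs)
            markers = [f"m{i}" for i in range(n_markers)]
            drugs = [f"d{i}" for i in range(n_drugs)]
            sauc = fs.SAUCMatrix(pd.DataFrame(S, index=drugs, columns=markers))
            expected = _naive_optimize(S, y, markers)
            if expected is None:
                with pytest.raises(OptimizationError):
                    fs.optimize_weights(sauc, _index(drugs, y), "CCl4_treatment")
            else:
                res = fs.optimize_weights(sauc, _index(drugs, y), "CCl4_treatment")
                assert res.rho_achieving_count == expected[0]
                assert res.weights.tolist() == expected[1]

    def test_signal_marker_gets_positive_weight(self):
        """With one marker rank-identical to E_in_vivo and one scrambled,
        the signal marker's optimized weight is strictly positive."""
        drugs = list("abcde")
        sauc = fs.SAUCMatrix(
            pd.DataFrame({"A": [10, 20, 30, 40, 50], "B": [50, 10, 40, 20, 30]}, index=drugs)
        )
        res = fs.optimize_weights(sauc, _index(drugs, [1, 2, 3, 4, 5]), "CCl4_treatment")
        assert res.weights["A"] in (1, 2)
        assert res.weights["B"] == 0

    def test_histogram_mass_equals_rho_count(self, small_sauc, small_invivo):
        res = fs.optimize_weights(small_sauc, small_invivo, "CCl4_treatment")
        assert (res.weight_frequency.sum(axis=1) == res.rho_achieving_count).all()
        assert res.rho_achieving_count >= 1

    def test_proportional_screen_admits_all_ones_vector(self, small_sauc, small_invivo):
        """All markers respond proportionally to true efficacy, so the
        all-ones combination already ranks drugs perfectly."""
        e = small_sauc.frame.sum(axis=1).clip(lower=0)
        y = small_invivo.for_model("CCl4_treatment").loc[e.index]
        rho, _ = fs.spearman_with_outlier(e.to_numpy(), y.to_numpy())
        assert rho == pytest.approx(1.0)

    def test_failure_reports_best_rho(self):
        drugs = list("abcd")
        sauc = fs.SAUCMatrix(pd.DataFrame({"A": [1.0, 2, 3, 4]}, index=drugs))
        # anti-concordant target: no non-negative combination can match
        with pytest.raises(OptimizationError) as err:
            fs.optimize_weights(sauc, _index(drugs, [4, 3, 2, 1]), "CCl4_treatment")
        assert err.value.best_rho < 1.0

    def test_too_few_shared_drugs_rejected(self):
        sauc = fs.SAUCMatrix(pd.DataFrame({"A": [1.0, 2, 3]}, index=list("abc")))
        with pytest.raises(ValidationError):
            fs.optimize_weights(sauc, _index(list("abc"), [1, 2, 3]), "CCl4_treatment")


class TestEfficacyModelAPI:
    def test_fit_returns_results_with_summary(self, small_sauc, small_invivo):
        results = fs.EfficacyModel(small_sauc, small_invivo, model="CCl4_treatment").fit()
        assert (results.e_predict >= 0).all()
        text = results.summary()
        assert "rho = 1" in text and "drug05" in text

    def test_from_profile_constructor(self, small_profile, directions, small_invivo):
        model = fs.EfficacyModel.from_profile(
            small_profile, directions, small_invivo, model="CCl4_treatment"
        )
        results = model.fit()
        assert set(results.e_predict.index) == set(small_profile.drugs)
        assert not results.nonspecific_flags.any()


class TestNonspecificFlag:
    @pytest.fixture(scope="class")
    def flagged_screen(self):
        drugs = [
            fs.SyntheticDrug("stressor", 0.6, nonspecific_collagen=True),
            fs.SyntheticDrug("genuine", 0.6),
            fs.SyntheticDrug("inert", 0.0),
        ]
        design = fs.ScreenDesign(
            markers=("collagenIII",), cells_per_condition=200, seed=5
        )
        return fs.compute_kr_profile(fs.generate_screen(design, drugs))

    def test_collagen_increasing_drug_is_flagged(self, flagged_screen):
        assert fs.flag_nonspecific(flagged_screen, "stressor") is True

    def test_collagen_decreasing_drug_is_not_flagged(self, flagged_screen):
        assert fs.flag_nonspecific(flagged_screen, "genuine") is False

    def test_null_drug_is_not_flagged(self, flagged_screen):
        assert fs.flag_nonspecific(flagged_screen, "inert") is False

    def test_missing_marker_rejected(self, small_profile):
        with pytest.raises(ConfigurationError):
            fs.flag_nonspecific(small_profile, "drug00", marker="collagenX")

    def test_flag_all_returns_per_drug_series(self, flagged_screen):
        flags = fs.flag_nonspecific_all(flagged_screen)
        assert flags.to_dict() == {"stressor": True, "genuine": False, "inert": False}


class TestWeightRobustness:
    def test_rank_identical_markers_make_every_nonzero_vector_win(self):
        drugs = list("abcde")
        S = pd.DataFrame(
            np.outer([1, 2, 3, 4, 5], np.ones(10)) * 100,
            index=drugs,
            columns=list(fs.DEFAULT_MARKERS),
        )
        frac, rand = fs.weight_robustness(
            fs.SAUCMatrix(S), _index(drugs, [1, 2, 3, 4, 5]), "CCl4_treatment"
        )
        assert frac == pytest.approx((3**10 - 1) / 3**10)
        assert rand is None

    def test_permuted_control_is_computed_when_requested(self, small_sauc, small_invivo):
        frac, rand = fs.weight_robustness(
            small_sauc, small_invivo, "CCl4_treatment", n_random=3, seed=0
        )
        assert 0 <= rand <= 1
        assert frac >= rand
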