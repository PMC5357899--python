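import numpy as np
import pytest

import sirnafusion as sf
from sirnafusion.fusion import (
    FusionModel,
    kernel_sweep,
    out_of_fold_scores,
    train_stage1,
)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(80, 5))
    y = 10.0 + 4.0 * X[:, 0]
    return X, y


class TestStage1:
    def test_exact_linear_fit(self, linear_data):
        X, y = linear_data
        model = train_stage1(X, y, kernel="linear")
        assert sf.pearson(model.predict(X), y) >= 0.999

    def test_constant_targets_within_epsilon_tube(self, linear_data):
        X, _ = linear_data
        model = train_stage1(X, np.full(X.shape[0], 5.0), kernel="linear")
        assert np.allclose(model.predict(X), 5.0, atol=0.1 + 1e-9)

    def test_unsupported_kernel(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError, match="kernel"):
            train_stage1(X, y, kernel="laplace")

    def test_nan_features_rejected(self, linear_data):
        X, y = linear_data
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_stage1(X, y, kernel="linear")


class TestOutOfFoldScores:
    def test_leave_one_out_differs_from_in_sample(self, linear_data):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(10, 3))
        y = X[:, 0] + 0.3 * rng.normal(size=10)
        oof = out_of_fold_scores(X, y, "linear", k=10, seed=0)
        insample = train_stage1(X, y, "linear").predict(X)
        assert not np.allclose(oof, insample)

    def test_same_seed_identical(self, linear_data):
        X, y = linear_data
        a = out_of_fold_scores(X, y, "rbf", k=5, seed=3)
        b = out_of_fold_scores(X, y, "rbf", k=5, seed=3)
        assert np.array_equal(a, b)

    def test_fold_count_validation(self, linear_data):
        X, y = linear_data
        with pytest.raises(ValueError):
            out_of_fold_scores(X, y, "linear", k=1)
        with pytest.raises(ValueError):
            out_of_fold_scores(X, y, "linear", k=len(y) + 1)


class TestTrainFusion:
    def test_quant_only_signal_fusion_not_worse_than_qual(self, small_dataset):
        rng = np.random.default_rng(23)
        n = 120
        quant = rng.normal(size=(n, 12))
        qual = rng.choice([-1.0, 0.0, 1.0], size=(n, 8))
        y = 50 + 10 * quant[:, 0] - 6 * quant[:, 3] + rng.normal(0, 1, n)
        model = sf.train_fusion(quant[:80], qual[:80], y[:80], n_folds=5, seed=0)
        fused = model.predict(quant[80:], qual[80:])
        s_ql = model.stage1_qual.predict(qual[80:])
        assert sf.pearson(fused, y[80:]) >= sf.pearson(s_ql, y[80:])

    def test_split_signal_fusion_beats_branches(self):
        rng = np.random.default_rng(24)
        n = 150
        quant = rng.normal(size=(n, 10))
        qual = rng.choice([-1.0, 1.0], size=(n, 6))
        y = 5 * quant[:, 0] + 3 * quant[:, 1] + 4 * qual[:, 0] + 3 * qual[:, 2]
        y = y + rng.normal(0, 1, n)
        model = sf.train_fusion(quant[:100], qual[:100], y[:100], n_folds=5, seed=1)
        pairs = model.score_pair(quant[100:], qual[100:])
        fused = model.predict(quant[100:], qual[100:])
        branch_best = max(
            sf.pearson(pairs[:, 0], y[100:]), sf.pearson(pairs[:, 1], y[100:])
        )
        assert sf.pearson(fused, y[100:]) >= branch_best - 0.02

    def test_row_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            sf.train_fusion(np.ones((10, 3)), np.ones((9, 2)), np.ones(10))

    def test_stage2_sees_only_out_of_fold_scores(self):
        """Leakage guard: the score pairs stage 2 was fitted on differ from
        in-sample stage-1 predictions whenever the signal is nontrivial."""
        rng = np.random.default_rng(25)
        n = 60
        quant = rng.normal(size=(n, 6))
        qual = rng.choice([-1.0, 1.0], size=(n, 4))
        y = 8 * quant[:, 0] + 2 * qual[:, 0] + rng.normal(0, 0.5, n)
        model = sf.train_fusion(quant, qual, y, n_folds=6, seed=2)
        oof = np.asarray(model.metadata["oof_scores"])
        insample = model.score_pair(quant, qual)
        assert not np.allclose(oof[:, 0], insample[:, 0])
        assert not np.allclose(oof[:, 1], insample[:, 1])


class TestPredict:
    def test_decomposes_through_score_pair(self, fitted_results, small_dataset):
        records, mrnas, _ = small_dataset
        fusion = fitted_results.fusion
        quant, qual = sf.featurize_records(records[:4], mrnas)
        pairs = fusion.score_pair(quant, qual)
        direct = fusion.predict(quant, qual)
        assert np.array_equal(direct, fusion.stage2.predict(pairs))

    def test_duplicated_record_identical_predictions(self, fitted_results, small_dataset):
        records, mrnas, _ = small_dataset
        quant, qual = sf.featurize_records([records[0], records[0]], mrnas)
        predictions = fitted_results.fusion.predict(quant, qual)
        assert predictions[0] == predictions[1]

    def test_wrong_width_qual_vector_errors(self, fitted_results):
        fusion = fitted_results.fusion
        with pytest.raises(ValueError):
            fusion.predict(np.ones((1, 275)), np.ones((1, 50)))


class TestSerialization:
    def test_save_load_round_trip(self, fitted_results, small_dataset, tmp_path):
        records, mrnas, _ = small_dataset
        fusion = fitted_results.fusion
        fusion.save(tmp_path / "bundle")
        reloaded = FusionModel.load(tmp_path / "bundle")
        quant, qual = sf.featurize_records(records[:8], mrnas)
        assert np.array_equal(
            reloaded.predict(quant, qual), fusion.predict(quant, qual)
        )


class TestKernelSweep:
    def test_linear_data_won_by_linear_kernel(self):
        rng = np.random.default_rng(26)
        X = rng.normal(size=(120, 6))
        y = 3 * X[:, 0] - 2 * X[:, 1] + 0.1 * rng.normal(size=120)
        rows = kernel_sweep(X[:80], y[:80], X[80:], y[80:], input_name="quant")
        best = max(rows, key=lambda r: r[2])
        assert best[1] == "linear"

    def test_interaction_structure_favors_rbf_over_linear(self):
        rng = np.random.default_rng(27)
        X = rng.choice([-1.0, 1.0], size=(200, 4))
        y = X[:, 0] * X[:, 1] + 0.5 * X[:, 2] * X[:, 3]
        rows = kernel_sweep(X[:140], y[:140], X[140:], y[140:],
                            kernels=["linear", "rbf"], hyper={"C": 10.0})
        pcc = {kernel: p for _, kernel, p in rows}
        assert pcc["rbf"] >= pcc["linear"]

    def test_empty_kernel_list_errors(self):
        with pytest.raises(ValueError):
            kernel_sweep(np.ones((12, 2)), np.ones(12), np.ones((4, 2)),
                         np.ones(4), kernels=[])
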