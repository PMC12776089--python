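"""ROI-weighted loss, balanced folds, optimization and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from tausynth.atlas import Atlas
from tausynth.model import NetworkConfig, SynthesisModel
from tausynth.nn.autodiff import Tensor
from tausynth.phantom import PhantomParams, simulate_cohort
from tausynth.tabular import LeakageError
from tausynth.training import (FoldAssignment, RoiWeights, TrainConfig,
                               assemble_samples, cross_validate, make_folds,
                               roi_weighted_mse, train)
from tausynth import tabular as tb


def cube_atlas():
    """4^3 grid, single ROI covering a 2x2x2 corner (8 of 64 voxels)."""
    lab = np.zeros((4, 4, 4), dtype=int)
    lab[:2, :2, :2] = 1
    tab = pd.DataFrame([{"id": 1, "name": "a", "hemisphere": "left",
                         "lobe": "temporal", "braak_onset_stage": 1,
                         "in_meta_temp": 1}])
    return Atlas(lab, tab, frozenset({1}), (4, 4, 4))


class TestRoiWeightedMse:
    def test_perfect_prediction_is_zero(self, atlas12, rng):
        v = rng.random(atlas12.grid)
        w = RoiWeights.meta_temporal_emphasis(atlas12)
        assert roi_weighted_mse(v, v, atlas12, w) == 0.0

    def test_unit_weights_reduce_to_plain_mse(self, atlas12, rng):
        pred = rng.random(atlas12.grid)
        true = rng.random(atlas12.grid)
        w1 = RoiWeights({r: 1.0 for r in atlas12.roi_ids})
        assert roi_weighted_mse(pred, true, atlas12, w1) == pytest.approx(
            np.mean((pred - true) ** 2), abs=1e-12)

    def test_hand_computed_weighted_loss(self):
        atlas = cube_atlas()
        pred = np.zeros((4, 4, 4))
        true = np.ones((4, 4, 4))  # unit residual everywhere
        loss = roi_weighted_mse(pred, true, atlas, RoiWeights({1: 3.0}))
        assert loss == pytest.approx((3.0 * 8 + 56) / 64, abs=1e-12)  # 1.25

    def test_monotone_in_weights(self, atlas12, rng):
        pred = rng.random(atlas12.grid)
        true = rng.random(atlas12.grid)
        rid = atlas12.roi_ids[0]
        base = {r: 1.0 for r in atlas12.roi_ids}
        lo = roi_weighted_mse(pred, true, atlas12, RoiWeights(base))
        hi = roi_weighted_mse(pred, true, atlas12,
                              RoiWeights({**base, rid: 4.0}))
        assert hi >= lo

    def test_tensor_path_matches_numpy_path(self, atlas12, rng):
        pred = rng.random((2, 1) + atlas12.grid)
        true = rng.random((2, 1) + atlas12.grid)
        w = RoiWeights.meta_temporal_emphasis(atlas12)
        t = roi_weighted_mse(Tensor(pred), true, atlas12, w).item()
        n = roi_weighted_mse(pred[:, 0], true[:, 0], atlas12, w)
        assert t == pytest.approx(n, abs=1e-12)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            RoiWeights({1: 0.0})


class TestMakeFolds:
    def test_exact_stratification_on_balanced_toy(self):
        df = pd.DataFrame({"subject_id": range(10),
                           "meta_temp": np.linspace(1, 2, 10),
                           "abeta": [0, 1] * 5})
        fa = make_folds(df, k=5, seed=3)
        for f in range(5):
            ids = fa.test_ids(f)
            assert len(ids) == 2
            assert df.set_index("subject_id").loc[ids, "abeta"].sum() == 1

    def test_deterministic(self):
        df = pd.DataFrame({"subject_id": range(40),
                           "meta_temp": np.random.default_rng(0).random(40),
                           "abeta": np.random.default_rng(1).integers(0, 2, 40)})
        assert make_folds(df, 5, seed=9).fold_of == make_folds(df, 5, seed=9).fold_of

    def test_partition_and_longitudinal_cohesion(self):
        df = pd.DataFrame({"subject_id": np.repeat(range(20), 2),
                           "meta_temp": np.tile(np.linspace(1, 2, 20), 2),
                           "abeta": np.tile([0, 1] * 10, 2)})
        fa = make_folds(df, k=4, seed=0)
        assert sorted(fa.fold_of) == list(range(20))
        all_ids = [i for f in range(4) for i in fa.test_ids(f)]
        assert sorted(all_ids) == list(range(20))

    def test_balance_beats_unstratified_95th_percentile(self):
        """Stratified fold means of MetaTempTau sit inside the spread of random
        partitions (Monte-Carlo comparison)."""
        rng = np.random.default_rng(5)
        n = 1000
        df = pd.DataFrame({"subject_id": range(n),
                           "meta_temp": rng.gamma(4, 0.35, n),
                           "abeta": rng.integers(0, 2, n)})
        fa = make_folds(df, k=5, seed=1)
        gmean = df["meta_temp"].mean()
        dev = max(abs(row["mean_meta_temp"] - gmean) for _, row in fa.summary.iterrows())
        rand_devs = []
        for rep in range(200):
            perm = rng.permutation(n) % 5
            rand_devs.append(max(abs(df["meta_temp"][perm == f].mean() - gmean)
                                 for f in range(5)))
        assert dev < np.quantile(rand_devs, 0.95)

    def test_more_folds_than_subjects_fails(self):
        df = pd.DataFrame({"subject_id": [1, 2], "meta_temp": [1, 2], "abeta": [0, 1]})
        with pytest.raises(ValueError, match="folds"):
            make_folds(df, k=5)


@pytest.fixture(scope="module")
def tiny_setup():
    """8-subject cohort at 8^3 with fitted auxiliaries, for fast train tests."""
    from tausynth.atlas import build_atlas

    atlas = build_atlas((8, 8, 8), 4, seed=2)
    cohort = simulate_cohort(atlas, PhantomParams(), 24, seed=33)
    aux = tb.fit_auxiliary(tb.cohort_feature_table(cohort),
                           tb.cohort_targets(cohort, atlas),
                           atlas.roi_ids, atlas=atlas, seed=0)
    est = tb.predict_auxiliary(aux, tb.cohort_feature_table(cohort))
    samples = assemble_samples(cohort, est, atlas, imputer=aux.imputer)
    return atlas, cohort, samples


class TestTrain:
    def test_early_stopping_on_flat_validation(self, tiny_setup):
        atlas, _, samples = tiny_setup
        net = SynthesisModel(NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4),
                                           prompt_channels=1, head_channels=2), seed=0)
        cfg = TrainConfig(max_epochs=30, early_stop_patience=5, batch_size=4, seed=0)
        _, hist = train(net, samples[:4], atlas,
                        RoiWeights.meta_temporal_emphasis(atlas), cfg,
                        val_samples=samples[4:6],
                        val_loss_override=lambda epoch: 1.0)
        # epoch 0 sets the best; patience flat epochs then stop
        assert len(hist) == cfg.early_stop_patience + 1

    def test_history_and_best_checkpoint_contract(self, tiny_setup):
        atlas, _, samples = tiny_setup
        net = SynthesisModel(NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4),
                                           prompt_channels=1, head_channels=2), seed=0)
        cfg = TrainConfig(max_epochs=4, early_stop_patience=10, batch_size=4, seed=0)
        net, hist = train(net, samples[:6], atlas,
                          RoiWeights.meta_temporal_emphasis(atlas), cfg,
                          val_samples=samples[6:8])
        assert len(hist) == 4
        assert list(hist.columns) == ["epoch", "train_loss", "val_loss", "lr"]
        # returned model carries the best-validation parameters
        from tausynth.training import _epoch_loss
        final = _epoch_loss(net, samples[6:8], atlas,
                            RoiWeights.meta_temporal_emphasis(atlas), 4)
        assert final == pytest.approx(hist.val_loss.min(), rel=1e-6)

    def test_empty_validation_rejected(self, tiny_setup):
        atlas, _, samples = tiny_setup
        net = SynthesisModel(NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4),
                                           prompt_channels=1, head_channels=2), seed=0)
        with pytest.raises(ValueError, match="validation"):
            train(net, samples[:2], atlas, RoiWeights.meta_temporal_emphasis(atlas),
                  TrainConfig(max_epochs=1), val_samples=[])

    def test_val_overlap_guard(self, tiny_setup):
        atlas, _, samples = tiny_setup
        net = SynthesisModel(NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4),
                                           prompt_channels=1, head_channels=2), seed=0)
        with pytest.raises(LeakageError):
            train(net, samples[:4], atlas, RoiWeights.meta_temporal_emphasis(atlas),
                  TrainConfig(max_epochs=1), val_samples=samples[:1])


class MockConstantModel:
    """Stand-in network returning a constant volume, for metric oracles."""

    def __init__(self, value, grid):
        self.value = value
        self.grid = grid

    def predict(self, mri, cond=None, prompts=None):
        return np.full((mri.shape[0],) + self.grid, self.value)


class TestCrossValidate:
    def test_mock_model_fold_mae_matches_bruteforce(self, tiny_setup):
        atlas, cohort, _ = tiny_setup
        meta = pd.DataFrame({"subject_id": [s.subject_id for s in cohort],
                             "meta_temp": [s.truth.meta_temp for s in cohort],
                             "abeta": [s.truth.abeta_status for s in cohort]})
        fa = make_folds(meta, k=3, seed=0)
        const = 1.3
        res = cross_validate(cohort, atlas, fa,
                             NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4)),
                             TrainConfig(max_epochs=1),
                             model_factory=lambda f: MockConstantModel(const, atlas.grid))
        # every subject appears exactly once out-of-fold
        assert len(res["oof_predictions"]) == len(cohort)
        mask = atlas.brain_mask
        for _, row in res["fold_metrics"].iterrows():
            ids = set(fa.test_ids(int(row["fold"])))
            maes = [np.abs(const - s.tau)[mask].mean()
                    for s in cohort if s.subject_id in ids]
            assert row["mae"] == pytest.approx(np.mean(maes), abs=1e-10)
            assert row["n"] == len(ids)

    def test_leakage_guard_trips_on_contaminated_split(self, tiny_setup):
        atlas, cohort, _ = tiny_setup

        class ContaminatedFolds(FoldAssignment):
            def train_ids(self, fold):  # leaks every subject into training
                return list(self.fold_of)

        meta = pd.DataFrame({"subject_id": [s.subject_id for s in cohort],
                             "meta_temp": [s.truth.meta_temp for s in cohort],
                             "abeta": [s.truth.abeta_status for s in cohort]})
        good = make_folds(meta, k=3, seed=0)
        bad = ContaminatedFolds(good.fold_of, good.k, good.summary)
        with pytest.raises(LeakageError):
            cross_validate(cohort, atlas, bad,
                           NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4)),
                           TrainConfig(max_epochs=1),
                           model_factory=lambda f: MockConstantModel(1.0, atlas.grid))

    def test_held_out_targets_do_not_influence_predictions(self, tiny_setup):
        """Mutating a held-out subject's tau volume leaves its out-of-fold
        prediction bit-identical (no leakage through any stage)."""
        import copy

        atlas, cohort, _ = tiny_setup
        meta = pd.DataFrame({"subject_id": [s.subject_id for s in cohort],
                             "meta_temp": [s.truth.meta_temp for s in cohort],
                             "abeta": [s.truth.abeta_status for s in cohort]})
        fa = make_folds(meta, k=3, seed=0)
        cfg = NetworkConfig(grid=atlas.grid, encoder_channels=(2, 4),
                            prompt_channels=1, head_channels=2)
        tcfg = TrainConfig(max_epochs=1, seed=0)
        res_a = cross_validate(cohort, atlas, fa, cfg, tcfg)
        victim = fa.test_ids(0)[0]
        mutated = copy.deepcopy(cohort)
        for s in mutated:
            if s.subject_id == victim:
                s.tau = s.tau + 5.0
        res_b = cross_validate(mutated, atlas, fa, cfg, tcfg)
        key = (victim, 0.0)
        assert np.array_equal(res_a["oof_predictions"][key],
                              res_b["oof_predictions"][key])
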