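import math

import numpy as np
import pytest

from enhprs.datasets import LabeledSequenceSet, SequenceRecord, SplitSpec, make_splits
from enhprs.encoding import encode_batch
from enhprs.network import NetworkConfig, build_network, l1_norms
from enhprs.synthetic import MotifModel, SyntheticSpec, generate_pretraining_set, pwm_from_consensus
from enhprs.training import (
    ObjectiveConfig,
    ab_initio,
    cross_entropy,
    grid_search,
    objective,
    predict_scores,
    pretrain,
    retrain,
    train,
)

TINY_CFG = NetworkConfig(filter_number=4, filter_length=5, pool_size=3,
                         gru_units_per_direction=4, dense_units=8,
                         dropout_rate=0.1, input_length=60)


def _tiny_spec(seed=0, n_pos=24):
    """One strong planted motif in 60 bp: a separable toy task."""
    return SyntheticSpec(
        shared_motifs=(pwm_from_consensus("m0", "TGACTCACGT", match_prob=0.95,
                                          planting_probability=1.0),),
        tissue_motifs={"t0": pwm_from_consensus("p0", "ATGCAAAT",
                                                planting_probability=1.0)},
        length=60, n_pretrain_pos=n_pos, n_tissue_pos=8, ratio=3, seed=seed,
    )


def _tiny_dataset(seed=0, n_pos=24):
    return generate_pretraining_set(_tiny_spec(seed, n_pos)).sequences


class TestCrossEntropy:
    def test_uninformative_score_gives_ln2(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(math.log(2), rel=1e-12)

    def test_perfect_scores_near_zero(self):
        eps = 1e-9
        y = np.array([1, 0, 1, 0])
        assert cross_entropy(y, np.clip(y.astype(float), eps, 1 - eps)) < 1e-8

    def test_matches_termwise_summation(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 20).astype(float)
        s = rng.uniform(0.01, 0.99, 20)
        expected = -sum(
            yi * math.log(si) + (1 - yi) * math.log(1 - si) for yi, si in zip(y, s)
        ) / 20
        assert cross_entropy(y, s) == pytest.approx(expected, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([], [])


class TestObjective:
    def test_zero_lambdas_reduce_to_cross_entropy(self):
        params = build_network(TINY_CFG, 0)
        data = _tiny_dataset()
        batch = encode_batch(data)
        obj = ObjectiveConfig(lambda1=0, lambda2=0, lambda3=0)
        got = objective(params, TINY_CFG, batch, obj)
        ce = cross_entropy(batch.labels, predict_scores(params, TINY_CFG, batch))
        assert got == pytest.approx(ce, rel=1e-12)

    def test_zero_parameters_balanced_labels(self):
        params = build_network(TINY_CFG, 0)
        for k in params.keys():
            params[k] = np.zeros_like(params[k])
        recs = [SequenceRecord(f"r{i}", "ACGT" * 15, i % 2) for i in range(10)]
        batch = encode_batch(LabeledSequenceSet(recs, fixed_length=60))
        got = objective(params, TINY_CFG, batch, ObjectiveConfig(lambda1=1.0))
        assert got == pytest.approx(math.log(2), rel=1e-9)

    def test_composition_of_cross_entropy_and_l1(self):
        params = build_network(TINY_CFG, 3)
        batch = encode_batch(_tiny_dataset(seed=3))
        obj = ObjectiveConfig(lambda1=0.1, lambda2=0.01, lambda3=0.001)
        got = objective(params, TINY_CFG, batch, obj)
        ce = cross_entropy(batch.labels, predict_scores(params, TINY_CFG, batch))
        n1, n2, n3 = l1_norms(params)
        assert got == pytest.approx(ce + 0.1 * n1 + 0.01 * n2 + 0.001 * n3, rel=1e-12)


class TestTrain:
    def test_single_epoch_selects_epoch_one(self):
        data = _tiny_dataset()
        tr, va, _ = make_splits(data, SplitSpec(seed=0))
        run = train(build_network(TINY_CFG, 0), TINY_CFG, tr, va,
                    ObjectiveConfig(max_epochs=1, seed=0))
        assert run.selected_epoch == 1
        assert len(run.history) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_training_reduces_cross_entropy_on_separable_task(self, seed):
        data = _tiny_dataset(seed=seed, n_pos=36)
        tr, va, _ = make_splits(data, SplitSpec(seed=seed))
        run = train(build_network(TINY_CFG, seed), TINY_CFG, tr, va,
                    ObjectiveConfig(max_epochs=8, seed=seed))
        assert run.history[run.selected_epoch - 1].train_ce < run.initial_train_ce

    def test_selected_epoch_minimizes_validation_objective(self):
        # tiny training set + many epochs: the validation objective rises
        # after the early optimum, so the last epoch must not be returned
        data = _tiny_dataset(seed=5, n_pos=12)
        tr, va, _ = make_splits(data, SplitSpec(seed=5))
        obj = ObjectiveConfig(max_epochs=25, learning_rate=5e-3, seed=5)
        run = train(build_network(TINY_CFG, 5), TINY_CFG, tr, va, obj)
        objs = [r.val_objective for r in run.history]
        assert run.selected_epoch == int(np.argmin(objs)) + 1
        assert objs[run.selected_epoch - 1] == min(objs)
        # returned parameters reproduce the recorded optimum
        recomputed = objective(run.parameters, TINY_CFG, encode_batch(va), obj)
        assert recomputed == pytest.approx(min(objs), rel=1e-9)

    def test_same_seed_reproducible(self):
        data = _tiny_dataset(seed=6)
        tr, va, _ = make_splits(data, SplitSpec(seed=6))
        obj = ObjectiveConfig(max_epochs=3, seed=6)
        a = train(build_network(TINY_CFG, 6), TINY_CFG, tr, va, obj)
        b = train(build_network(TINY_CFG, 6), TINY_CFG, tr, va, obj)
        assert a.selected_epoch == b.selected_epoch
        assert a.parameters.allclose(b.parameters, atol=0)

    def test_overlapping_validation_ids_rejected(self):
        data = _tiny_dataset(seed=7)
        with pytest.raises(ValueError, match="shares"):
            train(build_network(TINY_CFG, 7), TINY_CFG, data, data,
                  ObjectiveConfig(max_epochs=1))


class TestRetrain:
    @pytest.fixture()
    def checkpoint(self):
        params = build_network(TINY_CFG, 8)
        return params, TINY_CFG

    def test_zero_epochs_is_identity(self, checkpoint):
        data = _tiny_dataset(seed=8)
        run = retrain(checkpoint, data, epochs=0)
        assert run.parameters.allclose(checkpoint[0], atol=0)
        assert run.provenance.startswith("warm_start")

    def test_freezing_all_groups_trains_only_output_layer(self, checkpoint):
        data = _tiny_dataset(seed=9)
        run = retrain(checkpoint, data, epochs=2, freeze=("M", "WU", "WM"),
                      obj_cfg=ObjectiveConfig(max_epochs=2, seed=9))
        before = checkpoint[0]
        for k in before.keys():
            same = np.array_equal(run.parameters[k], before[k])
            if k in ("out_w", "out_b"):
                assert not same, f"{k} should have trained"
            else:
                assert same, f"{k} should have stayed frozen"

    def test_input_length_mismatch_rejected(self, checkpoint):
        bad = generate_pretraining_set(_spec_with_length(80)).sequences
        with pytest.raises(ValueError, match="fixed_length"):
            retrain(checkpoint, bad, epochs=1)

    def test_checkpoint_file_round_trip(self, checkpoint, tmp_path):
        from enhprs.network import save_checkpoint

        path = tmp_path / "pre.npz"
        save_checkpoint(path, checkpoint[0], checkpoint[1])
        data = _tiny_dataset(seed=10)
        run = retrain(path, data, epochs=0)
        assert run.parameters.allclose(checkpoint[0], atol=0)


def _spec_with_length(length):
    from enhprs.synthetic import SyntheticSpec, pwm_from_consensus

    return SyntheticSpec(
        shared_motifs=(pwm_from_consensus("m0", "TGACTCACGT",
                                          planting_probability=1.0),),
        tissue_motifs={}, length=length, n_pretrain_pos=6, n_tissue_pos=1,
        ratio=2, seed=0,
    )


class TestAbInitio:
    def test_reproducible(self):
        data = _tiny_dataset(seed=11)
        a = ab_initio(data, TINY_CFG, epochs=2, obj_cfg=ObjectiveConfig(seed=11))
        b = ab_initio(data, TINY_CFG, epochs=2, obj_cfg=ObjectiveConfig(seed=11))
        assert a.parameters.allclose(b.parameters, atol=0)
        assert a.provenance == "ab_initio"

    @pytest.mark.parametrize("epochs", [1, 2])
    def test_fixed_budget_runs_exactly_n_epochs(self, epochs):
        data = _tiny_dataset(seed=12)
        run = ab_initio(data, TINY_CFG, epochs=epochs,
                        obj_cfg=ObjectiveConfig(seed=12))
        assert len(run.history) == epochs


class TestPretrainStage:
    def test_checkpoint_written_and_loadable(self, tmp_path):
        from enhprs.network import load_checkpoint

        data = _tiny_dataset(seed=13, n_pos=24)
        out = tmp_path / "pre.npz"
        with pytest.warns(UserWarning, match="1:10"):
            result = pretrain(data, TINY_CFG, ObjectiveConfig(max_epochs=2, seed=13),
                              out_path=out)
        params, cfg, meta = load_checkpoint(out)
        assert cfg == TINY_CFG
        assert meta["stage"] == "pretrain"
        assert params.allclose(result.run.parameters, atol=0)

    @pytest.mark.parametrize("seed", range(3))
    def test_pretraining_learns_planted_motifs(self, seed):
        """On default synthetic pretraining data the held-out AUC is high:
        the generator plants recoverable motifs by construction.  The
        epoch-selected pretraining budget is 25 epochs at this scale."""
        from enhprs.synthetic import default_spec, generate_pretraining_set
        from enhprs.training import fast_profile_config

        spec = default_spec("fast", seed=seed)
        result = pretrain(
            generate_pretraining_set(spec).sequences,
            fast_profile_config(),
            ObjectiveConfig(max_epochs=25, seed=seed),
        )
        assert result.test_report.auc > 0.9


@pytest.fixture(scope="module")
def grid():
    data = _tiny_dataset(seed=14, n_pos=16)
    obj = ObjectiveConfig(max_epochs=1, seed=14)
    return grid_search(
        data, obj, filter_numbers=(2, 4), filter_lengths=(5, 7),
        pool_sizes=(3, 5), base_cfg=TINY_CFG,
    )


class TestGridSearch:

    def test_all_cells_present_and_finite(self, grid):
        stage1 = grid.table[grid.table.stage == "stage1"]
        assert len(stage1) == 4
        assert np.isfinite(grid.table["gm"]).all()
        assert np.isfinite(grid.table["auc"]).all()

    def test_stage_two_never_revaries_filter_number(self, grid):
        stage2 = grid.table[grid.table.stage == "stage2"]
        assert stage2["filter_number"].nunique() == 1
        assert stage2["filter_number"].unique()[0] == grid.best_filter_number
        assert len(stage2) == 4

    def test_best_cell_consistent_with_table(self, grid):
        stage2 = grid.table[grid.table.stage == "stage2"]
        assert grid.best["gm"] == stage2["gm"].max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(_tiny_dataset(), ObjectiveConfig(), filter_numbers=())
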