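import numpy as np
import pytest

from rxnbarrier.data import featurize_reactions
from rxnbarrier.dmpnn import ModelConfig, init_params, FeatureWidths
from rxnbarrier.splits import random_split
from rxnbarrier.synthetic import FixtureConfig, generate
from rxnbarrier.train_eval import (
    Metrics,
    TrainConfig,
    TrainingError,
    evaluate,
    permutation_importance,
    train,
)


def _tiny_sets(fixture_dataset):
    ids = [r.id for r in fixture_dataset.records]
    sp = random_split(ids, fractions=(0.8, 0.1, 0.1), seed=0)
    return fixture_dataset.subset(sp.train), fixture_dataset.subset(sp.validation)


SMALL_MODEL = ModelConfig(hidden_dim=8, depth=2, ffn_layers=2, ffn_hidden_dim=8)


class TestTrain:
    def test_two_epoch_runs_are_bit_identical(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        tc = TrainConfig(epochs=2, batch_size=10, seed=13)
        s1, h1 = train(tr, va, SMALL_MODEL, tc)
        s2, h2 = train(tr, va, SMALL_MODEL, tc)
        assert h1 == h2
        for k in s1.params:
            assert np.array_equal(s1.params[k], s2.params[k])

    def test_zero_learning_rate_leaves_weights_unchanged(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        tc = TrainConfig(epochs=3, batch_size=10, learning_rate=0.0, seed=1)
        state, history = train(tr, va, SMALL_MODEL, tc)
        ref = init_params(
            SMALL_MODEL,
            state.widths,
            seed=int(np.random.default_rng(1).integers(2**31 - 1)),
        )
        for k in state.params:
            assert np.array_equal(state.params[k], ref.params[k])
        assert len({h["val_mae"] for h in history}) == 1  # flat history

    def test_empty_partition_rejected(self, fixture_dataset):
        tr, _ = _tiny_sets(fixture_dataset)
        empty = fixture_dataset.subset([])
        with pytest.raises(TrainingError):
            train(tr, empty, SMALL_MODEL, TrainConfig(epochs=1))
        with pytest.raises(TrainingError):
            train(empty, tr, SMALL_MODEL, TrainConfig(epochs=1))

    def test_best_validation_checkpoint_returned(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        tc = TrainConfig(epochs=4, batch_size=10, seed=2)
        state, history = train(tr, va, SMALL_MODEL, tc)
        best = min(h["val_mae"] for h in history)
        assert evaluate(state, va).mae == pytest.approx(best, abs=1e-9)


class TestEvaluate:
    def test_hand_arithmetic(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        state, _ = train(tr, va, SMALL_MODEL, TrainConfig(epochs=1, batch_size=10, seed=0))
        two = fixture_dataset.subset([r.id for r in fixture_dataset.records[:2]])
        from rxnbarrier.train_eval import predict_dataset

        preds = predict_dataset(state, two)
        # overwrite targets so errors are exactly (0, 3)
        two.records[0].target = preds[0]
        two.records[1].target = preds[1] - 3.0
        m = evaluate(state, two)
        assert m.mae == pytest.approx(1.5)
        assert m.rmse == pytest.approx(np.sqrt(4.5))
        assert m.n == 2

    def test_order_invariance(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        state, _ = train(tr, va, SMALL_MODEL, TrainConfig(epochs=1, batch_size=10, seed=0))
        fwd = evaluate(state, va)
        rev = va.copy()
        rev.records = rev.records[::-1]
        bwd = evaluate(state, rev)
        assert fwd.mae == pytest.approx(bwd.mae) and fwd.rmse == pytest.approx(bwd.rmse)

    def test_rmse_dominates_mae(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        state, _ = train(tr, va, SMALL_MODEL, TrainConfig(epochs=2, batch_size=10, seed=0))
        m = evaluate(state, tr)
        assert m.rmse >= m.mae >= 0

    def test_empty_dataset_rejected(self, fixture_dataset):
        tr, va = _tiny_sets(fixture_dataset)
        state, _ = train(tr, va, SMALL_MODEL, TrainConfig(epochs=1, batch_size=10, seed=0))
        with pytest.raises(ValueError):
            evaluate(state, fixture_dataset.subset([]))


def _informative_extras_dataset(n=300, k=8, seed=21):
    """One extra column linearly carries the barrier; the rest are noise."""
    recs = generate(FixtureConfig(n_reactions=n, noise_sigma=0.0, gamma=0.0, seed=seed))
    ds = featurize_reactions([r.reaction for r in recs])
    rng = np.random.default_rng(seed)
    ds.atom_extra_columns = [f"x{i}" for i in range(k)]
    for rec, fx in zip(ds.records, recs):
        mat = rng.normal(size=(rec.cgr.n_atoms, k))
        mat[:, 0] = (fx.true_barrier - 25.0) / 5.0
        rec.atom_extras = mat
    return ds


@pytest.fixture(scope="module")
def trained():
    ds = _informative_extras_dataset()
    sp = random_split([r.id for r in ds.records], fractions=(0.8, 0.1, 0.1), seed=0)
    config = ModelConfig(
        hidden_dim=16,
        depth=2,
        ffn_layers=2,
        ffn_hidden_dim=16,
        extra_route="route2_plain",
        extra_placement="after_mpnn",
    )
    state, _ = train(
        ds.subset(sp.train),
        ds.subset(sp.validation),
        config,
        TrainConfig(epochs=15, batch_size=25, seed=3),
    )
    return state, ds.subset(sp.test)


class TestPermutationImportance:
    def test_informative_column_ranks_first(self, trained):
        state, test = trained
        report = permutation_importance(state, test, seed=5, repeats=3)
        assert report.ranking[0] == "x0"
        assert report.delta_mae["x0"] > 0

    def test_zero_weight_column_has_exactly_zero_delta(self, trained):
        state, test = trained
        # sever the last extra column from the head: its pooled value can no
        # longer influence the output, so permuting it must do nothing at all
        cut = state.copy()
        col = cut.config.hidden_dim + cut.widths.atom_extra - 1
        cut.params["W_f0"][col, :] = 0.0
        report = permutation_importance(cut, test, seed=6, repeats=2, columns=["x7"])
        assert report.delta_mae["x7"] == 0.0

    def test_constant_column_has_zero_delta(self, trained):
        state, test = trained
        const = test.copy()
        for rec in const.records:
            rec.atom_extras = rec.atom_extras.copy()
            rec.atom_extras[:, 4] = 2.0
        report = permutation_importance(state, const, seed=7, repeats=2, columns=["x4"])
        assert report.delta_mae["x4"] == 0.0


def test_metrics_container_contract():
    m = Metrics(mae=1.0, rmse=2.0, n=5)
    assert m.as_dict() == {"mae": 1.0, "rmse": 2.0, "n": 5}
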