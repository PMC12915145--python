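"""Loss contract, optimizer behaviour, early stopping, determinism,
ensembling and hyperparameter search mechanics."""

import numpy as np
import pytest

from resbind._autodiff import Parameter, Tensor
from resbind.datamodel import RunConfig
from resbind.decoder import Classifier
from resbind.embedding import SyntheticEmbedder
from resbind.synthetic import make_benchmark
from resbind.training import (
    Lookahead,
    RAdam,
    SchemeSpec,
    ensemble_predict,
    grid_search,
    train,
    train_single,
    weighted_ce,
)


class TestWeightedCE:
    def test_w1_equals_plain_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=40)
        y = rng.integers(0, 2, size=40)
        loss = weighted_ce(Tensor(p), y, w=1.0)
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert float(loss.data) == pytest.approx(expected, abs=1e-12)

    def test_weighted_single_residue_value(self):
        # y=1, p=0.5, w=2 -> 2 ln 2
        loss = weighted_ce(Tensor(np.array([0.5])), np.array([1]), w=2.0)
        assert float(loss.data) == pytest.approx(2 * np.log(2.0))

    def test_loss_vanishes_at_perfect_predictions(self):
        p = np.array([1.0 - 1e-9, 1e-9])
        loss = weighted_ce(Tensor(p), np.array([1, 0]), w=3.0)
        assert float(loss.data) < 1e-6

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_ce(Tensor(np.array([0.5])), np.array([1]), w=0.0)

    def test_gradient_through_classifier_matches_finite_differences(self, rng):
        """Autodiff gradient of the loss w.r.t. classifier weights agrees
        with central differences to 1e-4 relative error."""
        clf = Classifier(d_hid=6, rng=rng)
        x = rng.normal(size=(1, 6))
        y = np.array([1])

        def loss_value():
            _, prob = clf(Tensor(x))
            return float(weighted_ce(prob, y, w=2.0).data)

        _, prob = clf(Tensor(x))
        loss = weighted_ce(prob, y, w=2.0)
        loss.backward()
        for param in clf.parameters():
            analytic = param.grad.copy() if param.grad is not None else np.zeros_like(param.data)
            flat = param.data.ravel()
            for i in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[i]
                h = 1e-6
                flat[i] = orig + h
                hi = loss_value()
                flat[i] = orig - h
                lo = loss_value()
                flat[i] = orig
                fd = (hi - lo) / (2 * h)
                assert analytic.ravel()[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestOptimizers:
    def test_radam_descends_on_quadratic(self):
        theta = Parameter(np.array([1.0]))
        opt = RAdam([theta], lr=0.1)
        for _ in range(20):
            opt.zero_grad()
            (theta * theta).sum().backward()
            opt.step()
        assert abs(theta.data[0]) < 1.0

    def test_lookahead_alpha_one_matches_inner_at_sync(self):
        def run(alpha):
            theta = Parameter(np.array([1.0]))
            inner = RAdam([theta], lr=0.05)
            opt = Lookahead(inner, k=5, alpha=alpha) if alpha is not None else inner
            for _ in range(10):  # two sync cycles
                opt.zero_grad()
                (theta * theta).sum().backward()
                opt.step()
            return theta.data.copy()

        np.testing.assert_allclose(run(alpha=1.0), run(alpha=None), atol=1e-12)

    def test_lookahead_interpolation_after_k_steps(self):
        theta = Parameter(np.array([4.0]))
        opt = Lookahead(RAdam([theta], lr=0.1), k=5, alpha=0.5)
        slow0 = opt.slow[0].copy()
        fast = None
        for step in range(5):
            opt.zero_grad()
            (theta * theta).sum().backward()
            if step == 4:  # capture fast weights just before the sync
                opt.inner.step()
                fast = theta.data.copy()
                opt.counter += 1
                # manually trigger the sync the step() would have done
                for slow, p in zip(opt.slow, opt.inner.params):
                    slow += opt.alpha * (p.data - slow)
                    p.data = slow.copy()
                break
            opt.step()
        np.testing.assert_allclose(theta.data, 0.5 * (slow0 + fast), atol=1e-12)


@pytest.fixture(scope="module")
def tiny_benchmark():
    tr, va, te, _ = make_benchmark(14, 6, 4, length_range=(30, 45), seed=42)
    proteins = tr.proteins + va.proteins + te.proteins
    tracks = {**tr.tracks, **va.tracks}
    embedder = SyntheticEmbedder(d_p=64, seed=42, noise_sd=0.1)
    return tr, va, te, proteins, tracks, embedder


@pytest.fixture(scope="module")
def tiny_config():
    return RunConfig(d_hid=16, n_heads=4, d_ff=32, n_enc_layers=1, n_dec_layers=1,
                     window_size=7, dropout_rate=0.0, batch_size=64, seed=5)


class TestTrainSingle:
    def test_loss_decreases_on_small_dataset(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        result = train_single(proteins, tracks, embedder, tiny_config,
                              tuple(tr.ids()), tuple(va.ids()),
                              max_epochs=5, seed=5)
        history = result.report["history"]
        assert history[4]["train_loss"] < history[0]["train_loss"]

    def test_frozen_validation_stops_at_patience_plus_one(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        result = train_single(
            proteins, tracks, embedder, tiny_config,
            tuple(tr.ids()[:6]), tuple(va.ids()[:2]),
            max_epochs=50, patience=10, seed=5,
            validation_scorer=lambda model, epoch: 0.5,  # frozen score
            residues_per_protein=4,
        )
        assert result.report["epochs_run"] == 11
        assert result.best_epoch == 1

    def test_same_seed_bitwise_identical_checkpoints(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        kwargs = dict(max_epochs=2, seed=7, residues_per_protein=8)
        r1 = train_single(proteins, tracks, embedder, tiny_config,
                          tuple(tr.ids()[:6]), tuple(va.ids()[:2]), **kwargs)
        r2 = train_single(proteins, tracks, embedder, tiny_config,
                          tuple(tr.ids()[:6]), tuple(va.ids()[:2]), **kwargs)
        for a, b in zip(r1.model.state_arrays(), r2.model.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_no_positives_in_training_split_rejected(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        empty_tracks = {
            pid: type(t)(pid, np.zeros_like(t.labels), t.mask)
            for pid, t in tracks.items()
        }
        with pytest.raises(ValueError, match="no positive"):
            train_single(proteins, empty_tracks, embedder, tiny_config,
                         tuple(tr.ids()[:4]), tuple(va.ids()[:2]), max_epochs=1)

    def test_default_loss_weight_is_class_ratio(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        result = train_single(proteins, tracks, embedder, tiny_config,
                              tuple(tr.ids()[:6]), tuple(va.ids()[:2]),
                              max_epochs=1, seed=5, residues_per_protein=4)
        ids = tr.ids()[:6]
        pos = sum(tracks[i].n_positive for i in ids)
        neg = sum(tracks[i].n_effective - tracks[i].n_positive for i in ids)
        assert result.report["loss_weight"] == pytest.approx(neg / pos)


class TestSchemes:
    def test_repeated_splits_returns_r_models(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        sub_tracks = {pid: tracks[pid] for pid in (*tr.ids()[:8], *va.ids()[:2])}
        scheme = SchemeSpec(kind="repeated_splits", R=2, seed=3)
        results = train(proteins, sub_tracks, embedder, tiny_config, scheme,
                        max_epochs=2, residues_per_protein=4)
        assert len(results) == 2
        assert results[0].report["seed"] != results[1].report["seed"]

    def test_kfold_then_retrain_reports_folds(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        sub_tracks = {pid: tracks[pid] for pid in tr.ids()[:8]}
        scheme = SchemeSpec(kind="kfold_then_retrain", K=2, seed=3)
        result = train(proteins, sub_tracks, embedder, tiny_config, scheme,
                       max_epochs=2, residues_per_protein=4)
        assert len(result.report["fold_valid_mcc"]) == 2

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            SchemeSpec(kind="bootstrap")


class TestEnsemble:
    def test_single_model_identity(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        from resbind.model import BindingSiteModel, predict_protein

        model = BindingSiteModel(tiny_config, d_p=64, seed=1)
        protein = te.proteins[0]
        single = predict_protein(protein, embedder, model)
        ens = ensemble_predict([model], protein, embedder)
        np.testing.assert_allclose(single.probabilities(), ens.probabilities())

    def test_mean_probability_and_order_invariance(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        from resbind.model import BindingSiteModel

        m1 = BindingSiteModel(tiny_config, d_p=64, seed=1)
        m2 = BindingSiteModel(tiny_config, d_p=64, seed=2)
        protein = te.proteins[0]
        e12 = ensemble_predict([m1, m2], protein, embedder).probabilities()
        e21 = ensemble_predict([m2, m1], protein, embedder).probabilities()
        p1 = m1.predict_probabilities(embedder(protein))
        p2 = m2.predict_probabilities(embedder(protein))
        np.testing.assert_allclose(e12, (p1 + p2) / 2, atol=1e-12)
        np.testing.assert_allclose(e12, e21, atol=1e-12)

    def test_mismatched_configs_rejected(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        from resbind.model import BindingSiteModel

        m1 = BindingSiteModel(tiny_config, d_p=64, seed=1)
        m2 = BindingSiteModel(tiny_config.replace(window_size=9), d_p=64, seed=2)
        with pytest.raises(ValueError, match="configuration"):
            ensemble_predict([m1, m2], te.proteins[0], embedder)


class TestGridSearch:
    def test_singleton_grid_returns_that_config(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        sub_tracks = {pid: tracks[pid] for pid in (*tr.ids()[:6], *va.ids()[:2])}
        best, results = grid_search(
            proteins, sub_tracks, embedder, tiny_config,
            {"learning_rate": [0.002]}, SchemeSpec(kind="holdout", seed=1),
            max_epochs=1, residues_per_protein=4,
        )
        assert best.learning_rate == 0.002
        assert len(results) == 1

    def test_empty_grid_rejected(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        with pytest.raises(ValueError):
            grid_search(proteins, tracks, embedder, tiny_config, {},
                        SchemeSpec(kind="holdout"))

    def test_non_tunable_key_rejected(self, tiny_benchmark, tiny_config):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        with pytest.raises(ValueError, match="grid keys"):
            grid_search(proteins, tracks, embedder, tiny_config,
                        {"d_hid": [32]}, SchemeSpec(kind="holdout"))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tiny_benchmark, tiny_config, tmp_path):
        tr, va, te, proteins, tracks, embedder = tiny_benchmark
        from resbind.model import BindingSiteModel, load_checkpoint, save_checkpoint

        model = BindingSiteModel(tiny_config, d_p=64, seed=4)
        save_checkpoint(model, tmp_path / "m.npz")
        loaded = load_checkpoint(tmp_path / "m.npz")
        emb = embedder(te.proteins[0])
        np.testing.assert_array_equal(
            model.predict_probabilities(emb), loaded.predict_probabilities(emb)
        )
        assert loaded.config.to_dict() == tiny_config.to_dict()
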