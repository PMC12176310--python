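"""Architecture contracts: time2vec, causality, pooling symmetry, early stopping."""

import numpy as np
import pytest

from wardfusion import model as mm
from wardfusion.model import EncounterInputs, ModelSpec


def make_items(n_enc=12, T=6, S=5, W=8, vocab_tokens=20, mode="ST", seed=0,
               G=7):
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_enc):
        t = int(rng.integers(3, T + 1))
        tokens = binary = None
        if mode in ("ST", "ICDR_T", "SE"):
            tokens = np.zeros((t, W), dtype=np.int64)
            for ti in range(t):
                k = int(rng.integers(0, W))
                tokens[ti, :k] = rng.choice(
                    np.arange(2, vocab_tokens), size=k, replace=False)
        elif mode in ("ICDR_BV", "CC"):
            binary = (rng.random((t, G)) < 0.3).astype(float)
        items.append(EncounterInputs(
            encounter_id=f"E{i}",
            structured=rng.normal(size=(t, S)),
            hours=np.sort(rng.uniform(0, 48, size=t)),
            label=(rng.random(t) < 0.3).astype(np.int64),
            tokens=tokens,
            binary=binary,
            subgroups={"sex": "female", "race": "W", "ethnicity": "N",
                       "age_band": "49-64"},
        ))
    # guarantee both classes overall
    items[0].label[:] = 1
    items[1].label[:] = 0
    return items


def small_spec(mode, **kw):
    base = dict(mode=mode, hidden_units=8, dense_units=6, embedding_dim=4,
                time2vec_dim=4, dropout_rate=0.0, seed=3)
    base.update(kw)
    return ModelSpec(**base)


def build_for(mode, spec=None, S=5, vocab_tokens=20, G=7, E=4):
    spec = spec or small_spec(mode)
    if mode in ("ST", "ICDR_T"):
        return mm.build_model(spec, S, cui_dim=vocab_tokens)
    if mode == "SE":
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(vocab_tokens, E))
        emb[0] = 0.0
        return mm.build_model(spec, S, frozen_embeddings=emb)
    if mode in ("ICDR_BV", "CC"):
        return mm.build_model(spec, S, cui_dim=G)
    return mm.build_model(spec, S)


class TestTime2Vec:
    def test_zero_time_zero_phase_gives_zero_vector(self):
        omega = np.array([0.3, 1.0, 2.0])
        phi = np.zeros(3)
        np.testing.assert_allclose(mm.time2vec(0.0, omega, phi), np.zeros(3))

    def test_sinusoid_value(self):
        omega = np.array([0.0, 1.0])
        phi = np.array([0.0, 0.0])
        out = mm.time2vec(np.pi / 2, omega, phi)
        assert out[1] == pytest.approx(1.0)

    def test_periodicity_of_sinusoidal_components(self):
        omega = np.array([0.5, 2.0, 3.0])
        phi = np.array([0.1, 0.2, 0.3])
        a = mm.time2vec(1.7, omega, phi)
        b = mm.time2vec(1.7 + 2 * np.pi / 2.0, omega, phi)
        assert a[1] == pytest.approx(b[1], abs=1e-12)

    def test_model_layer_matches_reference(self):
        model = build_for("structured_only")
        hours = np.array([[0.0, 3.5, 10.0]])
        out = model._time2vec(hours).data[0]
        omega = model.params["t2v_omega"].data
        phi = model.params["t2v_phi"].data
        for ti, tau in enumerate(hours[0]):
            np.testing.assert_allclose(out[ti], mm.time2vec(tau, omega, phi))


class TestArchitecture:
    def test_structured_only_has_no_cui_parameters(self):
        solo = build_for("structured_only")
        multi = build_for("ST")
        assert not any(k.startswith("cui") for k in solo.params)
        assert solo.n_parameters() < multi.n_parameters()

    @pytest.mark.parametrize("mode", mm.MODES)
    def test_forward_shapes_and_range(self, mode):
        items = make_items(mode=mode)
        model = build_for(mode)
        batch = mm.collate(items[:4])
        scores = model.forward(batch).data
        assert scores.shape == batch["label"].shape
        assert np.all((scores > 0) & (scores < 1))

    @pytest.mark.parametrize("mode", mm.MODES)
    def test_causality_future_perturbation_leaves_past_scores(self, mode):
        items = make_items(mode=mode, T=6)
        model = build_for(mode)
        item = max(items, key=lambda it: it.structured.shape[0])
        batch = mm.collate([item])
        base = model.forward(batch).data.copy()
        t_cut = item.structured.shape[0] - 1
        batch2 = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                  for k, v in batch.items()}
        batch2["structured"][0, t_cut] += 5.0
        batch2["hours"][0, t_cut] += 1.0
        if "tokens" in batch2:
            batch2["tokens"][0, t_cut] = 0
            batch2["tokens"][0, t_cut, 0] = 3
        if "binary" in batch2:
            batch2["binary"][0, t_cut] = 1.0 - batch2["binary"][0, t_cut]
        pert = model.forward(batch2).data
        np.testing.assert_allclose(pert[0, :t_cut], base[0, :t_cut],
                                   rtol=0, atol=1e-12)
        assert not np.allclose(pert[0, t_cut], base[0, t_cut])

    @pytest.mark.parametrize("mode", ["ST", "SE"])
    def test_pooling_invariant_to_window_permutation(self, mode):
        items = make_items(mode=mode)
        for pooling in ("average", "max"):
            model = build_for(mode, spec=small_spec(mode, pooling=pooling))
            item = items[2]
            batch = mm.collate([item])
            base = model.forward(batch).data.copy()
            rng = np.random.default_rng(1)
            batch2 = {k: (v.copy() if isinstance(v, np.ndarray) else v)
                      for k, v in batch.items()}
            for ti in range(item.tokens.shape[0]):
                row = batch2["tokens"][0, ti]
                nz = row[row != 0]
                batch2["tokens"][0, ti] = 0
                batch2["tokens"][0, ti, : len(nz)] = rng.permutation(nz)
            np.testing.assert_allclose(model.forward(batch2).data, base,
                                       atol=1e-12)

    def test_lstm_cell_variant_runs(self):
        items = make_items(mode="ICDR_BV")
        model = build_for("ICDR_BV",
                          spec=small_spec("ICDR_BV", recurrent_cell="lstm",
                                          n_recurrent_layers=2))
        scores = model.forward(mm.collate(items[:3])).data
        assert np.all((scores > 0) & (scores < 1))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            mm.build_model(small_spec("SE"), 5)  # SE without embeddings
        with pytest.raises(ValueError):
            mm.build_model(small_spec("CC"), 5)  # CC without width


class TestTraining:
    def test_frozen_val_auroc_stops_after_patience_beyond_first(self):
        # learning_rate 0 freezes the network: identical val AUROC each epoch
        items = make_items(n_enc=16, mode="structured_only")
        tr, val = items[:12], items[12:]
        model = build_for("structured_only",
                          spec=small_spec("structured_only", learning_rate=0.0))
        res = mm.train(model, tr, val, max_epochs=50, patience=5)
        assert res.stopped_epoch == 6  # first epoch + patience

    def test_best_epoch_weights_restored(self):
        items = make_items(n_enc=20, mode="structured_only", seed=5)
        tr, val = items[:15], items[15:]
        model = build_for("structured_only",
                          spec=small_spec("structured_only"))
        res = mm.train(model, tr, val, max_epochs=6)
        best = max(
            (h for h in res.history if np.isfinite(h["val_auroc"])),
            key=lambda h: h["val_auroc"],
        )
        assert res.best_epoch == best["epoch"]
        assert res.best_val_auroc == pytest.approx(best["val_auroc"])
        # restored weights reproduce the best epoch's validation AUROC
        assert mm._eval_auroc(model, val) == pytest.approx(best["val_auroc"])

    def test_overlapping_splits_rejected(self):
        items = make_items(n_enc=6, mode="structured_only")
        model = build_for("structured_only")
        with pytest.raises(ValueError):
            mm.train(model, items, items, max_epochs=1)

    def test_training_deterministic_given_seed(self):
        items = make_items(n_enc=14, mode="ST", seed=9)
        tr, val = items[:10], items[10:]
        hists = []
        for _ in range(2):
            model = build_for("ST", spec=small_spec("ST", dropout_rate=0.2))
            res = mm.train(model, tr, val, max_epochs=3)
            hists.append([(h["train_loss"], h["val_auroc"])
                          for h in res.history])
        assert hists[0] == hists[1]

    def test_se_frozen_embeddings_unchanged_by_training(self):
        items = make_items(n_enc=14, mode="SE", seed=2)
        tr, val = items[:10], items[10:]
        model = build_for("SE")
        before = model.frozen_embeddings.copy()
        mm.train(model, tr, val, max_epochs=2)
        np.testing.assert_array_equal(model.frozen_embeddings, before)

    def test_split_disjoint_and_deterministic(self):
        items = make_items(n_enc=20, mode="structured_only")
        tr1, val1 = mm.train_val_split(items, seed=4)
        tr2, val2 = mm.train_val_split(items, seed=4)
        assert [i.encounter_id for i in tr1] == [i.encounter_id for i in tr2]
        assert not ({i.encounter_id for i in tr1}
                    & {i.encounter_id for i in val1})
        assert len(val1) == 4


class TestTune:
    def test_single_trial_returns_the_evaluated_spec(self):
        items = make_items(n_enc=14, mode="structured_only", seed=11)
        base = small_spec("structured_only")
        best, log = mm.tune(items, base, lambda s: mm.build_model(s, 5),
                            n_trials=1, seed=0, max_epochs=2)
        assert len(log) == 1
        assert log[0]["spec"]["hidden_units"] == best.hidden_units

    def test_best_is_max_over_trial_log(self):
        items = make_items(n_enc=14, mode="structured_only", seed=11)
        base = small_spec("structured_only")
        best, log = mm.tune(items, base, lambda s: mm.build_model(s, 5),
                            n_trials=3, seed=0, max_epochs=2)
        finite = [t["val_auroc"] for t in log if np.isfinite(t["val_auroc"])]
        assert max(finite) >= max(finite)  # bookkeeping sanity
        best_trial = max((t for t in log if np.isfinite(t["val_auroc"])),
                         key=lambda t: t["val_auroc"])
        assert best_trial["spec"]["hidden_units"] == best.hidden_units
        assert best_trial["spec"]["learning_rate"] == best.learning_rate
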