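"""Encoder correctness (vs a loop-based oracle), predictions, training, metrics."""

import numpy as np
import pytest

from fluorscreen import autodiff as ad
from fluorscreen.dmpnn import (
    EncoderConfig,
    GraphBatch,
    Model,
    Sample,
    encode_batch,
    encode_graph,
    evaluate,
    init_params,
    load_model,
    predict_activity,
    predict_property,
    save_model,
    train_model,
)
from fluorscreen.errors import (
    DataError,
    TaskMismatchError,
)
from fluorscreen.molgraph import WavelengthPair, featurize_molecule

HIDDEN = 12


def small_cfg(task="classification", **kw):
    defaults = dict(task=task, depth=3, hidden=HIDDEN, solvent_hidden=HIDDEN,
                    ffn_hidden=HIDDEN, epochs=2, seed=0, batch_size=8)
    defaults.update(kw)
    return EncoderConfig(**defaults)


def oracle_encode(g, cfg, params, prefix=""):
    """Straight-line evaluation of the update equations, one edge at a time.

    h0_e = relu(W_in [x_src ++ f_e]); m_e = sum of incoming h at src(e)
    excluding the reverse edge; h_e = relu(W_h [h_e ++ m_e]); readout
    a_v = relu(W_a [x_v ++ sum incoming]); embedding = mean over atoms.
    """
    w = {k: np.asarray(t.data, dtype=np.float64) for k, t in params.weights.items()}
    W_in, b_in = w[prefix + "W_in"], w[prefix + "b_in"]
    W_h = np.vstack([w[prefix + "W_h_self"], w[prefix + "W_h_msg"]])
    b_h = w[prefix + "b_h"]
    W_a = np.vstack([w[prefix + "W_a_x"], w[prefix + "W_a_in"]])
    b_a = w[prefix + "b_a"]
    relu = lambda v: np.maximum(v, 0.0)  # noqa: E731

    E, hidden = g.n_edges, W_in.shape[1]
    h = np.zeros((E, hidden))
    for e in range(E):
        x = np.concatenate([g.atom_features[g.edge_src[e]], g.bond_features[e]])
        h[e] = relu(x @ W_in + b_in)
    for _ in range(cfg.depth):
        new = np.zeros_like(h)
        for e in range(E):
            m = np.zeros(hidden)
            for e2 in g.incoming[g.edge_src[e]]:
                if e2 != g.reverse_index[e]:
                    m += h[e2]
            new[e] = relu(np.concatenate([h[e], m]) @ W_h + b_h)
        h = new
    a = np.zeros((g.n_atoms, hidden))
    for v in range(g.n_atoms):
        inc = np.zeros(hidden)
        for e in g.incoming[v]:
            inc += h[e]
        a[v] = relu(np.concatenate([g.atom_features[v], inc]) @ W_a + b_a)
    return a.mean(axis=0) if cfg.aggregation == "mean" else a.sum(axis=0)


SMALL_MOLECULES = ["C", "CC", "CCC", "C=C", "C#N", "CCO", "CC=O", "C1CC1",
                   "C1CCC1", "CC(C)O", "C1CCCC1", "O=C=O"]


@pytest.mark.parametrize("smiles", SMALL_MOLECULES)
def test_encoder_matches_loop_oracle(smiles):
    cfg = small_cfg()
    params = init_params(cfg, seed=11, dtype=np.float64)
    g = featurize_molecule(smiles)
    fast = encode_batch(GraphBatch([g], dtype=np.float64), cfg, params).data[0]
    slow = oracle_encode(g, cfg, params)
    assert np.max(np.abs(fast - slow)) < 1e-6


def test_propane_depth2_oracle_equivalence():
    cfg = small_cfg(depth=2)
    params = init_params(cfg, seed=3, dtype=np.float64)
    g = featurize_molecule("CCC")
    fast = encode_batch(GraphBatch([g], dtype=np.float64), cfg, params).data[0]
    assert np.max(np.abs(fast - oracle_encode(g, cfg, params))) < 1e-6


def test_batched_encoding_equals_individual_encoding():
    cfg = small_cfg()
    params = init_params(cfg, seed=5, dtype=np.float64)
    graphs = [featurize_molecule(s) for s in ["CCO", "c1ccccc1", "C"]]
    batched = encode_batch(GraphBatch(graphs, dtype=np.float64), cfg, params).data
    for i, g in enumerate(graphs):
        single = encode_batch(GraphBatch([g], dtype=np.float64), cfg, params).data[0]
        np.testing.assert_allclose(batched[i], single, atol=1e-10)


def test_single_atom_molecule_embedding_uses_zero_messages():
    cfg = small_cfg()
    params = init_params(cfg, seed=2, dtype=np.float64)
    g = featurize_molecule("C")
    emb = encode_graph(g, cfg, params)
    w = params.weights
    expected = np.maximum(
        np.concatenate([g.atom_features[0], np.zeros(HIDDEN)])
        @ np.vstack([w["W_a_x"].data, w["W_a_in"].data]) + w["b_a"].data, 0.0
    )
    np.testing.assert_allclose(emb, expected, atol=1e-10)


def test_depth_zero_uses_initial_edge_states_only():
    cfg = small_cfg(depth=0)
    params = init_params(cfg, seed=7, dtype=np.float64)
    g = featurize_molecule("CCO")
    fast = encode_batch(GraphBatch([g], dtype=np.float64), cfg, params).data[0]
    assert np.max(np.abs(fast - oracle_encode(g, cfg, params))) < 1e-6


def test_alternative_update_rule_runs_and_differs():
    g = featurize_molecule("CCO")
    a = encode_graph(g, small_cfg(), init_params(small_cfg(), seed=1))
    cfg_alt = small_cfg(update_rule="input_add")
    b = encode_graph(g, cfg_alt, init_params(cfg_alt, seed=1))
    assert a.shape == b.shape and not np.allclose(a, b)


def test_permutation_invariance_of_predictions():
    from rdkit import Chem

    cfg = small_cfg()
    params = init_params(cfg, seed=13)
    rng = np.random.default_rng(42)
    pair = WavelengthPair(400.0, 500.0)
    base_smiles = ["COc1ccc(C=CC#N)cc1", "CC(=O)Oc1ccccc1C(=O)O", "c1ccc2ccccc2c1",
                   "CN(C)c1ccc(C=O)cc1"]
    for smiles in base_smiles:
        mol = Chem.MolFromSmiles(smiles)
        ref = predict_activity(featurize_molecule(smiles), pair, cfg, params)
        for _ in range(5):
            perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
            alt = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
            score = predict_activity(featurize_molecule(alt), pair, cfg, params)
            assert abs(score - ref) < 1e-5


class TestPredictActivity:
    def test_zero_output_layer_gives_half(self):
        cfg = small_cfg()
        params = init_params(cfg, seed=0)
        params.weights["ffn_Wout"].data[...] = 0.0
        params.weights["ffn_bout"].data[...] = 0.0
        g = featurize_molecule("CCO")
        assert predict_activity(g, WavelengthPair(400, 500), cfg, params) == 0.5

    def test_score_increases_with_output_bias(self):
        cfg = small_cfg()
        params = init_params(cfg, seed=0)
        g = featurize_molecule("CCO")
        scores = []
        for bias in (-1.0, 0.0, 1.0):
            params.weights["ffn_bout"].data[...] = bias
            scores.append(predict_activity(g, WavelengthPair(400, 500), cfg, params))
        assert scores == sorted(scores) and scores[0] < scores[-1]

    def test_deterministic_across_runs(self):
        cfg = small_cfg()
        params = init_params(cfg, seed=4)
        g = featurize_molecule("c1ccccc1O")
        s1 = predict_activity(g, WavelengthPair(350, 450), cfg, params)
        s2 = predict_activity(g, WavelengthPair(350, 450), cfg, params)
        assert s1 == s2

    def test_regression_config_rejected(self):
        cfg = small_cfg("regression")
        with pytest.raises(TaskMismatchError):
            predict_activity(featurize_molecule("C"), WavelengthPair(400, 500),
                             cfg, init_params(cfg))


class TestPredictProperty:
    def test_solvent_branch_is_live(self):
        cfg = small_cfg("regression")
        params = init_params(cfg, seed=9)
        g = featurize_molecule("c1ccc2ccccc2c1")
        water = predict_property(g, "O", cfg, params)
        toluene = predict_property(g, "Cc1ccccc1", cfg, params)
        assert water != toluene

    def test_zero_ffn_returns_training_target_mean(self):
        cfg = small_cfg("regression")
        params = init_params(cfg, seed=0)
        params.weights["ffn_Wout"].data[...] = 0.0
        params.weights["ffn_bout"].data[...] = 0.0
        params.target_mean, params.target_sd = 512.5, 40.0
        assert predict_property(featurize_molecule("CCO"), "O", cfg, params) \
            == pytest.approx(512.5)

    def test_classification_config_rejected(self):
        cfg = small_cfg()
        with pytest.raises(TaskMismatchError):
            predict_property(featurize_molecule("C"), "O", cfg, init_params(cfg))


class TestTraining:
    def test_single_molecule_memorization(self):
        samples = [Sample("c1ccccc1", WavelengthPair(400, 500), 1.0),
                   Sample("CCCCCC", WavelengthPair(400, 500), 0.0)]
        cfg = small_cfg(epochs=200, init_lr=0.01, batch_size=2)
        params, hist = train_model(samples, samples, cfg)
        assert hist.train_loss[-1] < 0.05

    def test_same_seed_gives_identical_history(self):
        samples = [Sample(s, WavelengthPair(400, 500), float(i % 2))
                   for i, s in enumerate(["CCO", "CCC", "c1ccccc1", "CCN",
                                          "c1ccncc1", "CCCC"])]
        cfg = small_cfg(epochs=3)
        _, h1 = train_model(samples, samples, cfg)
        _, h2 = train_model(samples, samples, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_metric == h2.val_metric

    def test_empty_training_set_rejected(self):
        with pytest.raises(DataError):
            train_model([], [], small_cfg())

    def test_regression_training_normalizes_targets(self):
        samples = [Sample("CCO", "O", 500.0), Sample("CCC", "O", 520.0),
                   Sample("CCN", "CO", 480.0), Sample("CCCC", "O", 540.0)]
        cfg = small_cfg("regression", epochs=2)
        params, _ = train_model(samples, samples, cfg)
        assert params.target_mean == pytest.approx(510.0)
        assert params.target_sd > 0

    def test_history_length_and_best_epoch(self):
        samples = [Sample(s, WavelengthPair(400, 500), float(i % 2))
                   for i, s in enumerate(["CCO", "CCC", "c1ccccc1", "CCN"])]
        cfg = small_cfg(epochs=4)
        _, hist = train_model(samples, samples, cfg)
        assert len(hist.train_loss) == 4 and len(hist.val_metric) == 4
        assert hist.best_epoch == int(np.argmax(hist.val_metric))


class TestEvaluate:
    def test_auc_matches_pairwise_counting_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        # brute force over all (positive, negative) pairs with tie credit
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        concordant = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        oracle = concordant / (len(pos) * len(neg))
        assert oracle == 0.75
        assert evaluate(scores, labels, "classification")["auc"] == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                        "classification")["auc"] == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        base = evaluate(scores, labels, "classification")["auc"]
        for f in (lambda s: 2 * s + 1, np.exp, lambda s: s**3):
            assert evaluate(f(scores), labels, "classification")["auc"] \
                == pytest.approx(base)

    def test_identity_regression_metrics(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "regression")
        assert m["r2"] == 1.0 and m["mae"] == 0.0

    def test_r2_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.normal(size=20)
            p = rng.normal(size=20)
            assert evaluate(p, y, "regression")["r2"] <= 1.0

    def test_single_class_auc_undefined(self):
        with pytest.raises(DataError):
            evaluate([0.2, 0.8], [1, 1], "classification")

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            evaluate([0.2], [1], "classification")


def test_model_save_load_roundtrip(tmp_path):
    cfg = small_cfg()
    params = init_params(cfg, seed=21)
    cache = {("c1ccccc1", 400.0, 500.0): 1.0}
    model = Model(cfg, params, cache=cache)
    pair = WavelengthPair(420, 520)
    before = model.predict_activity_scores(["CCO", "c1ccncc1"], pair)
    path = tmp_path / "model.npz"
    save_model(model, str(path))
    loaded = load_model(str(path))
    after = loaded.predict_activity_scores(["CCO", "c1ccncc1"], pair)
    np.testing.assert_array_equal(before, after)
    assert loaded.cache == cache
    assert loaded.cfg == cfg
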