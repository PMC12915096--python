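"""Conditioned directed message-passing network for fluorescence prediction.

Two model families share one bond-centric encoder:

* **L1 activity classifier** — input: molecule + an (absorption, emission)
  wavelength query pair; output: a fluorescence activity score in [0, 1].
* **L2 property regressors** — input: molecule + solvent SMILES (embedded by
  a separate solvent encoder); output: one of seven photophysical properties
  in its own units (targets are z-scored on the training split and
  predictions denormalized).

Encoder update equations (hidden states live on directed edges)::

    h0_e  = relu(W_in · [x_src(e) ++ f_e])
    m_t_e = sum over incoming edges e' of src(e), e' != reverse(e), of h_{t-1}_e'
    h_t_e = relu(W_h · [h_{t-1}_e ++ m_t_e])        (default "concat_prev" rule)
          = relu(h0_e + W_h · m_t_e)                (alternative "input_add" rule)
    a_v   = relu(W_a · [x_v ++ sum of incoming h_depth])
    embedding = mean (or sum) over atoms of a_v

The exclusion of the reverse edge keeps messages from echoing straight back
along the bond they arrived on.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import mean_absolute_error, r2_score, roc_auc_score

from . import autodiff as ad
from .autodiff import Tensor
from .errors import (
    ConfigurationError,
    DataError,
    DivergenceError,
    TaskMismatchError,
)
from .molgraph import (
    ATOM_FDIM,
    BOND_FDIM,
    MolGraph,
    WavelengthPair,
    encode_condition,
    featurize_molecule,
)

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass
class EncoderConfig:
    task: str
    target_property: str | None = None
    depth: int = 3
    hidden: int = 300
    solvent_depth: int = 3
    solvent_hidden: int = 300
    activation: str = "relu"
    aggregation: str = "mean"          # atom pooling: mean | sum
    ffn_layers: int = 2
    ffn_hidden: int = 300
    dropout: float = 0.0
    epochs: int = 30
    init_lr: float = 1e-4
    seed: int = 0
    batch_size: int = 64
    update_rule: str = "concat_prev"   # concat_prev | input_add

    def __post_init__(self):
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ConfigurationError(f"unknown task {self.task!r}")
        if self.depth < 0 or self.hidden <= 0:
            raise ConfigurationError("depth must be >= 0 and hidden > 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.aggregation not in ("mean", "sum"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.update_rule not in ("concat_prev", "input_add"):
            raise ConfigurationError(f"unknown update rule {self.update_rule!r}")


@dataclass
class ModelParams:
    """Named weight tensors plus target-normalization constants."""

    weights: dict = field(default_factory=dict)
    target_mean: float = 0.0
    target_sd: float = 1.0

    def tensors(self):
        return list(self.weights.values())

    def copy_data(self):
        return {k: v.data.copy() for k, v in self.weights.items()}

    def load_data(self, state):
        for k, v in self.weights.items():
            v.data[...] = state[k]


def _glorot(rng, fan_in, fan_out, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(dtype)


def init_params(cfg: EncoderConfig, seed: int | None = None, dtype=np.float32) -> ModelParams:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    w: dict[str, Tensor] = {}

    def branch(prefix, hidden):
        w[prefix + "W_in"] = Tensor(_glorot(rng, ATOM_FDIM + BOND_FDIM, hidden, dtype), True)
        w[prefix + "b_in"] = Tensor(np.zeros(hidden, dtype), True)
        if cfg.update_rule == "concat_prev":
            # the stacked [W_self; W_msg] equals one W_h acting on [h ++ m];
            # stored split so the hot loop can skip the concatenation
            full = _glorot(rng, 2 * hidden, hidden, dtype)
            w[prefix + "W_h_self"] = Tensor(full[:hidden].copy(), True)
            w[prefix + "W_h_msg"] = Tensor(full[hidden:].copy(), True)
        else:
            w[prefix + "W_h"] = Tensor(_glorot(rng, hidden, hidden, dtype), True)
        w[prefix + "b_h"] = Tensor(np.zeros(hidden, dtype), True)
        full_a = _glorot(rng, ATOM_FDIM + hidden, hidden, dtype)
        w[prefix + "W_a_x"] = Tensor(full_a[:ATOM_FDIM].copy(), True)
        w[prefix + "W_a_in"] = Tensor(full_a[ATOM_FDIM:].copy(), True)
        w[prefix + "b_a"] = Tensor(np.zeros(hidden, dtype), True)

    branch("", cfg.hidden)
    if cfg.task == CLASSIFICATION:
        ffn_in = cfg.hidden + 2  # scaled wavelength pair
    else:
        branch("solv_", cfg.solvent_hidden)
        ffn_in = cfg.hidden + cfg.solvent_hidden
    d = ffn_in
    for i in range(cfg.ffn_layers):
        w[f"ffn_W{i}"] = Tensor(_glorot(rng, d, cfg.ffn_hidden, dtype), True)
        w[f"ffn_b{i}"] = Tensor(np.zeros(cfg.ffn_hidden, dtype), True)
        d = cfg.ffn_hidden
    w["ffn_Wout"] = Tensor(_glorot(rng, d, 1, dtype), True)
    w["ffn_bout"] = Tensor(np.zeros(1, dtype), True)
    return ModelParams(weights=w)


# ------------------------------------------------------------- batching

class GraphBatch:
    """Several molecular graphs packed into one disjoint graph."""

    def __init__(self, graphs: list[MolGraph], dtype=np.float32):
        n_atoms = sum(g.n_atoms for g in graphs)
        n_edges = sum(g.n_edges for g in graphs)
        self.n_atoms, self.n_edges, self.n_mols = n_atoms, n_edges, len(graphs)
        self.atom_features = np.zeros((n_atoms, ATOM_FDIM), dtype=dtype)
        self.bond_features = np.zeros((n_edges, BOND_FDIM), dtype=dtype)
        self.edge_src = np.zeros(n_edges, dtype=np.int64)
        self.edge_dst = np.zeros(n_edges, dtype=np.int64)
        self.rev_index = np.zeros(n_edges, dtype=np.int64)
        self.atom_mol_index = np.zeros(n_atoms, dtype=np.int64)
        ao = eo = 0
        for i, g in enumerate(graphs):
            self.atom_features[ao : ao + g.n_atoms] = g.atom_features
            self.atom_mol_index[ao : ao + g.n_atoms] = i
            if g.n_edges:
                self.bond_features[eo : eo + g.n_edges] = g.bond_features
                self.edge_src[eo : eo + g.n_edges] = g.edge_src + ao
                self.edge_dst[eo : eo + g.n_edges] = g.edge_dst + ao
                self.rev_index[eo : eo + g.n_edges] = g.reverse_index + eo
            ao += g.n_atoms
            eo += g.n_edges

        self.h0_input = np.concatenate(
            [self.atom_features[self.edge_src], self.bond_features], axis=1
        )
        # sort plans reused by every encoder pass over this batch
        self.dst_plan = ad.SegmentPlan(self.edge_dst, n_atoms)
        self.src_plan = ad.SegmentPlan(self.edge_src, n_atoms)
        self.mol_plan = ad.SegmentPlan(self.atom_mol_index, self.n_mols)


def encode_batch(batch: GraphBatch, cfg: EncoderConfig, params: ModelParams,
                 prefix: str = "", depth: int | None = None) -> Tensor:
    """Run the message-passing encoder; returns (n_mols, hidden) embeddings."""
    w = params.weights
    if w[prefix + "W_in"].shape[0] != ATOM_FDIM + BOND_FDIM:
        raise ConfigurationError("parameter shapes do not match feature widths")
    depth = cfg.depth if depth is None else depth
    h0 = ad.relu(ad.linear(Tensor(batch.h0_input), w[prefix + "W_in"], w[prefix + "b_in"]))
    h = h0
    for _ in range(depth):
        # per-atom sums of incoming edge states; subtracting the reverse
        # edge realizes "all incoming except the reverse" without a loop
        A = ad.segment_sum(h, batch.edge_dst, batch.n_atoms, batch.dst_plan)
        m = ad.gather_sub(A, batch.edge_src, h, batch.rev_index, batch.src_plan)
        if cfg.update_rule == "concat_prev":
            h = ad.relu(ad.affine2(h, w[prefix + "W_h_self"],
                                   m, w[prefix + "W_h_msg"], w[prefix + "b_h"]))
        else:
            h = ad.relu(ad.add(h0, ad.linear(m, w[prefix + "W_h"], w[prefix + "b_h"])))
    incoming = ad.segment_sum(h, batch.edge_dst, batch.n_atoms, batch.dst_plan)
    a = ad.relu(ad.affine2(Tensor(batch.atom_features), w[prefix + "W_a_x"],
                           incoming, w[prefix + "W_a_in"], w[prefix + "b_a"]))
    if cfg.aggregation == "mean":
        return ad.segment_mean(a, batch.atom_mol_index, batch.n_mols, batch.mol_plan)
    return ad.segment_sum(a, batch.atom_mol_index, batch.n_mols, batch.mol_plan)


def encode_graph(g: MolGraph, cfg: EncoderConfig, params: ModelParams) -> np.ndarray:
    """Embed a single molecule (inference only); returns a (hidden,) vector."""
    with ad.no_grad():
        return encode_batch(GraphBatch([g]), cfg, params).data[0]


def _ffn(x: Tensor, cfg: EncoderConfig, params: ModelParams,
         rng: np.random.Generator | None = None) -> Tensor:
    w = params.weights
    h = x
    for i in range(cfg.ffn_layers):
        h = ad.relu(ad.linear(h, w[f"ffn_W{i}"], w[f"ffn_b{i}"]))
        if cfg.dropout > 0 and rng is not None:
            h = ad.dropout(h, cfg.dropout, rng)
    return ad.linear(h, w["ffn_Wout"], w["ffn_bout"])


def _activity_logits(batch, wl_scaled, cfg, params, rng=None) -> Tensor:
    emb = encode_batch(batch, cfg, params)
    cond = np.broadcast_to(wl_scaled, (batch.n_mols, 2)).astype(emb.data.dtype)
    return _ffn(ad.concat([emb, Tensor(cond)]), cfg, params, rng)


def _property_raw(batch, solvent_emb: Tensor, cfg, params, rng=None) -> Tensor:
    emb = encode_batch(batch, cfg, params)
    return _ffn(ad.concat([emb, solvent_emb]), cfg, params, rng)


def predict_activity(g: MolGraph, wavelength_pair: WavelengthPair,
                     cfg: EncoderConfig, params: ModelParams) -> float:
    """Fluorescence activity score in [0, 1] for one molecule + query pair."""
    if cfg.task != CLASSIFICATION:
        raise TaskMismatchError("predict_activity requires a classification config")
    wl = encode_condition(wavelength_pair)
    with ad.no_grad():
        z = _activity_logits(GraphBatch([g]), wl, cfg, params)
    return float(1.0 / (1.0 + np.exp(-z.data[0, 0])))


def predict_property(g: MolGraph, solvent_smiles: str,
                     cfg: EncoderConfig, params: ModelParams) -> float:
    """Predicted property value (denormalized, property units)."""
    if cfg.task != REGRESSION:
        raise TaskMismatchError("predict_property requires a regression config")
    solvent_graph = encode_condition(solvent_smiles)
    with ad.no_grad():
        semb = encode_batch(GraphBatch([solvent_graph]), cfg, params, prefix="solv_",
                            depth=cfg.solvent_depth)
        raw = _property_raw(GraphBatch([g]), semb, cfg, params)
    return float(raw.data[0, 0] * params.target_sd + params.target_mean)


# ------------------------------------------------------------- training

@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_metric: list = field(default_factory=list)
    best_epoch: int = -1


@dataclass
class Sample:
    """One training/evaluation entry.

    ``condition`` is a :class:`WavelengthPair` for classification or a solvent
    SMILES for regression; ``target`` is the 0/1 label or the property value.
    """

    smiles: str
    condition: object
    target: float


class _PreparedData:
    """Featurized, pre-batched dataset reused across epochs."""

    def __init__(self, samples, cfg, rng, graph_cache, batch_size=None):
        if not samples:
            raise DataError("empty dataset")
        self.cfg = cfg
        order = rng.permutation(len(samples))
        samples = [samples[i] for i in order]
        bs = batch_size or cfg.batch_size
        self.batches = []
        self.targets = []
        if cfg.task == REGRESSION:
            self.solvents = sorted({s.condition for s in samples})
            self.solvent_batch = GraphBatch(
                [featurize_molecule(sv) for sv in self.solvents]
            )
            sidx = {sv: i for i, sv in enumerate(self.solvents)}
        for i in range(0, len(samples), bs):
            chunk = samples[i : i + bs]
            graphs = []
            for s in chunk:
                if s.smiles not in graph_cache:
                    graph_cache[s.smiles] = featurize_molecule(s.smiles)
                graphs.append(graph_cache[s.smiles])
            gb = GraphBatch(graphs)
            t = np.array([s.target for s in chunk], dtype=np.float32)[:, None]
            if cfg.task == CLASSIFICATION:
                wl = encode_condition(chunk[0].condition)
                conds = np.stack([encode_condition(s.condition) for s in chunk]) \
                    if any(s.condition != chunk[0].condition for s in chunk) else wl
                self.batches.append((gb, conds))
            else:
                self.batches.append(
                    (gb, np.array([sidx[s.condition] for s in chunk], dtype=np.int64))
                )
            self.targets.append(t)
        self.all_targets = np.concatenate(self.targets)[:, 0]


def _forward_scores(prep: _PreparedData, cfg, params) -> np.ndarray:
    """Inference over a prepared dataset, in its batch order."""
    outs = []
    with ad.no_grad():
        if cfg.task == REGRESSION:
            semb_all = encode_batch(prep.solvent_batch, cfg, params, "solv_",
                                    cfg.solvent_depth)
        for (gb, cond), _t in zip(prep.batches, prep.targets):
            if cfg.task == CLASSIFICATION:
                z = _activity_logits(gb, cond, cfg, params)
                outs.append(1.0 / (1.0 + np.exp(-z.data[:, 0])))
            else:
                semb = Tensor(semb_all.data[cond])
                raw = _property_raw(gb, semb, cfg, params)
                outs.append(raw.data[:, 0] * params.target_sd + params.target_mean)
    return np.concatenate(outs)


def train_model(train, val, cfg: EncoderConfig):
    """Train with Adam (constant LR, gradient-norm clip 10); returns
    (params, history) at the best validation epoch.

    ``train`` / ``val`` are lists of :class:`Sample`.  Classification
    minimizes binary cross-entropy; regression minimizes MSE on z-scored
    targets.  Fully deterministic given ``cfg.seed``.
    """
    if not train:
        raise DataError("empty training set")
    ad.pool.clear()
    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg, seed=cfg.seed)
    graph_cache: dict[str, MolGraph] = {}
    prep_train = _PreparedData(train, cfg, rng, graph_cache)
    prep_val = _PreparedData(val, cfg, rng, graph_cache) if val else None

    if cfg.task == REGRESSION:
        t = prep_train.all_targets
        params.target_mean = float(t.mean())
        params.target_sd = float(t.std()) or 1.0

    opt = ad.Adam(params.tensors(), lr=cfg.init_lr, clip_norm=10.0)
    history = TrainingHistory()
    best_state, best_metric = params.copy_data(), -np.inf
    n_batches = len(prep_train.batches)

    for epoch in range(cfg.epochs):
        losses = []
        for bi in rng.permutation(n_batches):
            (gb, cond), targets = prep_train.batches[bi], prep_train.targets[bi]
            opt.zero_grad()
            if cfg.task == CLASSIFICATION:
                z = _activity_logits(gb, cond, cfg, params, rng)
                loss = ad.bce_with_logits(z, targets)
            else:
                semb_all = encode_batch(prep_train.solvent_batch, cfg, params,
                                        "solv_", cfg.solvent_depth)
                raw = _property_raw(gb, ad.gather_rows(semb_all, cond), cfg, params, rng)
                norm_t = (targets - params.target_mean) / params.target_sd
                loss = ad.mse(raw, norm_t)
            if not np.isfinite(loss.data):
                raise DivergenceError(epoch)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.train_loss.append(float(np.mean(losses)))

        if prep_val is not None:
            preds = _forward_scores(prep_val, cfg, params)
            metric = _validation_metric(preds, prep_val.all_targets, cfg.task)
        else:
            metric = -history.train_loss[-1]
        history.val_metric.append(metric)
        if metric > best_metric:
            best_metric, best_state = metric, params.copy_data()
            history.best_epoch = epoch

    params.load_data(best_state)
    return params, history


def _validation_metric(preds, truths, task) -> float:
    if task == CLASSIFICATION:
        if len(np.unique(truths)) < 2:
            return 0.5
        return float(roc_auc_score(truths, preds))
    return float(r2_score(truths, preds))


def evaluate(predictions, truths, task: str) -> dict:
    """Held-out metrics: AUC (classification) or R² and MAE (regression)."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape or predictions.size < 2:
        raise DataError("predictions and truths must have equal length >= 2")
    if task == CLASSIFICATION:
        classes = np.unique(truths)
        if not np.isin(classes, (0.0, 1.0)).all():
            raise DataError("classification truths must be binary 0/1")
        if len(classes) < 2:
            raise DataError("AUC undefined for a single-class truth vector")
        return {"auc": float(roc_auc_score(truths, predictions))}
    return {
        "r2": float(r2_score(truths, predictions)),
        "mae": float(mean_absolute_error(truths, predictions)),
    }


# ------------------------------------------------------------- bundles

class Model:
    """A trained model bundle: config + params (+ optional retrieval cache).

    Counts predictor invocations so the screening pipeline can prove that
    cache hits bypass the network.
    """

    def __init__(self, cfg: EncoderConfig, params: ModelParams, cache: dict | None = None):
        self.cfg = cfg
        self.params = params
        self.cache = cache or {}
        self.n_predict_calls = 0
        self._graph_cache: dict[str, MolGraph] = {}

    def _graphs(self, smiles_list):
        out = []
        for s in smiles_list:
            if s not in self._graph_cache:
                self._graph_cache[s] = featurize_molecule(s)
            out.append(self._graph_cache[s])
        return out

    def predict_activity_scores(self, smiles_list, wavelength_pair) -> np.ndarray:
        if self.cfg.task != CLASSIFICATION:
            raise TaskMismatchError("not a classification model")
        self.n_predict_calls += len(smiles_list)
        if not smiles_list:
            return np.zeros(0)
        wl = encode_condition(wavelength_pair)
        with ad.no_grad():
            z = _activity_logits(GraphBatch(self._graphs(smiles_list)), wl,
                                 self.cfg, self.params)
        return 1.0 / (1.0 + np.exp(-z.data[:, 0]))

    def predict_property_values(self, smiles_list, solvent_smiles) -> np.ndarray:
        if self.cfg.task != REGRESSION:
            raise TaskMismatchError("not a regression model")
        self.n_predict_calls += len(smiles_list)
        if not smiles_list:
            return np.zeros(0)
        with ad.no_grad():
            semb = encode_batch(GraphBatch([featurize_molecule(solvent_smiles)]),
                                self.cfg, self.params, "solv_", self.cfg.solvent_depth)
            semb = Tensor(np.broadcast_to(semb.data, (len(smiles_list), semb.data.shape[1])))
            raw = _property_raw(GraphBatch(self._graphs(smiles_list)), semb,
                                self.cfg, self.params)
        return raw.data[:, 0] * self.params.target_sd + self.params.target_mean


FORMAT_VERSION = 1


def save_model(model: Model, path: str):
    """Serialize a model bundle (.npz with an embedded JSON header)."""
    header = {
        "format_version": FORMAT_VERSION,
        "config": asdict(model.cfg),
        "target_mean": model.params.target_mean,
        "target_sd": model.params.target_sd,
        "cache": [[list(k), v] for k, v in model.cache.items()],
    }
    arrays = {f"w_{k}": v.data for k, v in model.params.weights.items()}
    with open(path, "wb") as fh:
        np.savez_compressed(fh, header=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> Model:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header["format_version"] != FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported model format version {header['format_version']}"
            )
        cfg = EncoderConfig(**header["config"])
        params = init_params(cfg)
        for k in params.weights:
            params.weights[k].data = z[f"w_{k}"].copy()
        params.target_mean = header["target_mean"]
        params.target_sd = header["target_sd"]
        cache = {tuple(k): v for k, v in header["cache"]}
    return Model(cfg, params, cache)
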