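"""The re-ranking model: twin graph encoders, scorer, and pairwise training.

Each candidate (predicted reactant set, product) is encoded by two
independent attention-gated message-passing networks — one over the merged
reactant graph, one over the product graph — whose pooled outputs are
concatenated into a reaction representation.  A two-linear-layer scorer
maps that representation to a scalar re-ranking score.  Training is
pairwise: for each product, the recorded candidate should outscore sampled
non-recorded candidates, optimized with a label-smoothed two-class
cross-entropy on the score difference.

The encoder follows the attention-gated message-passing family (gated
edge messages, global attention readout); any node-order-invariant
aggregator would serve, and the backbone sits behind ``GraphEncoder`` so
alternatives can be added.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from . import featurization as fz
from .autodiff import Adam, Tensor, concat, gather, segment_softmax, spmm
from .chem_io import PredictionList, ReactionRecord
from .errors import SchemaError, UsageError
from .featurization import FeaturizedReactionGraph, GraphData, build_reaction_graphs
from .reaction_change import annotate_changes

logger = logging.getLogger(__name__)

#: Score assigned to unscorable (unparseable) candidates: the documented
#: minimum, so they always sort last under any strategy.
UNSCORABLE_SCORE = float("-inf")


@dataclass
class EncoderConfig:
    hidden_width: int = 64
    num_layers: int = 3
    num_readout_steps: int = 2
    attention_heads: int = 1  # readout is single-head; kept for extension
    dropout: float = 0.0
    schema_hash: str = field(default_factory=fz.schema_hash)

    def validate(self) -> None:
        if self.hidden_width <= 0 or self.num_layers <= 0 or self.num_readout_steps <= 0:
            raise UsageError("encoder widths and depths must be positive")
        if self.attention_heads < 1:
            raise UsageError("attention heads must be >= 1")


@dataclass
class TrainConfig:
    label_smoothing: float = 0.1
    learning_rate: float = 3e-3
    batch_size: int = 256
    epochs: int = 10
    max_pairs_per_product: int = 3
    seed: int = 0
    validation_fraction: float = 0.1
    resample_negatives: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.label_smoothing < 0.5):
            raise UsageError("label smoothing must be in [0, 0.5)")
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise UsageError("learning rate and batch size must be positive")
        if self.epochs < 0 or self.max_pairs_per_product <= 0:
            raise UsageError("epochs must be >= 0 and max pairs positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise UsageError("validation fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# batched graphs


@dataclass
class _Batch:
    """Several graphs packed into one disconnected block graph."""

    node_features: np.ndarray   # (N, d_atom)
    edge_features: np.ndarray   # (2M, d_bond), one row per directed edge
    src: np.ndarray             # (2M,)
    dst: np.ndarray             # (2M,)
    agg: sparse.csr_matrix      # (N, 2M) sums directed-edge values into dst nodes
    pool_sum: sparse.csr_matrix   # (G, N)
    pool_mean: sparse.csr_matrix  # (G, N)
    segment_ids: np.ndarray     # (N,) node -> graph
    num_graphs: int


def batch_graphs(graphs: list[GraphData]) -> _Batch:
    nodes, efeats, srcs, dsts, segs = [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        n = g.num_nodes
        nodes.append(g.node_features)
        segs.append(np.full(n, gi, dtype=np.int64))
        if len(g.edges):
            a = g.edges[:, 0] + offset
            b = g.edges[:, 1] + offset
            srcs.append(np.concatenate([a, b]))
            dsts.append(np.concatenate([b, a]))
            efeats.append(np.vstack([g.edge_features, g.edge_features]))
        offset += n
    node_features = np.vstack(nodes)
    if srcs:
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        edge_features = np.vstack(efeats)
    else:
        src = np.zeros(0, dtype=np.int64)
        dst = np.zeros(0, dtype=np.int64)
        edge_features = np.zeros((0, fz.BOND_DIM))
    seg = np.concatenate(segs)
    n_nodes = node_features.shape[0]
    n_edges = len(src)
    agg = sparse.csr_matrix(
        (np.ones(n_edges), (dst, np.arange(n_edges))), shape=(n_nodes, n_edges)
    )
    ones = np.ones(n_nodes)
    pool_sum = sparse.csr_matrix(
        (ones, (seg, np.arange(n_nodes))), shape=(len(graphs), n_nodes)
    )
    sizes = np.bincount(seg, minlength=len(graphs)).astype(float)
    pool_mean = sparse.csr_matrix(
        (1.0 / sizes[seg], (seg, np.arange(n_nodes))), shape=(len(graphs), n_nodes)
    )
    return _Batch(
        node_features=node_features,
        edge_features=edge_features,
        src=src,
        dst=dst,
        agg=agg,
        pool_sum=pool_sum,
        pool_mean=pool_mean,
        segment_ids=seg,
        num_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    scale = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-scale, scale, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(width: int) -> Tensor:
    return Tensor(np.zeros((1, width)), requires_grad=True)


class GraphEncoder:
    """Attention-gated message passing with an iterative attention readout."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        h = config.hidden_width
        self.config = config
        d_atom, d_bond = fz.ATOM_DIM, fz.BOND_DIM
        self.params: dict[str, Tensor] = {
            "w_node": _glorot(rng, d_atom, h), "b_node": _zeros(h),
            "w_edge": _glorot(rng, d_bond, h), "b_edge": _zeros(h),
        }
        for layer in range(config.num_layers):
            self.params[f"w_msg{layer}"] = _glorot(rng, 2 * h, h)
            self.params[f"b_msg{layer}"] = _zeros(h)
            self.params[f"w_gate{layer}"] = _glorot(rng, 3 * h, h)
            self.params[f"b_gate{layer}"] = _zeros(h)
            self.params[f"w_upd{layer}"] = _glorot(rng, 2 * h, h)
            self.params[f"b_upd{layer}"] = _zeros(h)
        self.params.update({
            "w_att": _glorot(rng, 2 * h, h), "b_att": _zeros(h),
            "w_att2": _glorot(rng, h, 1), "b_att2": _zeros(1),
            "w_read": _glorot(rng, h, h), "b_read": _zeros(h),
        })

    def forward(self, batch: _Batch) -> Tensor:
        p = self.params
        h = (Tensor(batch.node_features) @ p["w_node"] + p["b_node"]).relu()
        if len(batch.src):
            e = (Tensor(batch.edge_features) @ p["w_edge"] + p["b_edge"]).relu()
        for layer in range(self.config.num_layers):
            if len(batch.src):
                h_src = gather(h, batch.src)
                h_dst = gather(h, batch.dst)
                m = (concat([h_src, e]) @ p[f"w_msg{layer}"] + p[f"b_msg{layer}"]).relu()
                g = (concat([h_src, h_dst, e]) @ p[f"w_gate{layer}"] + p[f"b_gate{layer}"]).sigmoid()
                agg = spmm(batch.agg, g * m)
            else:
                agg = h * 0.0
            h = (concat([h, agg]) @ p[f"w_upd{layer}"] + p[f"b_upd{layer}"]).relu() + h
        # iterative global attention readout
        context = spmm(batch.pool_mean, h)
        projected = h @ p["w_read"] + p["b_read"]
        for _step in range(self.config.num_readout_steps):
            ctx_per_node = gather(context, batch.segment_ids)
            scores = (concat([h, ctx_per_node]) @ p["w_att"] + p["b_att"]).tanh() @ p["w_att2"] + p["b_att2"]
            alpha = segment_softmax(scores, batch.segment_ids, batch.num_graphs)
            context = spmm(batch.pool_sum, alpha * projected).tanh()
        return context  # (G, hidden)

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]


class RankerModel:
    """Twin encoders plus a two-linear-layer scorer."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        config.validate()
        rng = np.random.default_rng(seed)
        h = config.hidden_width
        self.config = config
        self.reactant_encoder = GraphEncoder(config, rng)
        self.product_encoder = GraphEncoder(config, rng)
        self.scorer: dict[str, Tensor] = {
            "w1": _glorot(rng, 2 * h, h), "b1": _zeros(h),
            "w2": _glorot(rng, h, 1), "b2": _zeros(1),
        }

    def parameters(self) -> list[Tensor]:
        return (
            self.reactant_encoder.parameters()
            + self.product_encoder.parameters()
            + [self.scorer[k] for k in sorted(self.scorer)]
        )

    def _check_schema(self, graphs: FeaturizedReactionGraph) -> None:
        if graphs.schema_hash != self.config.schema_hash:
            raise SchemaError(
                f"feature schema {graphs.schema_hash} does not match model "
                f"schema {self.config.schema_hash}"
            )

    def encode_batch(self, reactant: _Batch, product: _Batch) -> Tensor:
        r = self.reactant_encoder.forward(reactant)
        p = self.product_encoder.forward(product)
        return concat([r, p], axis=1)  # (G, 2h)

    def score_batch(self, reactant: _Batch, product: _Batch) -> Tensor:
        emb = self.encode_batch(reactant, product)
        s = self.scorer
        hidden = (emb @ s["w1"] + s["b1"]).relu()
        return hidden @ s["w2"] + s["b2"]  # (G, 1)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, params in (
            ("reactant", self.reactant_encoder.params),
            ("product", self.product_encoder.params),
            ("scorer", self.scorer),
        ):
            for k, v in params.items():
                out[f"{prefix}.{k}"] = v.data
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, params in (
            ("reactant", self.reactant_encoder.params),
            ("product", self.product_encoder.params),
            ("scorer", self.scorer),
        ):
            for k, v in params.items():
                v.data = np.array(state[f"{prefix}.{k}"], dtype=np.float64)


# ---------------------------------------------------------------------------
# single-record convenience API


def featurize_record(record: ReactionRecord, radius: int = 1) -> FeaturizedReactionGraph:
    """Annotate changes and build the paired graphs for one record."""
    annotation = annotate_changes(record, radius=radius)
    return build_reaction_graphs(record, annotation)


def encode_reaction(model: RankerModel, graphs: FeaturizedReactionGraph) -> np.ndarray:
    """Reaction embedding: concatenated reactant/product encoder outputs."""
    model._check_schema(graphs)
    rb = batch_graphs([graphs.reactant_graph])
    pb = batch_graphs([graphs.product_graph])
    return model.encode_batch(rb, pb).data[0]


def score_candidate(model: RankerModel, graphs: FeaturizedReactionGraph) -> float:
    """Scalar re-ranking score for one candidate (deterministic)."""
    model._check_schema(graphs)
    rb = batch_graphs([graphs.reactant_graph])
    pb = batch_graphs([graphs.product_graph])
    return float(model.score_batch(rb, pb).data[0, 0])


# ---------------------------------------------------------------------------
# loss and training pairs


def pairwise_loss(s_pos: float | Tensor, s_neg: float | Tensor, epsilon: float) -> float | Tensor:
    """Label-smoothed two-class cross-entropy on the score difference.

    Softmax over (s_pos, s_neg) against the smoothed target (1-eps, eps):
    ``(1-eps)*softplus(-(s_pos-s_neg)) + eps*softplus(s_pos-s_neg)``.
    Strictly decreasing in the margin for eps < 0.5; equals ln 2 at zero
    margin for every eps.
    """
    if not (0.0 <= epsilon < 0.5):
        raise UsageError("label smoothing must be in [0, 0.5)")
    if isinstance(s_pos, Tensor) or isinstance(s_neg, Tensor):
        z = (s_pos if isinstance(s_pos, Tensor) else Tensor(s_pos)) - s_neg
        return (1.0 - epsilon) * (-z).softplus() + epsilon * z.softplus()
    z = float(s_pos) - float(s_neg)
    softplus = lambda x: max(x, 0.0) + math.log1p(math.exp(-abs(x)))
    return (1.0 - epsilon) * softplus(-z) + epsilon * softplus(z)


def make_training_pairs(
    lists: list[PredictionList], max_pairs: int, seed: int
) -> list[tuple[ReactionRecord, ReactionRecord]]:
    """Sample up to ``max_pairs`` (recorded, non-recorded) tuples per product.

    Lists without a recorded candidate contribute nothing (counted and
    logged); unscorable candidates are never sampled as negatives.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[ReactionRecord, ReactionRecord]] = []
    skipped = 0
    for plist in lists:
        recorded = next((c for c in plist.candidates if c.is_recorded and not c.unscorable), None)
        if recorded is None:
            skipped += 1
            continue
        negatives = [c for c in plist.candidates if not c.is_recorded and not c.unscorable]
        if not negatives:
            skipped += 1
            continue
        take = min(max_pairs, len(negatives))
        chosen = rng.choice(len(negatives), size=take, replace=False)
        pairs.extend((recorded, negatives[int(i)]) for i in sorted(chosen))
    if skipped:
        logger.info("make_training_pairs: skipped %d lists without usable recorded candidate", skipped)
    return pairs


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")


class _GraphCache:
    """Featurizes each ReactionRecord once, keyed by object identity."""

    def __init__(self, radius: int = 1):
        self.radius = radius
        self._cache: dict[int, tuple[GraphData, GraphData]] = {}

    def get(self, record: ReactionRecord) -> tuple[GraphData, GraphData]:
        key = id(record)
        if key not in self._cache:
            g = featurize_record(record, radius=self.radius)
            self._cache[key] = (g.reactant_graph, g.product_graph)
        return self._cache[key]


def _pair_loss_and_hits(
    model: RankerModel,
    pairs: list[tuple[ReactionRecord, ReactionRecord]],
    cache: _GraphCache,
    epsilon: float,
    batch_size: int,
    train: bool,
    optimizer: Adam | None = None,
) -> tuple[float, float]:
    """Mean pairwise loss and pairwise accuracy over `pairs`; optionally steps."""
    total_loss = 0.0
    hits = 0
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        pos_r, pos_p, neg_r, neg_p = [], [], [], []
        for pos, neg in chunk:
            rg, pg = cache.get(pos)
            pos_r.append(rg)
            pos_p.append(pg)
            rg, pg = cache.get(neg)
            neg_r.append(rg)
            neg_p.append(pg)
        s_pos = model.score_batch(batch_graphs(pos_r), batch_graphs(pos_p))
        s_neg = model.score_batch(batch_graphs(neg_r), batch_graphs(neg_p))
        loss = pairwise_loss(s_pos, s_neg, epsilon).mean()
        total_loss += float(loss.data) * len(chunk)
        hits += int((s_pos.data > s_neg.data).sum())
        if train and optimizer is not None:
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    n = max(len(pairs), 1)
    return total_loss / n, hits / n


def train(
    train_data: list[PredictionList] | list[tuple[ReactionRecord, ReactionRecord]],
    model_or_config: RankerModel | EncoderConfig,
    config: TrainConfig,
    val_data: list[PredictionList] | None = None,
    radius: int = 1,
) -> tuple[RankerModel, TrainLog]:
    """Train a ranker with the pairwise label-smoothed objective.

    ``train_data`` may be prediction lists (negatives are then re-sampled
    every epoch when ``config.resample_negatives``) or pre-built pairs.
    The returned model carries the parameters of the epoch with the best
    validation pairwise accuracy; with no validation data, the final epoch.
    """
    config.validate()
    if not train_data:
        raise UsageError("train needs a nonempty training set")
    if isinstance(model_or_config, RankerModel):
        model = model_or_config
    else:
        model = RankerModel(model_or_config, seed=config.seed)

    as_lists = isinstance(train_data[0], PredictionList)
    if as_lists and val_data is None and config.validation_fraction > 0:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(train_data))
        n_val = max(1, int(len(train_data) * config.validation_fraction))
        val_data = [train_data[i] for i in order[:n_val]]
        train_data = [train_data[i] for i in order[n_val:]]

    cache = _GraphCache(radius=radius)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    val_pairs = (
        make_training_pairs(val_data, config.max_pairs_per_product, config.seed + 1)
        if val_data
        else []
    )
    log = TrainLog()
    best_state: dict[str, np.ndarray] | None = None
    shuffle_rng = np.random.default_rng(config.seed + 2)
    for epoch in range(config.epochs):
        if as_lists:
            pair_seed = config.seed + 10 + (epoch if config.resample_negatives else 0)
            pairs = make_training_pairs(train_data, config.max_pairs_per_product, pair_seed)
        else:
            pairs = list(train_data)
        order = shuffle_rng.permutation(len(pairs))
        pairs = [pairs[i] for i in order]
        loss, _acc = _pair_loss_and_hits(
            model, pairs, cache, config.label_smoothing, config.batch_size,
            train=True, optimizer=optimizer,
        )
        log.epoch_losses.append(loss)
        if val_pairs:
            _vl, val_acc = _pair_loss_and_hits(
                model, val_pairs, cache, config.label_smoothing, config.batch_size,
                train=False,
            )
            log.epoch_val_accuracy.append(val_acc)
            if math.isnan(log.best_val_accuracy) or val_acc > log.best_val_accuracy:
                log.best_val_accuracy = val_acc
                log.best_epoch = epoch
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        logger.info(
            "epoch %d: loss %.4f val pairwise accuracy %s",
            epoch, loss,
            f"{log.epoch_val_accuracy[-1]:.4f}" if val_pairs else "n/a",
        )
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


# ---------------------------------------------------------------------------
# scoring prediction lists and checkpoints


def score_predictions(
    model: RankerModel, lists: list[PredictionList], radius: int = 1, batch_size: int = 512
) -> list[np.ndarray]:
    """Re-ranking scores per list, aligned with candidate order.

    Unscorable candidates receive :data:`UNSCORABLE_SCORE`.
    """
    cache = _GraphCache(radius=radius)
    records: list[ReactionRecord] = []
    where: list[tuple[int, int]] = []
    out = [np.full(len(pl.candidates), UNSCORABLE_SCORE) for pl in lists]
    for li, plist in enumerate(lists):
        for ci, cand in enumerate(plist.candidates):
            if not cand.unscorable:
                records.append(cand)
                where.append((li, ci))
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        graphs = [cache.get(r) for r in chunk]
        scores = model.score_batch(
            batch_graphs([g[0] for g in graphs]), batch_graphs([g[1] for g in graphs])
        ).data[:, 0]
        for (li, ci), s in zip(where[start : start + batch_size], scores):
            out[li][ci] = float(s)
    return out


def save_checkpoint(model: RankerModel, path: str) -> None:
    """Single-file checkpoint: parameters + config + feature schema."""
    meta = {
        "encoder_config": asdict(model.config),
        "feature_schema": json.loads(fz.schema_json()),
        "schema_hash": model.config.schema_hash,
    }
    arrays = model.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> RankerModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = EncoderConfig(**meta["encoder_config"])
    if config.schema_hash != fz.schema_hash():
        raise SchemaError(
            "checkpoint was trained with a different feature schema "
            f"({config.schema_hash} != {fz.schema_hash()})"
        )
    model = RankerModel(config)
    model.load_state_dict(state)
    return model
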