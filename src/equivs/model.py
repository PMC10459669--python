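"""The EquiVS network.

A molecule is a bag of M conformer instances.  A GCN over the bond topology
produces a molecule-level topological representation H1; per conformer, L
stacked E(3)-equivariant message-passing layers (messages depend on
coordinates only through squared interatomic distances; coordinate updates
are equivariant residual moves along difference vectors) produce gated-sum
readouts whose concatenation across layers (skip connection) is the
conformer representation.  A softmax attention over conformer representations
yields importance coefficients alpha and the attention-weighted molecule
representation HG.  Two MLP heads predict bioactivity (in -logM) at the
conformer level (from each conformer representation) and at the molecule
level (from [H1, HG]).

Two implementations share one parameter set:

* a single-graph reference path in plain NumPy (`gcn_encode`, `egnn_layer`,
  `attend`, ... , `forward_single`) used for inference and as the readable
  definition of the architecture;
* a batched autodiff path (`EquiVS.forward`) that flattens all conformers of
  all molecules in a minibatch into one disconnected graph for training
  throughput.  The two are cross-checked in the test suite.

Ablation variants: single conformer (M=1), linear layer instead of the GCN,
no skip connection (last readout only), unweighted sum instead of attention,
and no instance predictor/loss.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, segment_sum
from .errors import AttentionUnavailableError, ShapeError
from .molgraph import EDGE_FEATURE_DIM, NODE_FEATURE_DIM, MolecularGraph

CHECKPOINT_VERSION = 1


@dataclass
class EquiVSConfig:
    """Architecture hyper-parameters and ablation toggles."""

    hidden_dim: int = 128
    n_layers: int = 2                 # L stacked equivariant layers
    n_conformers: int = 10            # M instances per bag
    dropout: float = 0.05
    node_dim: int = NODE_FEATURE_DIM
    edge_dim: int = EDGE_FEATURE_DIM
    use_gcn: bool = True              # False: plain linear layer instead
    use_skip: bool = True             # False: last-layer readout only
    use_attention: bool = True        # False: unweighted sum over conformers
    use_instance_predictor: bool = True
    # "divide": C = 1/(n_heavy - 1); "multiply": C = n_heavy - 1
    coord_scale_mode: str = "divide"
    seed: int = 0

    @property
    def rep_dim(self) -> int:
        """Width of a conformer representation after (optional) skip concat."""
        return self.n_layers * self.hidden_dim if self.use_skip else self.hidden_dim

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "EquiVSConfig":
        """Named configurations used in the ablation comparisons."""
        toggles = {
            "full": {},
            "single": {"n_conformers": 1},
            "no_gcn": {"use_gcn": False},
            "no_skip": {"use_skip": False},
            "no_aa": {"use_attention": False},
            "no_ip": {"use_instance_predictor": False},
        }
        if variant not in toggles:
            raise ValueError(f"unknown variant {variant!r}")
        return cls(**{**toggles[variant], **kwargs})


@dataclass
class PredictionResult:
    """Molecule-level and conformer-level predictions plus attention."""

    molecule_id: str
    yG: float                      # molecule-level prediction, -logM
    yGm: np.ndarray                # (M,) conformer-level predictions
    alpha: np.ndarray | None       # (M,) attention coefficients, or None
    label: float | None = None


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


def init_params(config: EquiVSConfig) -> dict[str, np.ndarray]:
    """Glorot-uniform weights, zero biases, seeded by config.seed."""
    rng = np.random.default_rng(config.seed)
    h = config.hidden_dim
    d_node, d_edge = config.node_dim, config.edge_dim
    p: dict[str, np.ndarray] = {}

    def zeros(n):
        return np.zeros(n, dtype=np.float32)

    if config.use_gcn:
        p["gcn_phi_e_W"] = _glorot(rng, 2 * d_node, h)
        p["gcn_phi_e_b"] = zeros(h)
        p["gcn_phi_h_W"] = _glorot(rng, d_node + h, h)
        p["gcn_phi_h_b"] = zeros(h)
    else:
        p["lin_W"] = _glorot(rng, d_node, h)
        p["lin_b"] = zeros(h)
    p["readout0_W"] = _glorot(rng, h, h)
    p["readout0_b"] = zeros(h)

    d_in = d_node
    for l in range(config.n_layers):
        p[f"egnn{l}_phi_e_W"] = _glorot(rng, 2 * d_in + 1 + d_edge, h)
        p[f"egnn{l}_phi_e_b"] = zeros(h)
        p[f"egnn{l}_phi_x_W"] = _glorot(rng, h, 1)
        p[f"egnn{l}_phi_x_b"] = zeros(1)
        p[f"egnn{l}_phi_h_W"] = _glorot(rng, d_in + h, h)
        p[f"egnn{l}_phi_h_b"] = zeros(h)
        p[f"egnn{l}_readout_W"] = _glorot(rng, h, h)
        p[f"egnn{l}_readout_b"] = zeros(h)
        d_in = h

    rep = config.rep_dim
    if config.use_attention:
        p["attn_W"] = _glorot(rng, rep, h)
        p["attn_b"] = zeros(h)
        p["attn_q"] = _glorot(rng, h, 1)
    p["ins_W1"] = _glorot(rng, rep, h)
    p["ins_b1"] = zeros(h)
    p["ins_W2"] = _glorot(rng, h, 1)
    p["ins_b2"] = zeros(1)
    p["bag_W1"] = _glorot(rng, h + rep, h)
    p["bag_b1"] = zeros(h)
    p["bag_W2"] = _glorot(rng, h, 1)
    p["bag_b2"] = zeros(1)
    return p


# ---------------------------------------------------------------------------
# Single-graph reference operations (NumPy, inference semantics)
# ---------------------------------------------------------------------------

def _edges_from_adjacency(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    src, dst = np.nonzero(A)
    return src, dst


def gcn_encode(
    A: np.ndarray, HV: np.ndarray, params: dict, use_gcn: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Topological encoder: node features h1 and gated-sum graph readout H1.

    Messages are linear in the concatenated endpoint features; the node
    update is linear in [own features, aggregated message]; the readout is
    sum(sigmoid(W h + b) * h).  Isolated nodes receive a zero message sum.
    """
    if use_gcn:
        src, dst = _edges_from_adjacency(A)
        msgs = np.concatenate([HV[src], HV[dst]], axis=1) @ params["gcn_phi_e_W"]
        msgs = msgs + params["gcn_phi_e_b"]
        agg = np.zeros((HV.shape[0], msgs.shape[1]), dtype=msgs.dtype)
        np.add.at(agg, src, msgs)
        h1 = np.concatenate([HV, agg], axis=1) @ params["gcn_phi_h_W"]
        h1 = h1 + params["gcn_phi_h_b"]
    else:
        h1 = HV @ params["lin_W"] + params["lin_b"]
    gate = _sigmoid(h1 @ params["readout0_W"] + params["readout0_b"])
    H1 = (gate * h1).sum(axis=0)
    return h1, H1


def _sigmoid(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def egnn_message(
    h_i: np.ndarray,
    h_j: np.ndarray,
    x_i: np.ndarray,
    x_j: np.ndarray,
    e_ij: np.ndarray,
    params: dict,
    layer: int,
) -> np.ndarray:
    """Edge message: linear map of [h_i, h_j, ||x_i - x_j||^2, e_ij].

    Coordinates enter only through the squared Euclidean distance, which is
    what makes downstream node features rotation/translation invariant.
    """
    d2 = np.atleast_1d(np.sum((np.asarray(x_i) - np.asarray(x_j)) ** 2, axis=-1))
    h_i, h_j, e_ij = np.atleast_2d(h_i), np.atleast_2d(h_j), np.atleast_2d(e_ij)
    inp = np.concatenate([h_i, h_j, d2.reshape(-1, 1), e_ij], axis=1)
    out = inp @ params[f"egnn{layer}_phi_e_W"] + params[f"egnn{layer}_phi_e_b"]
    return out[0] if out.shape[0] == 1 and np.asarray(h_i).ndim == 2 else out


def coord_scale_constant(n_atoms: int, mode: str = "divide") -> float:
    """The constant C of the coordinate update; guarded for single atoms."""
    if n_atoms <= 1:
        return 1.0
    return 1.0 / (n_atoms - 1) if mode == "divide" else float(n_atoms - 1)


def egnn_coord_update(
    x: np.ndarray,
    src: np.ndarray,
    dst: np.ndarray,
    messages: np.ndarray,
    params: dict,
    layer: int,
    coord_scale_mode: str = "divide",
) -> np.ndarray:
    """Equivariant residual update: x_i += C * sum_j (x_i - x_j) phi_x(m_ij)."""
    C = coord_scale_constant(x.shape[0], coord_scale_mode)
    scal = messages @ params[f"egnn{layer}_phi_x_W"] + params[f"egnn{layer}_phi_x_b"]
    delta = np.zeros_like(x)
    np.add.at(delta, src, (x[src] - x[dst]) * scal)
    return x + C * delta


def egnn_layer(
    A: np.ndarray,
    h: np.ndarray,
    HE_directed: np.ndarray,
    x: np.ndarray,
    params: dict,
    layer: int,
    edge_index: np.ndarray | None = None,
    coord_scale_mode: str = "divide",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One equivariant layer: (h_new, x_new, gated-sum readout).

    `HE_directed` rows must follow `edge_index` order; when `edge_index` is
    None edges are taken from the adjacency matrix (row-major nonzeros).
    """
    if edge_index is None:
        src, dst = _edges_from_adjacency(A)
    else:
        src, dst = edge_index[0], edge_index[1]
    if HE_directed.shape[0] != src.shape[0]:
        raise ShapeError("edge feature rows do not match directed edge count")
    d2 = np.sum((x[src] - x[dst]) ** 2, axis=1, keepdims=True)
    inp = np.concatenate([h[src], h[dst], d2, HE_directed], axis=1)
    msgs = inp @ params[f"egnn{layer}_phi_e_W"] + params[f"egnn{layer}_phi_e_b"]
    x_new = egnn_coord_update(
        x, src, dst, msgs, params, layer, coord_scale_mode=coord_scale_mode
    )
    agg = np.zeros((h.shape[0], msgs.shape[1]), dtype=msgs.dtype)
    np.add.at(agg, src, msgs)
    h_new = np.concatenate([h, agg], axis=1) @ params[f"egnn{layer}_phi_h_W"]
    h_new = h_new + params[f"egnn{layer}_phi_h_b"]
    gate = _sigmoid(
        h_new @ params[f"egnn{layer}_readout_W"] + params[f"egnn{layer}_readout_b"]
    )
    readout = (gate * h_new).sum(axis=0)
    return h_new, x_new, readout


def skip_concat(per_layer_readouts: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-layer readouts (layer order preserved)."""
    widths = {r.shape[-1] for r in per_layer_readouts}
    if len(widths) != 1:
        raise ShapeError(f"mismatched readout widths: {sorted(widths)}")
    return np.concatenate(per_layer_readouts, axis=-1)


def attend(conformer_reps: np.ndarray, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Softmax attention over the M conformer representations.

    Returns (alpha of shape (M,), HG = sum_m alpha_m * rep_m).
    """
    reps = np.atleast_2d(conformer_reps)
    scores = np.tanh(reps @ params["attn_W"] + params["attn_b"]) @ params["attn_q"]
    scores = scores.reshape(-1)
    z = scores - scores.max()
    e = np.exp(z)
    alpha = e / e.sum()
    HG = alpha @ reps
    return alpha, HG


def predict_conformer(HGm: np.ndarray, params: dict) -> np.ndarray:
    """Instance head: two-layer ReLU MLP, one scalar per conformer rep."""
    reps = np.atleast_2d(HGm)
    if reps.shape[1] != params["ins_W1"].shape[0]:
        raise ShapeError(
            f"conformer rep width {reps.shape[1]} != {params['ins_W1'].shape[0]}"
        )
    hid = np.maximum(reps @ params["ins_W1"] + params["ins_b1"], 0.0)
    out = (hid @ params["ins_W2"] + params["ins_b2"]).reshape(-1)
    return out[0] if np.asarray(HGm).ndim == 1 else out


def predict_molecule(H1: np.ndarray, HG: np.ndarray, params: dict) -> float:
    """Bag head: two-layer ReLU MLP on [H1, HG]."""
    z = np.concatenate([np.asarray(H1).reshape(-1), np.asarray(HG).reshape(-1)])
    if z.shape[0] != params["bag_W1"].shape[0]:
        raise ShapeError(f"bag input width {z.shape[0]} != {params['bag_W1'].shape[0]}")
    hid = np.maximum(z @ params["bag_W1"] + params["bag_b1"], 0.0)
    out = hid @ params["bag_W2"] + params["bag_b2"]
    return float(np.asarray(out).reshape(()))


def forward_single(
    graph: MolecularGraph, params: dict, config: EquiVSConfig
) -> PredictionResult:
    """Reference forward pass over one molecule (inference, no dropout)."""
    M = min(config.n_conformers, graph.M)
    _, H1 = gcn_encode(graph.A, graph.HV, params, use_gcn=config.use_gcn)
    reps = []
    for m in range(M):
        h = graph.HV
        x = graph.conformer_coords(m).astype(np.float32)
        readouts = []
        for l in range(config.n_layers):
            h, x, readout = egnn_layer(
                graph.A,
                h,
                graph.HE,
                x,
                params,
                l,
                edge_index=graph.edge_index,
                coord_scale_mode=config.coord_scale_mode,
            )
            readouts.append(readout)
        reps.append(skip_concat(readouts) if config.use_skip else readouts[-1])
    reps = np.stack(reps)
    if config.use_attention:
        alpha, HG = attend(reps, params)
    else:
        alpha, HG = None, reps.sum(axis=0)
    yGm = predict_conformer(reps, params)
    yG = predict_molecule(H1, HG, params)
    return PredictionResult(
        molecule_id=graph.molecule_id,
        yG=yG,
        yGm=np.atleast_1d(yGm),
        alpha=alpha,
        label=graph.label_y,
    )


# ---------------------------------------------------------------------------
# Batched training path
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """All conformers of all molecules in a minibatch as one flat graph.

    Bags (molecule, conformer pairs) are ordered molecule-major so that
    reshaping a (B*M,) bag vector to (B, M) groups conformers per molecule.
    """

    B: int
    M: int
    # molecule-level topology (for the GCN)
    HV_mol: np.ndarray
    mol_edge_index: np.ndarray
    node2mol: np.ndarray
    # conformer-level flattened graph
    HV_conf: np.ndarray
    conf_edge_index: np.ndarray
    HE_conf: np.ndarray
    X: np.ndarray               # (total conformer atoms, 3)
    coord_scale: np.ndarray     # per-edge C constant, (E, 1)
    node2bag: np.ndarray
    bag2mol: np.ndarray
    y: np.ndarray | None
    molecule_ids: list[str] = field(default_factory=list)


def make_batch(
    graphs: list[MolecularGraph], M: int, coord_scale_mode: str = "divide"
) -> GraphBatch:
    """Flatten molecules x conformers into one disconnected graph."""
    HV_mol, mol_edges, node2mol = [], [], []
    HV_conf, conf_edges, HE_conf, X, cscale, node2bag = [], [], [], [], [], []
    labels, ids = [], []
    n_off = 0
    c_off = 0
    bag = 0
    for k, g in enumerate(graphs):
        if g.M < M:
            raise ShapeError(
                f"molecule {g.molecule_id!r} has {g.M} conformers, need {M}"
            )
        n = g.n_atoms
        HV_mol.append(g.HV)
        mol_edges.append(g.edge_index + n_off)
        node2mol.append(np.full(n, k, dtype=np.int64))
        n_off += n
        C = coord_scale_constant(n, coord_scale_mode)
        for m in range(M):
            HV_conf.append(g.HV)
            conf_edges.append(g.edge_index + c_off)
            HE_conf.append(g.HE)
            X.append(g.conformer_coords(m))
            cscale.append(np.full((g.edge_index.shape[1], 1), C, dtype=np.float32))
            node2bag.append(np.full(n, bag, dtype=np.int64))
            c_off += n
            bag += 1
        ids.append(g.molecule_id)
        labels.append(g.label_y)
    y = None
    if all(v is not None for v in labels):
        y = np.asarray(labels, dtype=np.float32)
    return GraphBatch(
        B=len(graphs),
        M=M,
        HV_mol=np.concatenate(HV_mol).astype(np.float32),
        mol_edge_index=np.concatenate(mol_edges, axis=1),
        node2mol=np.concatenate(node2mol),
        HV_conf=np.concatenate(HV_conf).astype(np.float32),
        conf_edge_index=np.concatenate(conf_edges, axis=1),
        HE_conf=np.concatenate(HE_conf).astype(np.float32),
        X=np.concatenate(X).astype(np.float32),
        coord_scale=np.concatenate(cscale),
        node2bag=np.concatenate(node2bag),
        bag2mol=np.repeat(np.arange(len(graphs), dtype=np.int64), M),
        y=y,
        molecule_ids=ids,
    )


@dataclass
class ForwardResult:
    """Autodiff tensors of one batched forward pass."""

    yG: Tensor                 # (B,)
    yGm: Tensor                # (B, M)
    alpha: Tensor | None       # (B, M) or None for the no-attention variant
    H1: Tensor
    HG: Tensor
    param_tensors: dict[str, Tensor]


class EquiVS:
    """Trainable model: parameters + batched forward pass."""

    def __init__(self, config: EquiVSConfig, params: dict | None = None):
        self.config = config
        self.params = params if params is not None else init_params(config)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {"version": CHECKPOINT_VERSION, "config": asdict(self.config)}
        meta_arr = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(str(path), __meta__=meta_arr, **self.params)

    @classmethod
    def load(cls, path) -> "EquiVS":
        with np.load(str(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ShapeError(
                    f"unsupported checkpoint version {meta.get('version')}"
                )
            params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(EquiVSConfig(**meta["config"]), params)

    # -- forward -----------------------------------------------------------
    def forward(
        self,
        batch: GraphBatch,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> ForwardResult:
        cfg = self.config
        if batch.M != cfg.n_conformers:
            raise ShapeError(
                f"batch has M={batch.M}, config expects {cfg.n_conformers}"
            )
        p = {k: Tensor(v, requires_grad=True) for k, v in self.params.items()}
        drop = cfg.dropout if train else 0.0
        if drop > 0.0 and rng is None:
            rng = np.random.default_rng(0)

        def dropout(t: Tensor) -> Tensor:
            if drop <= 0.0:
                return t
            mask = (rng.random(t.shape) >= drop).astype(np.float32) / (1.0 - drop)
            return t * Tensor(mask)

        B, M = batch.B, batch.M

        # --- molecule-level topological encoder ---
        hV = Tensor(batch.HV_mol)
        if cfg.use_gcn:
            src, dst = batch.mol_edge_index
            msgs = concat([hV.gather(src), hV.gather(dst)], axis=1)
            msgs = msgs @ p["gcn_phi_e_W"] + p["gcn_phi_e_b"]
            agg = segment_sum(msgs, src, batch.HV_mol.shape[0])
            h1 = concat([hV, agg], axis=1) @ p["gcn_phi_h_W"] + p["gcn_phi_h_b"]
        else:
            h1 = hV @ p["lin_W"] + p["lin_b"]
        h1 = dropout(h1)
        gate = (h1 @ p["readout0_W"] + p["readout0_b"]).sigmoid()
        H1 = segment_sum(gate * h1, batch.node2mol, B)

        # --- conformer-level equivariant stack ---
        h = Tensor(batch.HV_conf)
        x = Tensor(batch.X)
        csrc, cdst = batch.conf_edge_index
        HE = Tensor(batch.HE_conf)
        Cedge = Tensor(batch.coord_scale)
        n_conf_nodes = batch.HV_conf.shape[0]
        readouts = []
        for l in range(cfg.n_layers):
            xi, xj = x.gather(csrc), x.gather(cdst)
            diff = xi - xj
            d2 = (diff * diff).sum(axis=1, keepdims=True)
            inp = concat([h.gather(csrc), h.gather(cdst), d2, HE], axis=1)
            msgs = inp @ p[f"egnn{l}_phi_e_W"] + p[f"egnn{l}_phi_e_b"]
            scal = msgs @ p[f"egnn{l}_phi_x_W"] + p[f"egnn{l}_phi_x_b"]
            x = x + segment_sum(diff * scal * Cedge, csrc, n_conf_nodes)
            agg = segment_sum(msgs, csrc, n_conf_nodes)
            h = concat([h, agg], axis=1) @ p[f"egnn{l}_phi_h_W"] + p[f"egnn{l}_phi_h_b"]
            h = dropout(h)
            rgate = (h @ p[f"egnn{l}_readout_W"] + p[f"egnn{l}_readout_b"]).sigmoid()
            readouts.append(segment_sum(rgate * h, batch.node2bag, B * M))
        Hm = concat(readouts, axis=1) if cfg.use_skip else readouts[-1]

        # --- attention MIL aggregation ---
        alpha: Tensor | None
        if cfg.use_attention:
            scores = (Hm @ p["attn_W"] + p["attn_b"]).tanh() @ p["attn_q"]
            alpha = scores.reshape(B, M).softmax(axis=1)
            HG = segment_sum(Hm * alpha.reshape(B * M, 1), batch.bag2mol, B)
        else:
            alpha = None
            HG = segment_sum(Hm, batch.bag2mol, B)

        # --- prediction heads ---
        ins_hid = dropout((Hm @ p["ins_W1"] + p["ins_b1"]).relu())
        yGm = (ins_hid @ p["ins_W2"] + p["ins_b2"]).reshape(B, M)
        bag_in = concat([H1, HG], axis=1)
        bag_hid = dropout((bag_in @ p["bag_W1"] + p["bag_b1"]).relu())
        yG = (bag_hid @ p["bag_W2"] + p["bag_b2"]).reshape(B)

        return ForwardResult(yG=yG, yGm=yGm, alpha=alpha, H1=H1, HG=HG, param_tensors=p)

    # -- inference ---------------------------------------------------------
    def predict(
        self, graphs: list[MolecularGraph], batch_size: int = 128
    ) -> list[PredictionResult]:
        cfg = self.config
        results: list[PredictionResult] = []
        for start in range(0, len(graphs), batch_size):
            chunk = graphs[start : start + batch_size]
            batch = make_batch(chunk, cfg.n_conformers, cfg.coord_scale_mode)
            out = self.forward(batch, train=False)
            yG = out.yG.value
            yGm = out.yGm.value
            alpha = out.alpha.value if out.alpha is not None else None
            for i, g in enumerate(chunk):
                results.append(
                    PredictionResult(
                        molecule_id=g.molecule_id,
                        yG=float(yG[i]),
                        yGm=yGm[i].copy(),
                        alpha=None if alpha is None else alpha[i].copy(),
                        label=g.label_y,
                    )
                )
        return results

    def attention_coefficients(self, graphs: list[MolecularGraph]) -> np.ndarray:
        if not self.config.use_attention:
            raise AttentionUnavailableError(
                "this variant replaced attention with an unweighted sum"
            )
        return np.stack([r.alpha for r in self.predict(graphs)])
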