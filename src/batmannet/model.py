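"""Bi-branch asymmetric masked graph transformer autoencoder.

Two parallel autoencoders — a node branch over atoms and an edge branch over
directed bonds (the dual graph) — share one architecture:

* input linear projection to hidden size ``d`` plus absolute sinusoidal
  positional encodings indexed by the parser's element order;
* a stack of GNN-Attention blocks: queries, keys and values each come from a
  small K-hop message-passing GNN (weights shared across the K hops of a
  stack), followed by multi-head scaled dot-product attention over all
  elements of the same molecule, with post-norm residual feed-forward;
* at the encoder's end, a neighbor-sum aggregation (for the edge branch with
  the N(v)\\w exclusion), a long-range residual from the projected raw
  features, and a final feed-forward + layer norm;
* a Feature Reordering step that scatters visible latents back to their
  original positions, fills masked slots with a learned per-branch mask
  token, and re-adds positional encodings;
* a lightweight decoder (M < N blocks) over the full, unmasked adjacency and
  a linear reconstruction head whose width is the branch's categorical
  feature dimensionality.

The encoder sees only the visible subset: masked raw features are absent
from its inputs by construction, never merely zeroed.

Molecules in a batch are concatenated into one disjoint-union graph with a
block-diagonal additive attention mask, so no padding is ever materialised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem import FeatureSchema, default_atom_schema, default_bond_schema
from .errors import (ConfigError, EncodeError, NumericalError, ReorderError,
                     ShapeError)
from .masking import apply_mask

__all__ = ["ModelConfig", "EmbeddingSet", "BranchBatch", "BatmanNet",
           "sinusoidal_positions", "gnn_hop", "assemble_full_batch",
           "assemble_masked_batch"]

NEG_INF = -1e9


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the reference configuration: hidden size 100, 6 encoder and
    2 decoder GNN-Attention blocks per branch, 3 GNN hops and 2 attention
    heads per block, feed-forward width 256.
    """

    hidden: int = 100
    n_encoder: int = 6
    n_decoder: int = 2
    gnn_hops: int = 3
    heads: int = 2
    ffn_dim: int = 256
    branches: tuple = ("node", "edge")

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ConfigError("hidden size must be divisible by the head count")
        if self.hidden % 2:
            raise ConfigError("hidden size must be even for sinusoidal positions")
        if not (self.n_encoder >= 1 and self.n_decoder >= 1 and
                self.gnn_hops >= 1 and self.heads >= 1 and self.ffn_dim >= 1):
            raise ConfigError("all architecture counts must be >= 1")
        if self.n_decoder >= self.n_encoder:
            raise ConfigError("decoder must be shallower than the encoder (M < N)")
        if not self.branches or any(b not in ("node", "edge") for b in self.branches):
            raise ConfigError("branches must be a non-empty subset of ('node', 'edge')")

    @property
    def d_head(self) -> int:
        return self.hidden // self.heads

    def to_dict(self) -> dict:
        return {"hidden": self.hidden, "n_encoder": self.n_encoder,
                "n_decoder": self.n_decoder, "gnn_hops": self.gnn_hops,
                "heads": self.heads, "ffn_dim": self.ffn_dim,
                "branches": list(self.branches)}

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        doc = dict(doc)
        doc["branches"] = tuple(doc.get("branches", ("node", "edge")))
        return cls(**doc)


@dataclass
class EmbeddingSet:
    """Hidden matrix for one branch at some network stage, with the original
    element positions each row corresponds to."""

    H: np.ndarray
    positions: np.ndarray
    branch: str


# -------------------------------------------------------------- positional
def sinusoidal_positions(max_pos: int, d: int) -> np.ndarray:
    """Classic absolute sinusoidal table: row p holds sin(p / 10000^(2i/d))
    at even columns and the matching cos at odd columns."""
    if d % 2:
        raise ConfigError("positional encoding dimension must be even")
    pos = np.arange(max_pos, dtype=np.float64)[:, None]
    i = np.arange(d // 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d)
    table = np.zeros((max_pos, d), dtype=np.float64)
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


# ------------------------------------------------------------------- batching
@dataclass
class BranchBatch:
    """Disjoint union of per-molecule element sets for one branch.

    ``msg_src -> msg_dst`` lists every directed message of the GNN stage
    (atom-level directed edges for the node branch; dual-node predecessor
    links for the edge branch), in batch-local element indices.
    """

    features: np.ndarray                 # (n, F) raw input features
    positions: np.ndarray                # (n,) within-molecule original index
    mol_ids: np.ndarray                  # (n,)
    msg_src: np.ndarray
    msg_dst: np.ndarray
    msg_edge_feats: np.ndarray | None    # (n_msg, F_bond) node branch only

    @property
    def n(self) -> int:
        return int(self.features.shape[0])


def _stack_branch(per_mol) -> BranchBatch:
    """Concatenate per-molecule (features, positions, msg_src, msg_dst,
    edge_feats) tuples with index offsets."""
    feats, poss, mids, srcs, dsts, efs = [], [], [], [], [], []
    offset = 0
    for mid, (f, p, s, d, ef) in enumerate(per_mol):
        feats.append(f)
        poss.append(p)
        mids.append(np.full(len(p), mid, dtype=np.int64))
        srcs.append(np.asarray(s, dtype=np.int64) + offset)
        dsts.append(np.asarray(d, dtype=np.int64) + offset)
        if ef is not None:
            efs.append(ef)
        offset += len(p)
    any_ef = bool(efs)
    return BranchBatch(
        features=np.concatenate(feats) if feats else np.zeros((0, 0)),
        positions=np.concatenate(poss).astype(np.int64) if poss else np.zeros(0, np.int64),
        mol_ids=np.concatenate(mids) if mids else np.zeros(0, np.int64),
        msg_src=np.concatenate(srcs) if srcs else np.zeros(0, np.int64),
        msg_dst=np.concatenate(dsts) if dsts else np.zeros(0, np.int64),
        msg_edge_feats=np.concatenate(efs) if any_ef else None,
    )


def assemble_full_batch(graphs, duals):
    """Full (unmasked) node and edge BranchBatches for a list of molecules."""
    node = _stack_branch([
        (g.atom_features, np.arange(g.n_atoms),
         g.directed_edges[:, 0], g.directed_edges[:, 1], g.bond_features)
        for g in graphs])
    per_dual = []
    for d in duals:
        src = [p for preds in d.predecessors for p in preds]
        dst = [e for e, preds in enumerate(d.predecessors) for _ in preds]
        per_dual.append((d.dual_node_features, np.arange(d.n_dual_nodes),
                         src, dst, None))
    edge = _stack_branch(per_dual)
    return node, edge


@dataclass
class MaskedBatch:
    """Everything one pre-training step needs: visible batches for the
    encoder, full batches for the decoder, and the global index bookkeeping
    linking the two (Feature Reordering)."""

    node_vis: BranchBatch
    edge_vis: BranchBatch
    node_full: BranchBatch
    edge_full: BranchBatch
    node_vis_idx: np.ndarray     # global full-row index of each visible row
    node_mask_idx: np.ndarray
    edge_vis_idx: np.ndarray
    edge_mask_idx: np.ndarray
    node_targets: np.ndarray     # full-length one-hot atom features
    edge_targets: np.ndarray     # full-length one-hot bond features (per dual node)


def assemble_masked_batch(graphs, duals, plans) -> MaskedBatch:
    node_full, edge_full = assemble_full_batch(graphs, duals)
    per_node, per_edge = [], []
    nvis, nmask, evis, emask = [], [], [], []
    n_off = e_off = 0
    for g, d, plan in zip(graphs, duals, plans):
        ni, ei = apply_mask(g, d, plan)
        per_node.append((ni.features, ni.positions, ni.msg_src, ni.msg_dst,
                         ni.msg_edge_feats))
        per_edge.append((ei.features, ei.positions, ei.msg_src, ei.msg_dst, None))
        nvis.append(plan.visible_nodes + n_off)
        nmask.append(plan.masked_nodes + n_off)
        evis.append(plan.visible_dual + e_off)
        emask.append(plan.masked_dual + e_off)
        n_off += g.n_atoms
        e_off += d.n_dual_nodes
    cat = lambda xs: (np.concatenate(xs).astype(np.int64) if xs
                      else np.zeros(0, np.int64))
    edge_targets = (np.concatenate([g.bond_features for g in graphs])
                    if graphs else np.zeros((0, 0)))
    return MaskedBatch(
        node_vis=_stack_branch(per_node), edge_vis=_stack_branch(per_edge),
        node_full=node_full, edge_full=edge_full,
        node_vis_idx=cat(nvis), node_mask_idx=cat(nmask),
        edge_vis_idx=cat(evis), edge_mask_idx=cat(emask),
        node_targets=node_full.features.copy(),
        edge_targets=edge_targets,
    )


# ------------------------------------------------------------------ the model
def _glorot(rng, fan_in, fan_out):
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_in, fan_out))


def gnn_hop(H: Tensor, msg_src, msg_dst, n: int, weights: dict,
            edge_feats: np.ndarray | None = None) -> Tensor:
    """One message-passing hop: each directed message transforms the source
    state (concatenated with its bond features in the node branch), messages
    are sum-aggregated at their destination, and the update
    ``h' = relu(W m + b)`` is applied.  Elements with no messages keep
    ``m = 0`` and output ``relu(b)``."""
    if H.shape[1] != weights["upd_W"].shape[0]:
        raise ShapeError("hidden size does not match hop weights")
    if len(msg_src):
        src_h = ad.gather_rows(H, msg_src)
        inp = (ad.concat([src_h, Tensor(edge_feats)], axis=1)
               if edge_feats is not None else src_h)
        msg = inp @ weights["msg_W"] + weights["msg_b"]
        m = ad.segment_sum(msg, msg_dst, n)
    else:
        m = Tensor(np.zeros((n, weights["upd_W"].shape[0])))
    return ad.relu(m @ weights["upd_W"] + weights["upd_b"])


class BatmanNet:
    """Both branches of the autoencoder plus their reconstruction heads.

    Parameters live in a flat name -> Tensor dict; initialisation is
    deterministic in the seed.
    """

    def __init__(self, config: ModelConfig | None = None,
                 atom_schema: FeatureSchema | None = None,
                 bond_schema: FeatureSchema | None = None,
                 seed: int = 0):
        self.config = config or ModelConfig()
        self.atom_schema = atom_schema or default_atom_schema()
        self.bond_schema = bond_schema or default_bond_schema()
        self.seed = int(seed)
        self.params: dict[str, Tensor] = {}
        self._build(np.random.default_rng(np.random.SeedSequence(self.seed)))
        self._pos_cache: np.ndarray | None = None

    # ------------------------------------------------------------ parameters
    def _add(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True, name=name)
        self.params[name] = t
        return t

    def _add_linear(self, rng, name, fan_in, fan_out):
        self._add(f"{name}.W", _glorot(rng, fan_in, fan_out))
        self._add(f"{name}.b", np.zeros(fan_out))

    def _add_ln(self, name):
        self._add(f"{name}.g", np.ones(self.config.hidden))
        self._add(f"{name}.b", np.zeros(self.config.hidden))

    def _build(self, rng):
        c = self.config
        d = c.hidden
        dims = {"node": self.atom_schema.total_dim,
                "edge": self.atom_schema.total_dim + self.bond_schema.total_dim}
        msg_in = {"node": d + self.bond_schema.total_dim, "edge": d}
        head_out = {"node": self.atom_schema.total_dim,
                    "edge": self.bond_schema.total_dim}
        for br in c.branches:
            self._add_linear(rng, f"{br}.in_proj", dims[br], d)
            self._add_linear(rng, f"{br}.res_proj", dims[br], d)
            for stage, count in (("enc", c.n_encoder), ("dec", c.n_decoder)):
                for i in range(count):
                    base = f"{br}.{stage}{i}"
                    for gate in ("q_gnn", "k_gnn", "v_gnn"):
                        self._add_linear(rng, f"{base}.{gate}.msg", msg_in[br], d)
                        self._add_linear(rng, f"{base}.{gate}.upd", d, d)
                    for proj in ("Wq", "Wk", "Wv", "Wo"):
                        self._add_linear(rng, f"{base}.attn.{proj}", d, d)
                    self._add_ln(f"{base}.ln1")
                    self._add_linear(rng, f"{base}.ffn.W1", d, c.ffn_dim)
                    self._add_linear(rng, f"{base}.ffn.W2", c.ffn_dim, d)
                    self._add_ln(f"{base}.ln2")
            self._add_linear(rng, f"{br}.fin.ffn.W1", d, c.ffn_dim)
            self._add_linear(rng, f"{br}.fin.ffn.W2", c.ffn_dim, d)
            self._add_ln(f"{br}.fin.ln")
            self._add(f"{br}.mask_token", rng.normal(0.0, 0.02, size=d))
            self._add_linear(rng, f"{br}.head", d, head_out[br])

    def parameters(self):
        return self.params

    @property
    def n_parameters(self) -> int:
        return sum(t.size for t in self.params.values())

    # ---------------------------------------------------------------- helpers
    def _positions(self, max_pos: int) -> np.ndarray:
        if self._pos_cache is None or self._pos_cache.shape[0] < max_pos:
            self._pos_cache = sinusoidal_positions(max(max_pos, 64), self.config.hidden)
        return self._pos_cache

    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _ffn(self, name: str, x: Tensor) -> Tensor:
        h = ad.relu(x @ self.params[f"{name}.W1.W"] + self.params[f"{name}.W1.b"])
        return h @ self.params[f"{name}.W2.W"] + self.params[f"{name}.W2.b"]

    def _ln(self, name: str, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.params[f"{name}.g"], self.params[f"{name}.b"])

    def _hop_weights(self, base: str) -> dict:
        return {"msg_W": self.params[f"{base}.msg.W"],
                "msg_b": self.params[f"{base}.msg.b"],
                "upd_W": self.params[f"{base}.upd.W"],
                "upd_b": self.params[f"{base}.upd.b"]}

    def _gnn_stack(self, base: str, H: Tensor, batch: BranchBatch) -> Tensor:
        w = self._hop_weights(base)
        for _ in range(self.config.gnn_hops):
            H = gnn_hop(H, batch.msg_src, batch.msg_dst, batch.n, w,
                        edge_feats=batch.msg_edge_feats)
        return H

    def _attention(self, base: str, Q: Tensor, K: Tensor, V: Tensor,
                   attn_mask: np.ndarray) -> Tensor:
        c = self.config
        n = Q.shape[0]
        heads = []
        Qp = self._linear(f"{base}.Wq", Q).reshape(n, c.heads, c.d_head).transpose((1, 0, 2))
        Kp = self._linear(f"{base}.Wk", K).reshape(n, c.heads, c.d_head).transpose((1, 0, 2))
        Vp = self._linear(f"{base}.Wv", V).reshape(n, c.heads, c.d_head).transpose((1, 0, 2))
        logits = Qp @ Kp.transpose((0, 2, 1)) * (1.0 / np.sqrt(c.d_head)) + Tensor(attn_mask)
        if not np.isfinite(logits.data[np.broadcast_to(attn_mask == 0.0, logits.shape)]).all():
            raise NumericalError("non-finite attention logits")
        A = ad.softmax(logits, axis=-1)
        out = (A @ Vp).transpose((1, 0, 2)).reshape(n, c.hidden)
        return self._linear(f"{base}.Wo", out)

    def _block(self, base: str, H: Tensor, batch: BranchBatch,
               attn_mask: np.ndarray) -> Tensor:
        Q = self._gnn_stack(f"{base}.q_gnn", H, batch)
        K = self._gnn_stack(f"{base}.k_gnn", H, batch)
        V = self._gnn_stack(f"{base}.v_gnn", H, batch)
        H = self._ln(f"{base}.ln1", H + self._attention(f"{base}.attn", Q, K, V, attn_mask))
        return self._ln(f"{base}.ln2", H + self._ffn(f"{base}.ffn", H))

    @staticmethod
    def _attn_mask(mol_ids: np.ndarray) -> np.ndarray:
        same = mol_ids[:, None] == mol_ids[None, :]
        return np.where(same, 0.0, NEG_INF)

    # ------------------------------------------------------------- main paths
    def encode(self, branch: str, batch: BranchBatch) -> Tensor:
        """Run the encoder of one branch on a (possibly visible-restricted)
        batch.  Output depends only on the elements present in the batch."""
        if branch not in self.config.branches:
            raise ConfigError(f"branch {branch!r} not instantiated")
        if batch.n == 0:
            raise EncodeError("encoder invoked on an empty visible set")
        pos = self._positions(int(batch.positions.max()) + 1)
        X0 = Tensor(batch.features)
        H = self._linear(f"{branch}.in_proj", X0) + Tensor(pos[batch.positions])
        mask = self._attn_mask(batch.mol_ids)
        for i in range(self.config.n_encoder):
            H = self._block(f"{branch}.enc{i}", H, batch, mask)
        return self.branch_finalize(branch, H, batch)

    def branch_finalize(self, branch: str, H: Tensor, batch: BranchBatch) -> Tensor:
        """Neighbor-sum aggregation (edge branch: over N(v)\\w predecessors),
        long-range residual from projected raw features, feed-forward + norm."""
        if len(batch.msg_src):
            m = ad.segment_sum(ad.gather_rows(H, batch.msg_src), batch.msg_dst, batch.n)
        else:
            m = Tensor(np.zeros((batch.n, self.config.hidden)))
        z = m + self._linear(f"{branch}.res_proj", Tensor(batch.features))
        return self._ln(f"{branch}.fin.ln", z + self._ffn(f"{branch}.fin.ffn", z))

    def reorder_features(self, branch: str, latent: Tensor,
                         vis_idx: np.ndarray, mask_idx: np.ndarray,
                         full_positions: np.ndarray) -> Tensor:
        """Feature Reordering: visible latents return to their original rows,
        masked rows get the branch mask token, and positional encodings are
        re-added everywhere."""
        n_total = len(full_positions)
        occupied = np.concatenate([vis_idx, mask_idx])
        if len(np.unique(occupied)) != n_total or (len(occupied) and
                                                   occupied.max() >= n_total):
            raise ReorderError("visible/masked positions do not partition the rows")
        if latent.shape[0] != len(vis_idx):
            raise ReorderError("latent row count does not match visible positions")
        pos = self._positions(int(full_positions.max()) + 1 if n_total else 1)
        X = ad.segment_sum(latent, vis_idx, n_total)
        if len(mask_idx):
            token = self.params[f"{branch}.mask_token"].reshape(1, self.config.hidden)
            tok_rows = Tensor(np.ones((len(mask_idx), 1))) @ token
            X = X + ad.segment_sum(tok_rows, mask_idx, n_total)
        return X + Tensor(pos[full_positions])

    def decode(self, branch: str, X: Tensor, full_batch: BranchBatch) -> Tensor:
        """Lightweight decoder: M GNN-Attention blocks on the full adjacency."""
        mask = self._attn_mask(full_batch.mol_ids)
        for i in range(self.config.n_decoder):
            X = self._block(f"{branch}.dec{i}", X, full_batch, mask)
        return X

    def reconstruct_logits(self, branch: str, decoded: Tensor) -> Tensor:
        head_W = self.params[f"{branch}.head.W"]
        if decoded.shape[1] != head_W.shape[0]:
            raise ShapeError("decoded width does not match the reconstruction head")
        return self._linear(f"{branch}.head", decoded)

    def forward_pretrain(self, mb: MaskedBatch):
        """Encoder -> reorder -> decoder -> heads for both branches.

        Returns ``(node_logits, edge_logits)``; a branch that is not
        instantiated, or whose batch is empty, yields None.
        """
        out = {"node": None, "edge": None}
        specs = {
            "node": (mb.node_vis, mb.node_full, mb.node_vis_idx, mb.node_mask_idx),
            "edge": (mb.edge_vis, mb.edge_full, mb.edge_vis_idx, mb.edge_mask_idx),
        }
        for br in self.config.branches:
            vis, full, vis_idx, mask_idx = specs[br]
            if full.n == 0:
                continue
            latent = self.encode(br, vis)
            X = self.reorder_features(br, latent, vis_idx, mask_idx, full.positions)
            out[br] = self.reconstruct_logits(br, self.decode(br, X, full))
        return out["node"], out["edge"]

    # ----------------------------------------------------- downstream helpers
    def encode_graphs(self, graphs, duals):
        """Full-graph (rho = 0) encoder pass; returns per-branch element
        embeddings and mol ids, for readout/fine-tuning."""
        node_b, edge_b = assemble_full_batch(graphs, duals)
        res = {}
        if "node" in self.config.branches and node_b.n:
            res["node"] = (self.encode("node", node_b), node_b.mol_ids)
        if "edge" in self.config.branches and edge_b.n:
            res["edge"] = (self.encode("edge", edge_b), edge_b.mol_ids)
        return res

    # -------------------------------------------------------------- state i/o
    def state_arrays(self) -> dict:
        return {name: t.data for name, t in self.params.items()}

    def load_state(self, arrays: dict):
        for name, t in self.params.items():
            if name not in arrays:
                raise ShapeError(f"checkpoint missing parameter {name}")
            if arrays[name].shape != t.data.shape:
                raise ShapeError(f"shape mismatch for {name}")
            t.data = np.asarray(arrays[name], dtype=np.float64).copy()
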