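"""Masked-reconstruction pre-training.

The objective is multi-label categorical reconstruction restricted to masked
elements: per masked atom (node branch) or masked directed bond (edge
branch), each categorical feature block contributes a softmax cross-entropy
term against its one-hot target; block losses are summed per element and
averaged over the branch's masked elements, and the total is

    L_pretrain = L_node + L_edge        (exactly, by construction).

Optimisation is Adam under the Noam learning-rate schedule
``d^-0.5 * min(step^-0.5, step * warmup^-1.5)`` with global-norm gradient
clipping.  Masks are resampled fresh for every molecule at every step from
per-(seed, step, molecule) substreams, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .chem import (FeatureSchema, default_atom_schema, default_bond_schema,
                   featurize)
from .errors import DataError, LossError, NumericalError, ParseError
from .masking import MaskPlan, sample_mask
from .model import BatmanNet, ModelConfig, assemble_masked_batch

__all__ = ["LossReport", "TrainConfig", "reconstruction_loss", "noam_lr",
           "Adam", "pretrain", "count_parameters",
           "masked_reconstruction_accuracy", "prepare_corpus"]


# ----------------------------------------------------------------------- loss
@dataclass
class LossReport:
    """Branch and total reconstruction losses over masked elements only."""

    L_node: float
    L_edge: float
    L_pretrain: float
    node_blocks: dict
    edge_blocks: dict
    n_masked_nodes: int
    n_masked_edges: int
    loss: Tensor = field(repr=False, default=None)   # backprop handle


def _branch_loss(logits: Tensor, targets: np.ndarray, mask_idx: np.ndarray,
                 schema: FeatureSchema):
    """Mean-over-masked-elements of the summed per-block cross-entropies."""
    logits_m = ad.gather_rows(logits, mask_idx)
    targets_m = targets[mask_idx]
    total = None
    blocks = {}
    for name, start, stop in schema.block_slices:
        lsm = ad.log_softmax(logits_m.slice_cols(start, stop), axis=-1)
        ce = -(lsm * Tensor(targets_m[:, start:stop])).sum(axis=-1)
        blocks[name] = float(ce.mean().item())
        total = ce if total is None else total + ce
    return total.mean(), blocks


def reconstruction_loss(node_logits, edge_logits, node_targets, edge_targets,
                        plan: MaskPlan | None = None, *,
                        node_mask_idx=None, edge_mask_idx=None,
                        atom_schema: FeatureSchema | None = None,
                        bond_schema: FeatureSchema | None = None) -> LossReport:
    """Reconstruction loss restricted to masked positions.

    Logits and targets are full-length (one row per element of the original
    graph).  Masked positions come from `plan` or from explicit index arrays.
    A branch with no masked elements (or no logits, for single-branch
    models) contributes exactly 0; if *both* branches are empty there is
    nothing to reconstruct and :class:`LossError` is raised.
    """
    atom_schema = atom_schema or default_atom_schema()
    bond_schema = bond_schema or default_bond_schema()
    if plan is not None:
        node_mask_idx = plan.masked_nodes
        edge_mask_idx = plan.masked_dual
    node_mask_idx = np.asarray(node_mask_idx if node_mask_idx is not None else [],
                               dtype=np.int64)
    edge_mask_idx = np.asarray(edge_mask_idx if edge_mask_idx is not None else [],
                               dtype=np.int64)
    do_node = node_logits is not None and node_mask_idx.size > 0
    do_edge = edge_logits is not None and edge_mask_idx.size > 0
    if not do_node and not do_edge:
        raise LossError("no masked elements in either branch: nothing to reconstruct")

    zero = Tensor(0.0)
    if do_node:
        node_logits = node_logits if isinstance(node_logits, Tensor) else Tensor(node_logits)
        l_node, nb = _branch_loss(node_logits, np.asarray(node_targets),
                                  node_mask_idx, atom_schema)
    else:
        l_node, nb = zero, {}
    if do_edge:
        edge_logits = edge_logits if isinstance(edge_logits, Tensor) else Tensor(edge_logits)
        l_edge, eb = _branch_loss(edge_logits, np.asarray(edge_targets),
                                  edge_mask_idx, bond_schema)
    else:
        l_edge, eb = zero, {}
    total = l_node + l_edge
    return LossReport(L_node=float(l_node.item()), L_edge=float(l_edge.item()),
                      L_pretrain=float(l_node.item()) + float(l_edge.item()),
                      node_blocks=nb, edge_blocks=eb,
                      n_masked_nodes=int(node_mask_idx.size),
                      n_masked_edges=int(edge_mask_idx.size),
                      loss=total)


# ------------------------------------------------------------------ optimiser
def noam_lr(step: int, d: int, warmup: int) -> float:
    """Noam schedule: linear warmup then inverse-sqrt decay, scaled by
    d^-0.5.  The two branches of the min cross at step == warmup."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if warmup < 1:
        raise ValueError("warmup must be >= 1")
    return d ** -0.5 * min(step ** -0.5, step * warmup ** -1.5)


class Adam:
    """Adam over a name -> Tensor parameter dict, with optional global-norm
    gradient clipping."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def step(self, lr: float):
        grads = {k: t.grad for k, t in self.params.items() if t.grad is not None}
        if self.clip_norm is not None and grads:
            norm = math.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            self.params[k].data -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------------- training
@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    total_steps: int = 1000
    warmup: int = 1000
    mask_ratio: float = 0.6
    seed: int = 0
    val_fraction: float = 0.1
    lr_factor: float = 1.0
    clip_norm: float = 5.0
    eval_every: int = 50

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.warmup < 1:
            raise ValueError("warmup must be >= 1")


def prepare_corpus(smiles_list, atom_schema=None, bond_schema=None):
    """Parse and featurize a SMILES corpus, dropping unparsable strings and
    molecules with fewer than 2 heavy atoms.  Returns (graphs, duals, rejects)."""
    graphs, duals, rejects = [], [], []
    for smi in smiles_list:
        try:
            g, d = featurize(smi, atom_schema, bond_schema)
        except ParseError:
            rejects.append(smi)
            continue
        if g.n_atoms < 2:
            rejects.append(smi)
            continue
        graphs.append(g)
        duals.append(d)
    return graphs, duals, rejects


def _step_plans(graphs, duals, indices, ratio, seed, tag, step):
    plans = []
    for j, idx in enumerate(indices):
        ss = np.random.SeedSequence([seed, tag, step, int(idx)])
        plans.append(sample_mask(graphs[idx].n_atoms, duals[idx].n_dual_nodes,
                                 ratio, ss))
    return plans


def _eval_loss(model, graphs, duals, indices, ratio, seed, step):
    plans = _step_plans(graphs, duals, indices, ratio, seed, 1299709, step)
    mb = assemble_masked_batch([graphs[i] for i in indices],
                               [duals[i] for i in indices], plans)
    nl, el = model.forward_pretrain(mb)
    rep = reconstruction_loss(nl, el, mb.node_targets, mb.edge_targets,
                              node_mask_idx=mb.node_mask_idx,
                              edge_mask_idx=mb.edge_mask_idx,
                              atom_schema=model.atom_schema,
                              bond_schema=model.bond_schema)
    return rep


def pretrain(corpus, model_config: ModelConfig | None = None,
             train_config: TrainConfig | None = None,
             atom_schema=None, bond_schema=None, model: BatmanNet | None = None):
    """Run masked-reconstruction pre-training on a SMILES corpus.

    Returns ``(model, history)`` where `model` carries the best-validation
    weights and `history` is a step-indexed DataFrame of learning rate and
    train/validation losses.
    """
    tc = train_config or TrainConfig()
    graphs, duals, _rejects = prepare_corpus(corpus, atom_schema, bond_schema)
    if not graphs:
        raise DataError("corpus empty after the >=2-atom filter")

    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 7919]))
    order = rng.permutation(len(graphs))
    n_val = int(round(tc.val_fraction * len(graphs)))
    n_val = min(n_val, len(graphs) - 1)
    val_idx = order[:n_val]
    train_idx = order[n_val:]

    if model is None:
        model = BatmanNet(model_config or ModelConfig(),
                          atom_schema or default_atom_schema(),
                          bond_schema or default_bond_schema(), seed=tc.seed)
    opt = Adam(model.parameters(), clip_norm=tc.clip_norm)
    d = model.config.hidden

    history = []
    best_val = np.inf
    best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    epoch_order = rng.permutation(train_idx)
    cursor = 0
    for step in range(1, tc.total_steps + 1):
        if cursor >= len(epoch_order):
            epoch_order = rng.permutation(train_idx)
            cursor = 0
        batch_idx = epoch_order[cursor:cursor + tc.batch_size]
        cursor += tc.batch_size

        plans = _step_plans(graphs, duals, batch_idx, tc.mask_ratio, tc.seed,
                            104729, step)
        mb = assemble_masked_batch([graphs[i] for i in batch_idx],
                                   [duals[i] for i in batch_idx], plans)
        nl, el = model.forward_pretrain(mb)
        rep = reconstruction_loss(nl, el, mb.node_targets, mb.edge_targets,
                                  node_mask_idx=mb.node_mask_idx,
                                  edge_mask_idx=mb.edge_mask_idx,
                                  atom_schema=model.atom_schema,
                                  bond_schema=model.bond_schema)
        if not np.isfinite(rep.L_pretrain):
            raise NumericalError(f"divergent loss at step {step}: {rep.L_pretrain}")
        opt.zero_grad()
        rep.loss.backward()
        lr = tc.lr_factor * noam_lr(step, d, tc.warmup)
        opt.step(lr)

        row = {"step": step, "lr": lr, "train_L_node": rep.L_node,
               "train_L_edge": rep.L_edge, "train_L_pretrain": rep.L_pretrain,
               "val_L_node": np.nan, "val_L_edge": np.nan,
               "val_L_pretrain": np.nan}
        if len(val_idx) and (step % tc.eval_every == 0 or step == tc.total_steps):
            vrep = _eval_loss(model, graphs, duals, val_idx, tc.mask_ratio,
                              tc.seed, step)
            row.update(val_L_node=vrep.L_node, val_L_edge=vrep.L_edge,
                       val_L_pretrain=vrep.L_pretrain)
            if vrep.L_pretrain < best_val:
                best_val = vrep.L_pretrain
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        history.append(row)

    if len(val_idx):
        model.load_state(best_state)
    return model, pd.DataFrame(history)


def count_parameters(config: ModelConfig | None = None,
                     atom_schema=None, bond_schema=None) -> int:
    """Exact count of trainable scalars in the full autoencoder (both
    branches' encoder + decoder blocks, projections, finalisation layers,
    mask tokens and reconstruction heads)."""
    return BatmanNet(config or ModelConfig(), atom_schema, bond_schema,
                     seed=0).n_parameters


def masked_reconstruction_accuracy(model: BatmanNet, graphs, duals, plans,
                                   block: str = "element") -> float:
    """Fraction of masked atoms whose predicted category in `block` (argmax
    of the node-branch logits) matches the one-hot target."""
    mb = assemble_masked_batch(graphs, duals, plans)
    nl, _el = model.forward_pretrain(mb)
    if nl is None or not mb.node_mask_idx.size:
        raise LossError("no masked atoms to score")
    for name, start, stop in model.atom_schema.block_slices:
        if name == block:
            pred = nl.data[mb.node_mask_idx, start:stop].argmax(axis=1)
            true = mb.node_targets[mb.node_mask_idx, start:stop].argmax(axis=1)
            return float((pred == true).mean())
    raise KeyError(f"no atom feature block named {block!r}")
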