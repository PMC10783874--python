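"""Bi-branch random masking.

Each branch (atoms; directed dual bonds) is masked independently at ratio
rho: ``floor(rho * n)`` elements are hidden, sampled uniformly without
replacement.  The directed scheme means (u, v) and (v, u) are distinct
maskable elements — hiding one says nothing about the other.  One seed per
molecule is split into a node sub-stream and a dual sub-stream so the two
branch masks are independent yet jointly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import DualGraph, MoleculeGraph
from .errors import MaskError

__all__ = ["MaskPlan", "VisibleInputs", "sample_mask", "apply_mask"]


@dataclass(frozen=True)
class MaskPlan:
    """Visible/masked index partition for both branches, with RNG provenance."""

    ratio: float
    visible_nodes: np.ndarray
    masked_nodes: np.ndarray
    visible_dual: np.ndarray
    masked_dual: np.ndarray
    seed: int


@dataclass
class VisibleInputs:
    """Encoder-visible slice of one branch: features and positions of visible
    elements only, with adjacency restricted to visible-visible links.
    Masked features are absent, not zeroed."""

    features: np.ndarray        # (n_visible, F)
    positions: np.ndarray       # original element indices
    msg_src: np.ndarray         # local (visible-relative) source of each message
    msg_dst: np.ndarray         # local destination
    msg_edge_feats: np.ndarray | None   # bond features per message (node branch only)


def _mask_counts(n: int, ratio: float) -> int:
    k = int(np.floor(ratio * n))
    if ratio > 0 and n >= 2:
        k = max(k, 1)           # always something to reconstruct
        k = min(k, n - 1)       # always something visible
    return k


def sample_mask(n_atoms: int, n_dual: int, ratio: float, rng_state) -> MaskPlan:
    """Sample a bi-branch mask plan.

    `rng_state` is an integer seed or a ``numpy.random.SeedSequence``; it is
    split into independent node and dual sub-streams.  Deterministic: the same
    state yields the same plan.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"masking ratio must be in [0, 1], got {ratio}")
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if isinstance(rng_state, np.random.SeedSequence):
        ss = rng_state
        seed = int(ss.entropy) if isinstance(ss.entropy, int) else -1
    else:
        seed = int(rng_state)
        ss = np.random.SeedSequence(seed)
    node_ss, dual_ss = ss.spawn(2)
    node_rng = np.random.default_rng(node_ss)
    dual_rng = np.random.default_rng(dual_ss)

    k_nodes = _mask_counts(n_atoms, ratio)
    masked_nodes = np.sort(node_rng.choice(n_atoms, size=k_nodes, replace=False))
    visible_nodes = np.setdiff1d(np.arange(n_atoms), masked_nodes)

    k_dual = _mask_counts(n_dual, ratio) if n_dual > 0 else 0
    masked_dual = (np.sort(dual_rng.choice(n_dual, size=k_dual, replace=False))
                   if n_dual > 0 else np.zeros(0, dtype=np.int64))
    visible_dual = np.setdiff1d(np.arange(n_dual), masked_dual)

    return MaskPlan(ratio=ratio,
                    visible_nodes=visible_nodes.astype(np.int64),
                    masked_nodes=masked_nodes.astype(np.int64),
                    visible_dual=visible_dual.astype(np.int64),
                    masked_dual=masked_dual.astype(np.int64),
                    seed=seed)


def _check_indices(idx: np.ndarray, n: int, what: str):
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise MaskError(f"{what} indices out of range [0, {n})")


def apply_mask(graph: MoleculeGraph, dual: DualGraph, plan: MaskPlan):
    """Restrict a featurized molecule to the plan's visible subsets.

    Returns ``(node_inputs, dual_inputs)`` as :class:`VisibleInputs`.  The
    node branch keeps directed edges whose endpoints are both visible (with
    their bond features — messages need them); the dual branch keeps
    predecessor links between visible dual nodes.
    """
    _check_indices(plan.visible_nodes, graph.n_atoms, "visible node")
    _check_indices(plan.masked_nodes, graph.n_atoms, "masked node")
    _check_indices(plan.visible_dual, dual.n_dual_nodes, "visible dual")
    _check_indices(plan.masked_dual, dual.n_dual_nodes, "masked dual")

    # node branch ---------------------------------------------------------
    local = -np.ones(graph.n_atoms, dtype=np.int64)
    local[plan.visible_nodes] = np.arange(plan.visible_nodes.size)
    src, dst, efeat = [], [], []
    for e_idx, (u, v) in enumerate(graph.directed_edges):
        lu, lv = local[u], local[v]
        if lu >= 0 and lv >= 0:
            src.append(lu)
            dst.append(lv)
            efeat.append(graph.bond_features[e_idx])
    node_inputs = VisibleInputs(
        features=graph.atom_features[plan.visible_nodes].copy(),
        positions=plan.visible_nodes.copy(),
        msg_src=np.asarray(src, dtype=np.int64),
        msg_dst=np.asarray(dst, dtype=np.int64),
        msg_edge_feats=(np.asarray(efeat) if efeat
                        else np.zeros((0, graph.bond_features.shape[1]))),
    )

    # edge (dual) branch --------------------------------------------------
    dlocal = -np.ones(max(dual.n_dual_nodes, 1), dtype=np.int64)
    dlocal[plan.visible_dual] = np.arange(plan.visible_dual.size)
    dsrc, ddst = [], []
    for e, preds in enumerate(dual.predecessors):
        le = dlocal[e]
        if le < 0:
            continue
        for p in preds:
            lp = dlocal[p]
            if lp >= 0:
                dsrc.append(lp)
                ddst.append(le)
    dual_inputs = VisibleInputs(
        features=dual.dual_node_features[plan.visible_dual].copy(),
        positions=plan.visible_dual.copy(),
        msg_src=np.asarray(dsrc, dtype=np.int64),
        msg_dst=np.asarray(ddst, dtype=np.int64),
        msg_edge_feats=None,
    )
    return node_inputs, dual_inputs
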