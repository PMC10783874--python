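"""Architecture unit tests: positional encodings, GNN hops, attention,
feature reordering, encoder blindness, equivariance, decoder gradients."""

import numpy as np
import pytest

from batmannet import featurize, sample_mask, sinusoidal_positions
from batmannet.autodiff import Tensor
from batmannet.errors import (ConfigError, EncodeError, ReorderError)
from batmannet.masking import apply_mask
from batmannet.model import (BatmanNet, BranchBatch, ModelConfig,
                             assemble_full_batch, assemble_masked_batch,
                             gnn_hop)

TINY = ModelConfig(hidden=32, n_encoder=2, n_decoder=1, gnn_hops=2,
                   heads=2, ffn_dim=64)


def visible_batch(g, d, plan):
    ni, ei = apply_mask(g, d, plan)
    nb = BranchBatch(features=ni.features, positions=ni.positions,
                     mol_ids=np.zeros(len(ni.positions), dtype=np.int64),
                     msg_src=ni.msg_src, msg_dst=ni.msg_dst,
                     msg_edge_feats=ni.msg_edge_feats)
    eb = BranchBatch(features=ei.features, positions=ei.positions,
                     mol_ids=np.zeros(len(ei.positions), dtype=np.int64),
                     msg_src=ei.msg_src, msg_dst=ei.msg_dst,
                     msg_edge_feats=None)
    return nb, eb


# ----------------------------------------------------------- positions
def test_sinusoidal_row_zero_pattern():
    P = sinusoidal_positions(4, 8)
    np.testing.assert_allclose(P[0, 0::2], 0.0)
    np.testing.assert_allclose(P[0, 1::2], 1.0)


def test_sinusoidal_entry_closed_form():
    P = sinusoidal_positions(2, 8)
    assert P[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)


def test_sinusoidal_range_and_odd_dim():
    P = sinusoidal_positions(512, 32)
    assert np.all(P >= -1.0) and np.all(P <= 1.0)
    with pytest.raises(ConfigError):
        sinusoidal_positions(4, 7)


# ------------------------------------------------------------- gnn hop
def test_gnn_hop_star_sum_aggregation():
    """Star center with 3 neighbors, unit scalar states, identity weights:
    center state is the neighbor count."""
    H = Tensor(np.ones((4, 1)))
    # edges: leaves 1,2,3 -> center 0
    w = {"msg_W": Tensor(np.eye(1)), "msg_b": Tensor(np.zeros(1)),
         "upd_W": Tensor(np.eye(1)), "upd_b": Tensor(np.zeros(1))}
    out = gnn_hop(H, np.array([1, 2, 3]), np.array([0, 0, 0]), 4, w)
    assert out.data[0, 0] == pytest.approx(3.0)


def test_gnn_hop_isolated_element_outputs_activated_bias():
    H = Tensor(np.ones((2, 3)))
    b = np.array([0.5, -0.5, 2.0])
    w = {"msg_W": Tensor(np.eye(3)), "msg_b": Tensor(np.zeros(3)),
         "upd_W": Tensor(np.eye(3)), "upd_b": Tensor(b)}
    out = gnn_hop(H, np.zeros(0, np.int64), np.zeros(0, np.int64), 2, w)
    np.testing.assert_allclose(out.data[0], np.maximum(b, 0.0))


def test_receptive_field_is_exactly_k_hops():
    """On a path graph, perturbing a node more than K hops away leaves a
    node's post-stack state unchanged; within K hops it changes."""
    rng = np.random.default_rng(0)
    n, d, K = 6, 4, 2
    src = np.array([i for i in range(n - 1) for _ in (0,)] +
                   [i + 1 for i in range(n - 1)])
    dst = np.array([i + 1 for i in range(n - 1)] + list(range(n - 1)))
    w = {"msg_W": Tensor(rng.normal(size=(d, d))),
         "msg_b": Tensor(rng.normal(size=d)),
         "upd_W": Tensor(rng.normal(size=(d, d))),
         "upd_b": Tensor(rng.normal(size=d))}

    def run(H0):
        H = Tensor(H0)
        for _ in range(K):
            H = gnn_hop(H, src, dst, n, w)
        return H.data

    H0 = rng.normal(size=(n, d))
    base = run(H0)
    far = H0.copy()
    far[5] += 10.0               # node 5 is 5 hops from node 0
    near = H0.copy()
    near[2] += 10.0              # node 2 is 2 hops from node 0
    assert np.allclose(run(far)[0], base[0])
    assert not np.allclose(run(near)[0], base[0])


# ----------------------------------------------------------- attention
def test_single_element_attention_is_identity_on_values():
    """Softmax over one logit is 1, so attention returns its own value row;
    a one-atom 'molecule' flows through a block without error."""
    model = BatmanNet(TINY, seed=0)
    g, d = featurize("CC")
    plan = sample_mask(2, 2, 0.5, 0)
    nb, _eb = visible_batch(g, d, plan)
    assert nb.n == 1
    out = model.encode("node", nb)
    assert out.data.shape == (1, TINY.hidden)
    assert np.isfinite(out.data).all()


def test_constant_queries_give_uniform_attention_rows():
    """With constant Q and K the softmax weights are exactly 1/n and rows
    sum to 1 — checked against the explicit formula."""
    n, dk = 5, 4
    Q = np.ones((1, n, dk))
    K = np.ones((1, n, dk))
    logits = Q @ K.transpose(0, 2, 1) / np.sqrt(dk)
    from batmannet.autodiff import softmax
    A = softmax(Tensor(logits), axis=-1).data
    np.testing.assert_allclose(A, 1.0 / n)
    np.testing.assert_allclose(A.sum(axis=-1), 1.0)


def test_attention_scale_factor_halves_when_dk_quadruples():
    """1/sqrt(d_k): quadrupling d_k halves the logits scale factor."""
    assert (1 / np.sqrt(16)) == pytest.approx(0.5 * (1 / np.sqrt(4)))


def test_attention_rows_sum_to_one_in_model_blocks():
    model = BatmanNet(TINY, seed=1)
    g, d = featurize("CC(C)c1ccccc1O")
    nb, eb = assemble_full_batch([g], [d])
    # spot-check via direct softmax on the first block's Q/K
    H = model._linear("node.in_proj", Tensor(nb.features))
    Q = model._gnn_stack("node.enc0.q_gnn", H, nb)
    K = model._gnn_stack("node.enc0.k_gnn", H, nb)
    from batmannet import autodiff as ad
    c = model.config
    Qp = model._linear("node.enc0.attn.Wq", Q).reshape(nb.n, c.heads, c.d_head).transpose((1, 0, 2))
    Kp = model._linear("node.enc0.attn.Wk", K).reshape(nb.n, c.heads, c.d_head).transpose((1, 0, 2))
    logits = Qp @ Kp.transpose((0, 2, 1)) * (1 / np.sqrt(c.d_head))
    A = ad.softmax(logits, axis=-1).data
    np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-12)


# ----------------------------------------------------- branch finalize
def test_edge_branch_finalize_obeys_exclusion_rule():
    """On propane, the aggregate for dual node (1,2) uses only h(0,1),
    never the reverse h(2,1)."""
    model = BatmanNet(TINY, seed=0)
    g, d = featurize("CCC")
    _nb, eb = assemble_full_batch([g], [d])
    edge_of = {tuple(e): i for i, e in enumerate(g.directed_edges)}
    rng = np.random.default_rng(3)
    H = rng.normal(size=(eb.n, TINY.hidden))
    out1 = model.branch_finalize("edge", Tensor(H), eb).data
    H2 = H.copy()
    H2[edge_of[(2, 1)]] += 5.0       # reverse edge state must not matter
    out2 = model.branch_finalize("edge", Tensor(H2), eb).data
    np.testing.assert_allclose(out1[edge_of[(1, 2)]], out2[edge_of[(1, 2)]])
    H3 = H.copy()
    H3[edge_of[(0, 1)]] += 5.0       # true predecessor must matter
    out3 = model.branch_finalize("edge", Tensor(H3), eb).data
    assert not np.allclose(out1[edge_of[(1, 2)]], out3[edge_of[(1, 2)]])


def test_finalize_with_no_neighbors_reduces_to_residual_path():
    model = BatmanNet(TINY, seed=0)
    g, d = featurize("CC")
    plan = sample_mask(2, 2, 0.5, 1)
    nb, _ = visible_batch(g, d, plan)          # single visible atom, no links
    H = Tensor(np.random.default_rng(0).normal(size=(1, TINY.hidden)))
    out = model.branch_finalize("node", H, nb).data
    # m_v = 0: output must be independent of H
    out2 = model.branch_finalize("node", Tensor(np.zeros((1, TINY.hidden))), nb).data
    np.testing.assert_allclose(out, out2)


# ---------------------------------------------------------------- encode
def test_encoder_blindness_to_masked_features(fixture_smiles):
    """Randomizing masked elements' raw features leaves encoder outputs
    bit-identical (they are absent from the visible inputs)."""
    model = BatmanNet(TINY, seed=0)
    rng = np.random.default_rng(1)
    for i, smi in enumerate(fixture_smiles[:10]):
        g, d = featurize(smi)
        plan = sample_mask(g.n_atoms, d.n_dual_nodes, 0.6, 300 + i)
        nb, eb = visible_batch(g, d, plan)
        out1 = model.encode("node", nb).data
        g.atom_features[plan.masked_nodes] = rng.normal(
            size=(plan.masked_nodes.size, g.atom_features.shape[1]))
        nb2, _ = visible_batch(g, d, plan)
        out2 = model.encode("node", nb2).data
        np.testing.assert_array_equal(out1, out2)


def test_encode_empty_visible_set_raises():
    model = BatmanNet(TINY, seed=0)
    empty = BranchBatch(features=np.zeros((0, model.atom_schema.total_dim)),
                        positions=np.zeros(0, np.int64),
                        mol_ids=np.zeros(0, np.int64),
                        msg_src=np.zeros(0, np.int64),
                        msg_dst=np.zeros(0, np.int64), msg_edge_feats=None)
    with pytest.raises(EncodeError):
        model.encode("node", empty)


def test_encode_is_deterministic():
    g, d = featurize("CCOC(C)C")
    nb, _ = assemble_full_batch([g], [d])
    out1 = BatmanNet(TINY, seed=5).encode("node", nb).data
    out2 = BatmanNet(TINY, seed=5).encode("node", nb).data
    np.testing.assert_array_equal(out1, out2)


def test_consistent_relabeling_equivariance():
    """Permuting atom order, positional indices and adjacency by the same
    permutation permutes encoder outputs identically."""
    model = BatmanNet(TINY, seed=2)
    g, d = featurize("CC(C)CCO")
    nb, _ = assemble_full_batch([g], [d])
    out = model.encode("node", nb).data
    rng = np.random.default_rng(0)
    perm = rng.permutation(g.n_atoms)           # new index of old atom i
    inv = np.argsort(perm)
    # row j of the permuted batch is old atom inv[j]; features, positions
    # and adjacency all move with the atom
    nb_p = BranchBatch(
        features=nb.features[inv],
        positions=nb.positions[inv],
        mol_ids=nb.mol_ids,
        msg_src=perm[nb.msg_src], msg_dst=perm[nb.msg_dst],
        msg_edge_feats=nb.msg_edge_feats)
    out_p = model.encode("node", nb_p).data
    np.testing.assert_allclose(out_p, out[inv], atol=1e-10)


# --------------------------------------------------------------- reorder
def test_reorder_fills_tokens_and_restores_positions():
    model = BatmanNet(TINY, seed=0)
    d_h = TINY.hidden
    latent = Tensor(np.random.default_rng(0).normal(size=(2, d_h)))
    vis = np.array([2, 0])
    msk = np.array([1])
    full_pos = np.arange(3)
    out = model.reorder_features("node", latent, vis, msk, full_pos).data
    pos = sinusoidal_positions(3, d_h)
    np.testing.assert_allclose(out[2], latent.data[0] + pos[2])
    np.testing.assert_allclose(out[0], latent.data[1] + pos[0])
    token = model.params["node.mask_token"].data
    np.testing.assert_allclose(out[1], token + pos[1])


def test_reorder_round_trip_recovers_visible_rows(small_corpus):
    model = BatmanNet(TINY, seed=0)
    graphs, duals = small_corpus
    g, d = graphs[0], duals[0]
    plan = sample_mask(g.n_atoms, d.n_dual_nodes, 0.6, 9)
    nb, _ = visible_batch(g, d, plan)
    latent = model.encode("node", nb)
    full = model.reorder_features("node", latent, plan.visible_nodes,
                                  plan.masked_nodes, np.arange(g.n_atoms))
    pos = sinusoidal_positions(g.n_atoms, TINY.hidden)
    recovered = full.data[plan.visible_nodes] - pos[plan.visible_nodes]
    np.testing.assert_allclose(recovered, latent.data, atol=1e-12)


def test_reorder_with_no_masked_elements_is_position_sort():
    model = BatmanNet(TINY, seed=0)
    latent = Tensor(np.random.default_rng(1).normal(size=(3, TINY.hidden)))
    vis = np.array([1, 2, 0])
    out = model.reorder_features("node", latent, vis, np.zeros(0, np.int64),
                                 np.arange(3)).data
    pos = sinusoidal_positions(3, TINY.hidden)
    np.testing.assert_allclose(out[vis] - pos[vis], latent.data)


def test_reorder_position_collision_raises():
    model = BatmanNet(TINY, seed=0)
    latent = Tensor(np.zeros((2, TINY.hidden)))
    with pytest.raises(ReorderError):
        model.reorder_features("node", latent, np.array([0, 1]),
                               np.array([1]), np.arange(3))


# ----------------------------------------------------------------- decode
def test_decoder_output_lengths_match_element_counts(small_corpus):
    model = BatmanNet(TINY, seed=0)
    graphs, duals = small_corpus
    gs, ds = graphs[:4], duals[:4]
    plans = [sample_mask(g.n_atoms, d.n_dual_nodes, 0.6, 70 + i)
             for i, (g, d) in enumerate(zip(gs, ds))]
    mb = assemble_masked_batch(gs, ds, plans)
    nl, el = model.forward_pretrain(mb)
    assert nl.data.shape == (sum(g.n_atoms for g in gs),
                             model.atom_schema.total_dim)
    assert el.data.shape == (sum(d.n_dual_nodes for d in ds),
                             model.bond_schema.total_dim)


def test_gradients_reach_mask_token_through_masked_positions():
    """Finite-difference check on a 3-atom molecule: the loss moves when the
    node mask token moves."""
    from batmannet.pretrain import reconstruction_loss
    model = BatmanNet(TINY, seed=0)
    g, d = featurize("CCO")
    plan = sample_mask(g.n_atoms, d.n_dual_nodes, 0.5, 4)
    mb = assemble_masked_batch([g], [d], [plan])

    def loss_value():
        nl, el = model.forward_pretrain(mb)
        rep = reconstruction_loss(nl, el, mb.node_targets, mb.edge_targets,
                                  node_mask_idx=mb.node_mask_idx,
                                  edge_mask_idx=mb.edge_mask_idx)
        return rep

    rep = loss_value()
    for t in model.params.values():
        t.grad = None
    rep.loss.backward()
    token = model.params["node.mask_token"]
    assert token.grad is not None
    k = int(np.argmax(np.abs(token.grad)))
    eps = 1e-5
    token.data[k] += eps
    up = loss_value().L_pretrain
    token.data[k] -= 2 * eps
    dn = loss_value().L_pretrain
    token.data[k] += eps
    fd = (up - dn) / (2 * eps)
    assert fd == pytest.approx(token.grad[k], rel=1e-3, abs=1e-6)


# ------------------------------------------------------- logits / config
def test_reconstruction_logits_width_and_block_softmax():
    from batmannet import autodiff as ad
    model = BatmanNet(TINY, seed=0)
    g, d = featurize("CCN")
    nb, eb = assemble_full_batch([g], [d])
    dec = model.encode("node", nb)
    logits = model.reconstruct_logits("node", dec)
    assert logits.data.shape[1] == model.atom_schema.total_dim
    for _n, s, e in model.atom_schema.block_slices:
        p = ad.softmax(logits.slice_cols(s, e), axis=-1).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
    # all-zero logits -> uniform per-block probabilities
    z = Tensor(np.zeros((2, model.atom_schema.total_dim)))
    for _n, s, e in model.atom_schema.block_slices:
        p = ad.softmax(z.slice_cols(s, e), axis=-1).data
        np.testing.assert_allclose(p, 1.0 / (e - s))


def test_config_validation():
    with pytest.raises(ConfigError):
        ModelConfig(hidden=33, heads=2)                   # not divisible
    with pytest.raises(ConfigError):
        ModelConfig(n_encoder=2, n_decoder=2)             # M < N violated
    with pytest.raises(ConfigError):
        ModelConfig(branches=())
    cfg = ModelConfig()
    assert cfg.n_encoder == 6 and cfg.n_decoder == 2
    assert cfg.gnn_hops == 3 and cfg.heads == 2 and cfg.hidden == 100
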