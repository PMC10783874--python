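"""Scaffold splitting, readout, head averaging, pair prediction, embeddings."""

import numpy as np
import pandas as pd
import pytest

from batmannet import (TaskSpec, extract_embeddings, featurize, readout,
                       scaffold_split)
from batmannet.autodiff import Tensor
from batmannet.downstream import (PredictionModel, _head_average, _init_mlp,
                                  pair_predict, init_pair_head, scaffold_key)
from batmannet.errors import ConfigError, ReadoutError
from batmannet.model import BatmanNet, ModelConfig

TINY = ModelConfig(hidden=32, n_encoder=2, n_decoder=1, gnn_hops=2,
                   heads=2, ffn_dim=64)


# ------------------------------------------------------------ scaffold split
def test_singleton_scaffolds_split_80_10_10(fixture_smiles):
    smiles = []
    seen = set()
    for s in fixture_smiles:
        k = scaffold_key(s)
        if k not in seen:
            seen.add(k)
            smiles.append(s)
        if len(smiles) == 100:
            break
    assert len(smiles) == 100
    split = scaffold_split(smiles, (0.8, 0.1, 0.1))
    sizes = [len(split.indices(w)) for w in ("train", "valid", "test")]
    assert sizes == [80, 10, 10]


def test_benzene_derivatives_share_scaffold_and_set():
    smiles = ["Cc1ccccc1", "CCc1ccccc1"] + [f"{'C' * k}O" for k in range(1, 9)]
    split = scaffold_split(smiles, (0.8, 0.1, 0.1))
    assert split.scaffold_keys[0] == split.scaffold_keys[1]
    assert split.labels[0] == split.labels[1]


def test_all_train_fractions():
    smiles = [f"{'C' * k}O" for k in range(1, 11)]
    split = scaffold_split(smiles, (1.0, 0.0, 0.0))
    assert np.all(split.labels == 0)


def test_unparsable_smiles_go_to_rejects():
    split = scaffold_split(["CCO", "not_a_smiles", "CCC"])
    assert split.rejects == ["not_a_smiles"]
    assert len(split.labels) == 2


def test_scaffold_co_membership_never_violated(fixture_smiles):
    split = scaffold_split(fixture_smiles[:120])
    by_key = {}
    for key, lab in zip(split.scaffold_keys, split.labels):
        by_key.setdefault(key, set()).add(int(lab))
    assert all(len(v) == 1 for v in by_key.values())


# ------------------------------------------------------------------- readout
def test_readout_mean_and_invariances():
    H = np.tile(np.array([1.0, 2.0, 3.0]), (5, 1))
    np.testing.assert_allclose(readout(H), [1.0, 2.0, 3.0])
    single = np.array([[4.0, 5.0]])
    np.testing.assert_allclose(readout(single), [4.0, 5.0])
    rng = np.random.default_rng(0)
    M = rng.normal(size=(7, 3))
    np.testing.assert_allclose(readout(M), readout(M[rng.permutation(7)]))
    with pytest.raises(ReadoutError):
        readout(np.zeros((0, 3)))


# ------------------------------------------------------------ head averaging
def test_prediction_is_mean_of_branch_heads():
    node = Tensor(np.array([[0.8]]))
    edge = Tensor(np.array([[0.6]]))
    out = _head_average(node, edge, np.array([1.0]), True, True)
    assert out.data[0, 0] == pytest.approx(0.7)


def test_identical_heads_average_to_either():
    node = Tensor(np.array([[1.3, -0.2]]))
    out = _head_average(node, node, np.array([1.0]), True, True)
    np.testing.assert_allclose(out.data, node.data)


def test_bond_free_molecule_uses_node_head_alone():
    node = Tensor(np.array([[0.8]]))
    edge = Tensor(np.array([[123.0]]))      # must be ignored
    out = _head_average(node, edge, np.array([0.0]), True, True)
    assert out.data[0, 0] == pytest.approx(0.8)


def test_weight_tied_heads_make_average_equal_either_head():
    model = BatmanNet(TINY, seed=0)
    task = TaskSpec("classification", ("y",))
    rng = np.random.default_rng(0)
    heads = {}
    heads.update(_init_mlp(rng, TINY.hidden, 8, 1, "node_head"))
    for k in list(heads):
        heads[k.replace("node_head", "edge_head")] = Tensor(
            heads[k].data.copy(), requires_grad=True)
    pm = PredictionModel(model=model, heads=heads, task=task, head_hidden=8)
    g, d = featurize("CCO")
    out = pm.forward([g], [d]).data
    from batmannet.downstream import _branch_readouts, _mlp
    node_r, edge_r, _ = _branch_readouts(model, [g], [d])
    node_only = _mlp(heads, "node_head", node_r).data
    # averaged output generally differs from the node head unless readouts
    # coincide; what must hold: average of tied heads applied to the same
    # input equals the head output
    same = _head_average(_mlp(heads, "node_head", node_r),
                         _mlp(heads, "edge_head", node_r),
                         np.array([1.0]), True, True).data
    np.testing.assert_allclose(same, node_only, atol=1e-12)
    assert out.shape == (1, 1)


def test_task_spec_validation():
    with pytest.raises(ConfigError):
        TaskSpec("classification", ("y",), metric="rmse")
    with pytest.raises(ConfigError):
        TaskSpec("ranking", ("y",))
    assert TaskSpec("regression", ("y",)).metric == "rmse"


# ----------------------------------------------------------- pair prediction
def test_pair_prediction_is_symmetric_and_bounded():
    model = BatmanNet(TINY, seed=0)
    head = init_pair_head(TINY.hidden, hidden=16, seed=0)
    ga, da = featurize("CCO")
    gb, db = featurize("c1ccncc1")
    s_ab = pair_predict(ga, da, gb, db, model, head)
    s_ba = pair_predict(gb, db, ga, da, model, head)
    assert s_ab == pytest.approx(s_ba, abs=1e-12)
    assert 0.0 <= s_ab <= 1.0


# -------------------------------------------------------------- embeddings
def test_extract_embeddings_shape_and_determinism(fixture_smiles):
    model = BatmanNet(TINY, seed=0)
    smiles = fixture_smiles[:10] + ["definitely_not_smiles"]
    df1, rej1 = extract_embeddings(smiles, model)
    df2, rej2 = extract_embeddings(smiles, model)
    assert len(df1) == 10
    assert rej1 == ["definitely_not_smiles"]
    assert df1.shape[1] == 1 + 2 * TINY.hidden
    pd.testing.assert_frame_equal(df1, df2)


# ------------------------------------------------------- learning smokes
def test_pair_head_learns_joint_nitrogen_rule(fixture_smiles):
    """Interact iff both molecules contain nitrogen: the symmetric pair head
    on frozen encoder embeddings separates 200 balanced pairs."""
    from rdkit import Chem
    from batmannet.downstream import finetune_pairs

    model = BatmanNet(TINY, seed=0)

    def has_n(s):
        return any(a.GetSymbol() == "N" for a in Chem.MolFromSmiles(s).GetAtoms())

    npool = [s for s in fixture_smiles if has_n(s)][:40]
    opool = [s for s in fixture_smiles if not has_n(s)][:40]
    rng = np.random.default_rng(1)
    pairs, labels = [], []
    for _ in range(100):
        a, b = rng.choice(npool, 2, replace=False)
        pairs.append((a, b))
        labels.append(1.0)
    for _ in range(100):
        pairs.append((rng.choice(opool), rng.choice(fixture_smiles[:80])))
        labels.append(0.0)
    _head, auc = finetune_pairs(model, pairs, labels, seed=0, epochs=120,
                                lr=3e-3)
    assert auc >= 0.9


def test_regression_beats_constant_mean_baseline(fixture_smiles):
    """Fine-tuning on target = n_atoms/10 must beat predicting the train
    mean on the scaffold-split test set."""
    from batmannet.downstream import finetune
    from batmannet.pretrain import prepare_corpus

    graphs, _duals, _ = prepare_corpus(fixture_smiles[:120])
    tbl = pd.DataFrame({"smiles": [g.smiles for g in graphs],
                        "size": [g.n_atoms / 10.0 for g in graphs]})
    task = TaskSpec("regression", ("size",))
    res = finetune(lambda s: BatmanNet(TINY, seed=s), tbl, task,
                   seeds=(0,), epochs=12, lr=3e-3)
    rmse = res.summary["size"][0]
    split = scaffold_split(tbl["smiles"].tolist())
    y = tbl["size"].to_numpy()
    baseline = float(np.sqrt(np.mean(
        (y[split.indices("test")] - y[split.indices("train")].mean()) ** 2)))
    assert rmse < baseline


def test_all_missing_task_is_skipped_others_unaffected():
    from batmannet.downstream import _metric_per_task
    task = TaskSpec("classification", ("a", "b"))
    y = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, np.nan], [0.0, np.nan]])
    scores = np.array([[0.9, 0.1], [0.2, 0.3], [0.8, 0.5], [0.1, 0.6]])
    vals = _metric_per_task(task, y, scores)
    assert np.isnan(vals["b"])
    assert vals["a"] == 1.0
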