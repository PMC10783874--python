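"""Fine-tuning and evaluation on downstream tasks.

The pre-trained encoder becomes a feature extractor: a full-graph (nothing
masked) encoder pass, a mean READOUT over elements, and one two-layer MLP
head per branch whose outputs are averaged (on logits for classification).
Datasets are split by Bemis–Murcko scaffold so that test molecules come from
ring systems never seen in training; acyclic molecules, whose Murcko
scaffold is empty, each count as their own scaffold group.

Also here: the molecule-pair (drug–drug interaction style) head, embedding
extraction, the valid-vs-perturbed linear probe, and the ablation harness
(bi-branch vs single-branch, pre-trained vs scratch, mask-ratio sweep).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mean_squared_error, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from . import autodiff as ad
from .autodiff import Tensor
from .chem import build_dual_graph
from .data import PerturbedMolecule
from .errors import ConfigError, ReadoutError
from .model import BatmanNet, ModelConfig
from .pretrain import Adam, TrainConfig, prepare_corpus, pretrain

log = logging.getLogger("batmannet")

__all__ = ["TaskSpec", "SplitAssignment", "scaffold_split", "readout",
           "FineTuneResult", "finetune", "predict", "pair_predict",
           "finetune_pairs", "extract_embeddings", "embed_graphs",
           "validity_probe", "ablate"]


# ---------------------------------------------------------------------- types
@dataclass(frozen=True)
class TaskSpec:
    task_type: str                       # "classification" | "regression"
    label_columns: tuple
    metric: str = ""

    def __post_init__(self):
        if self.task_type not in ("classification", "regression"):
            raise ConfigError(f"unknown task type {self.task_type!r}")
        want = "roc_auc" if self.task_type == "classification" else "rmse"
        metric = self.metric or want
        if metric != want:
            raise ConfigError(f"metric {metric!r} does not match {self.task_type}")
        object.__setattr__(self, "metric", metric)

    @property
    def n_tasks(self) -> int:
        return len(self.label_columns)


@dataclass
class SplitAssignment:
    """Deterministic scaffold-grouped train/valid/test partition."""

    labels: np.ndarray                   # per accepted molecule: 0/1/2
    scaffold_keys: list
    fractions: tuple
    rejects: list = field(default_factory=list)

    def indices(self, which: str) -> np.ndarray:
        code = {"train": 0, "valid": 1, "test": 2}[which]
        return np.where(self.labels == code)[0]


# ------------------------------------------------------------- scaffold split
def scaffold_key(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; an acyclic molecule (empty scaffold) is
    its own group, keyed by its canonical SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    scaf = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
    return scaf if scaf else "acyclic:" + Chem.MolToSmiles(mol)


def scaffold_split(smiles_list, fractions=(0.8, 0.1, 0.1)) -> SplitAssignment:
    """Greedy scaffold split: groups sorted by size (largest first), filled
    into train, then valid, then test.  Molecules sharing a scaffold always
    share a set.  Unparsable SMILES are excluded and reported."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    keys, rejects, accepted = [], [], []
    for i, smi in enumerate(smiles_list):
        try:
            keys.append(scaffold_key(smi))
            accepted.append(i)
        except ValueError:
            rejects.append(smi)
    n = len(keys)
    groups: dict = {}
    for local, key in enumerate(keys):
        groups.setdefault(key, []).append(local)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    labels = np.full(n, 2, dtype=np.int64)
    c_train = c_valid = 0
    for key, members in ordered:
        if c_train + len(members) <= n_train:
            labels[members] = 0
            c_train += len(members)
        elif c_valid + len(members) <= n_valid:
            labels[members] = 1
            c_valid += len(members)
        # else: stays test
    return SplitAssignment(labels=labels, scaffold_keys=keys,
                           fractions=tuple(fractions), rejects=rejects)


# -------------------------------------------------------------------- readout
def readout(H: np.ndarray) -> np.ndarray:
    """Permutation-invariant mean pooling of element embeddings."""
    H = np.asarray(H)
    if H.size == 0:
        raise ReadoutError("readout of an empty embedding set")
    return H.mean(axis=0)


def _segment_mean(H: Tensor, mol_ids: np.ndarray, n_mols: int) -> Tensor:
    counts = np.bincount(mol_ids, minlength=n_mols).astype(np.float64)
    counts[counts == 0] = 1.0
    return ad.segment_sum(H, mol_ids, n_mols) * (1.0 / counts)[:, None]


def _branch_readouts(model: BatmanNet, graphs, duals):
    """Per-molecule (node_readout, edge_readout, has_edge) as Tensors."""
    B = len(graphs)
    enc = model.encode_graphs(graphs, duals)
    d = model.config.hidden
    outs = {}
    for br in ("node", "edge"):
        if br in enc:
            H, mids = enc[br]
            outs[br] = _segment_mean(H, mids, B)
        else:
            outs[br] = Tensor(np.zeros((B, d)))
    has_edge = np.zeros(B)
    if "edge" in enc:
        has_edge[np.unique(enc["edge"][1])] = 1.0
    if "edge" not in model.config.branches:
        has_edge[:] = 0.0
    return outs["node"], outs["edge"], has_edge


# ------------------------------------------------------------------ MLP heads
def _init_mlp(rng, d_in, hidden, d_out, prefix):
    def glorot(fan_in, fan_out):
        a = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-a, a, size=(fan_in, fan_out))
    return {
        f"{prefix}.W1": Tensor(glorot(d_in, hidden), requires_grad=True),
        f"{prefix}.b1": Tensor(np.zeros(hidden), requires_grad=True),
        f"{prefix}.W2": Tensor(glorot(hidden, d_out), requires_grad=True),
        f"{prefix}.b2": Tensor(np.zeros(d_out), requires_grad=True),
    }


def _mlp(params, prefix, x: Tensor) -> Tensor:
    h = ad.relu(x @ params[f"{prefix}.W1"] + params[f"{prefix}.b1"])
    return h @ params[f"{prefix}.W2"] + params[f"{prefix}.b2"]


def _head_average(node_out: Tensor, edge_out: Tensor, has_edge: np.ndarray,
                  use_node: bool, use_edge: bool) -> Tensor:
    """Arithmetic mean of the two branch heads; a molecule with no bonds (or
    a single-branch model) falls back to the head(s) it has."""
    w_node = np.ones_like(has_edge) if use_node else np.zeros_like(has_edge)
    w_edge = has_edge if use_edge else np.zeros_like(has_edge)
    denom = np.maximum(w_node + w_edge, 1.0)
    return (node_out * w_node[:, None] + edge_out * w_edge[:, None]) \
        * (1.0 / denom)[:, None]


@dataclass
class PredictionModel:
    """Encoder + branch heads; callable on featurized molecules."""

    model: BatmanNet
    heads: dict
    task: TaskSpec
    head_hidden: int = 64

    def forward(self, graphs, duals) -> Tensor:
        node_r, edge_r, has_edge = _branch_readouts(self.model, graphs, duals)
        use_node = "node" in self.model.config.branches
        use_edge = "edge" in self.model.config.branches
        if use_edge and not np.all(has_edge[np.asarray(
                [g.n_directed_edges > 0 for g in graphs])]):
            log.debug("edge head skipped for bond-free molecules in batch")
        node_out = _mlp(self.heads, "node_head", node_r) if use_node \
            else Tensor(np.zeros((len(graphs), self.task.n_tasks)))
        edge_out = _mlp(self.heads, "edge_head", edge_r) if use_edge \
            else Tensor(np.zeros((len(graphs), self.task.n_tasks)))
        return _head_average(node_out, edge_out, has_edge, use_node, use_edge)


def predict(graphs, duals, pm: PredictionModel) -> np.ndarray:
    """Averaged two-branch prediction: pre-sigmoid logits for classification,
    unbounded reals for regression."""
    return pm.forward(graphs, duals).data


# ------------------------------------------------------------------ fine-tune
def _metric_per_task(task: TaskSpec, y_true: np.ndarray, y_score: np.ndarray):
    vals = {}
    for t, col in enumerate(task.label_columns):
        mask = np.isfinite(y_true[:, t])
        if not mask.any():
            vals[col] = np.nan
            continue
        yt, ys = y_true[mask, t], y_score[mask, t]
        if task.task_type == "classification":
            vals[col] = (roc_auc_score(yt, ys)
                         if len(np.unique(yt)) >= 2 else np.nan)
        else:
            vals[col] = float(np.sqrt(mean_squared_error(yt, ys)))
    return vals


def _masked_loss(task: TaskSpec, out: Tensor, y: np.ndarray) -> Tensor:
    mask = np.isfinite(y).astype(np.float64)
    y_filled = np.where(np.isfinite(y), y, 0.0)
    if task.task_type == "classification":
        p = ad.sigmoid(out)
        eps = 1e-9
        per = -(Tensor(y_filled) * ad.log(p + eps) +
                Tensor(1.0 - y_filled) * ad.log(1.0 - p + eps))
    else:
        diff = out - Tensor(y_filled)
        per = diff * diff
    return (per * Tensor(mask)).sum() * (1.0 / max(mask.sum(), 1.0))


@dataclass
class FineTuneResult:
    metrics: pd.DataFrame                # per seed x task test metrics
    summary: dict                        # task -> (mean, sd) over seeds
    model: PredictionModel               # fitted model from the last seed
    history: pd.DataFrame


def finetune(model_factory, table: pd.DataFrame, task: TaskSpec,
             split: SplitAssignment | None = None, seeds=(0, 1, 2),
             epochs: int = 30, batch_size: int = 32, lr: float = 1e-3,
             head_hidden: int = 64, freeze_encoder: bool = False) -> FineTuneResult:
    """End-to-end fine-tuning with validation-based model selection.

    `model_factory(seed)` must return a fresh :class:`BatmanNet` (typically a
    copy of a pre-trained checkpoint).  Missing labels (NaN / empty cells)
    are excluded from both the loss and the metrics.  Test metrics are
    reported per seed and summarised as mean +/- sd.
    """
    graphs, duals, _rej = prepare_corpus(table["smiles"].tolist())
    kept = set(g.smiles for g in graphs)
    table = table[table["smiles"].isin(kept)].reset_index(drop=True)
    y = table[list(task.label_columns)].to_numpy(dtype=np.float64)
    if split is None:
        split = scaffold_split(table["smiles"].tolist())
    idx_tr, idx_va, idx_te = (split.indices(w) for w in ("train", "valid", "test"))

    rows, hist_rows = [], []
    pm_final = None
    for seed in seeds:
        model = model_factory(seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 424243]))
        heads = {}
        heads.update(_init_mlp(rng, model.config.hidden, head_hidden,
                               task.n_tasks, "node_head"))
        heads.update(_init_mlp(rng, model.config.hidden, head_hidden,
                               task.n_tasks, "edge_head"))
        pm = PredictionModel(model=model, heads=heads, task=task,
                             head_hidden=head_hidden)
        trainable = dict(heads)
        if not freeze_encoder:
            trainable.update(model.parameters())
        opt = Adam(trainable, clip_norm=5.0)

        def evaluate(idx):
            if not len(idx):
                return {}, np.zeros((0, task.n_tasks))
            scores = predict([graphs[i] for i in idx], [duals[i] for i in idx], pm)
            return _metric_per_task(task, y[idx], scores), scores

        best_score, best_state = -np.inf, None
        sign = 1.0 if task.task_type == "classification" else -1.0
        for epoch in range(1, epochs + 1):
            order = rng.permutation(idx_tr)
            ep_loss = 0.0
            for s in range(0, len(order), batch_size):
                b = order[s:s + batch_size]
                out = pm.forward([graphs[i] for i in b], [duals[i] for i in b])
                loss = _masked_loss(task, out, y[b])
                opt.zero_grad()
                loss.backward()
                opt.step(lr)
                ep_loss += loss.item() * len(b)
            val_metrics, _ = evaluate(idx_va)
            val = np.nanmean(list(val_metrics.values())) if val_metrics else np.nan
            hist_rows.append({"seed": seed, "epoch": epoch,
                              "train_loss": ep_loss / max(len(order), 1),
                              "val_metric": val})
            if np.isfinite(val) and sign * val > best_score:
                best_score = sign * val
                best_state = ({k: t.data.copy() for k, t in heads.items()},
                              {k: v.copy() for k, v in model.state_arrays().items()})
        if best_state is not None:
            for k, t in heads.items():
                t.data = best_state[0][k]
            model.load_state(best_state[1])
        test_metrics, _ = evaluate(idx_te)
        for col, val in test_metrics.items():
            rows.append({"seed": seed, "task": col, "metric": task.metric,
                         "value": val})
        pm_final = pm

    metrics = pd.DataFrame(rows)
    summary = {}
    for col in task.label_columns:
        vals = metrics.loc[metrics["task"] == col, "value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        summary[col] = ((float(vals.mean()), float(vals.std()))
                        if len(vals) else ("skipped", "skipped"))
    return FineTuneResult(metrics=metrics, summary=summary, model=pm_final,
                          history=pd.DataFrame(hist_rows))


# ----------------------------------------------------------------- embeddings
def embed_graphs(model: BatmanNet, graphs, duals) -> np.ndarray:
    """Per-molecule [node-readout ⊕ edge-readout] matrix (B x 2d); the edge
    half is zero for molecules without bonds."""
    node_r, edge_r, _he = _branch_readouts(model, graphs, duals)
    return np.concatenate([node_r.data, edge_r.data], axis=1)


def extract_embeddings(smiles_list, model: BatmanNet):
    """Full-graph readout embeddings for a list of SMILES.

    Returns ``(DataFrame, rejects)``; the frame has one row per accepted
    molecule with `smiles` plus ``node_*`` and ``edge_*`` columns.
    """
    graphs, duals, rejects = prepare_corpus(smiles_list)
    if not graphs:
        return pd.DataFrame(), rejects
    emb = embed_graphs(model, graphs, duals)
    d = model.config.hidden
    cols = [f"node_{i}" for i in range(d)] + [f"edge_{i}" for i in range(d)]
    df = pd.DataFrame(emb, columns=cols)
    df.insert(0, "smiles", [g.smiles for g in graphs])
    return df, rejects


def embed_perturbed(model: BatmanNet, pert: PerturbedMolecule) -> np.ndarray:
    """Embedding of a structurally perturbed molecule: same topology, shuffled
    atom-feature rows (the dual features are rebuilt from the shuffled rows)."""
    import copy
    g = copy.copy(pert.base)
    g.atom_features = pert.atom_features
    dual = build_dual_graph(g)
    return embed_graphs(model, [g], [dual])[0]


def validity_probe(model: BatmanNet, graphs, duals, perturbed, seed: int = 0,
                   test_fraction: float = 0.3, n_splits: int = 3) -> float:
    """Held-out accuracy of a linear probe separating valid molecules from
    feature-shuffled invalid ones in embedding space.

    The probe is the standard linear-probing protocol: standardised features
    and an (almost) unregularised logistic regression, so it measures the
    linearly decodable information in the embedding rather than its scale.
    Accuracy is averaged over `n_splits` stratified train/test splits.
    """
    X_valid = embed_graphs(model, graphs, duals)
    X_invalid = np.stack([embed_perturbed(model, p) for p in perturbed])
    X = np.concatenate([X_valid, X_invalid])
    yv = np.concatenate([np.ones(len(X_valid)), np.zeros(len(X_invalid))])
    accs = []
    for k in range(n_splits):
        Xtr, Xte, ytr, yte = train_test_split(
            X, yv, test_size=test_fraction, random_state=seed + k, stratify=yv)
        clf = make_pipeline(StandardScaler(),
                            LogisticRegression(max_iter=2000, C=100.0))
        clf.fit(Xtr, ytr)
        accs.append(clf.score(Xte, yte))
    return float(np.mean(accs))


# -------------------------------------------------------------- pair (DDI)
def init_pair_head(d: int, hidden: int = 64, seed: int = 0) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 515151]))
    return _init_mlp(rng, 4 * d, hidden, 1, "pair_head")


def _pair_logit(head, emb_a: np.ndarray, emb_b: np.ndarray) -> Tensor:
    ab = _mlp(head, "pair_head", Tensor(np.concatenate([emb_a, emb_b], axis=-1)))
    ba = _mlp(head, "pair_head", Tensor(np.concatenate([emb_b, emb_a], axis=-1)))
    return (ab + ba) * 0.5


def pair_predict(graph_a, dual_a, graph_b, dual_b, model: BatmanNet,
                 head: dict) -> float:
    """Symmetrised interaction score in [0, 1] for a molecule pair: the pair
    MLP is applied to both orderings of the concatenated readouts and the
    mean logit is squashed by a sigmoid."""
    ea = embed_graphs(model, [graph_a], [dual_a])[0]
    eb = embed_graphs(model, [graph_b], [dual_b])[0]
    z = _pair_logit(head, ea[None, :], eb[None, :])
    return float(1.0 / (1.0 + np.exp(-z.data[0, 0])))


def finetune_pairs(model: BatmanNet, pair_smiles, labels, seed: int = 0,
                   epochs: int = 60, lr: float = 1e-3, hidden: int = 64,
                   test_fraction: float = 0.3):
    """Train the symmetric pair head on frozen encoder embeddings.

    `pair_smiles` is a list of (smiles_a, smiles_b); `labels` binary.
    Returns ``(head, test ROC-AUC)``.
    """
    uniq = sorted({s for ab in pair_smiles for s in ab})
    graphs, duals, _ = prepare_corpus(uniq)
    table = {g.smiles: i for i, g in enumerate(graphs)}
    emb = embed_graphs(model, graphs, duals)
    pairs = np.array([(table[a], table[b]) for a, b in pair_smiles])
    y = np.asarray(labels, dtype=np.float64)
    idx = np.arange(len(pairs))
    tr, te = train_test_split(idx, test_size=test_fraction, random_state=seed,
                              stratify=y)
    head = init_pair_head(model.config.hidden, hidden, seed)
    opt = Adam(head, clip_norm=5.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 616161]))
    for _ in range(epochs):
        order = rng.permutation(tr)
        z = _pair_logit(head, emb[pairs[order, 0]], emb[pairs[order, 1]])
        p = ad.sigmoid(z.reshape(-1))
        eps = 1e-9
        loss = -(Tensor(y[order]) * ad.log(p + eps) +
                 Tensor(1.0 - y[order]) * ad.log(1.0 - p + eps)).mean()
        opt.zero_grad()
        loss.backward()
        opt.step(lr)
    z_te = _pair_logit(head, emb[pairs[te, 0]], emb[pairs[te, 1]]).data.ravel()
    auc = roc_auc_score(y[te], z_te) if len(np.unique(y[te])) >= 2 else np.nan
    return head, float(auc)


# ------------------------------------------------------------------- ablation
def ablate(smiles_list, labels: np.ndarray, model_config: ModelConfig,
           pretrain_steps: int = 150, finetune_epochs: int = 12,
           seed: int = 0, mask_ratio: float = 0.6,
           mask_ratios=None) -> pd.DataFrame:
    """Toy-scale ablation table: bi-branch vs node-only vs edge-only, each
    pre-trained vs from scratch; optionally a mask-ratio sweep for the
    bi-branch model.  Reports test ROC-AUC on a single binary task."""
    table = pd.DataFrame({"smiles": list(smiles_list),
                          "y": np.asarray(labels, dtype=float)})
    task = TaskSpec("classification", ("y",))
    split = scaffold_split(table["smiles"].tolist())
    rows = []

    def run(branches, pretrained, ratio):
        cfg = ModelConfig(**{**model_config.to_dict(), "branches": branches})
        if pretrained:
            base, _hist = pretrain(
                table["smiles"].tolist(), cfg,
                TrainConfig(batch_size=16, total_steps=pretrain_steps,
                            warmup=100, mask_ratio=ratio, seed=seed,
                            eval_every=max(pretrain_steps // 3, 1)))
            state = base.state_arrays()

            def factory(s):
                m = BatmanNet(cfg, base.atom_schema, base.bond_schema, seed=s)
                m.load_state(state)
                return m
        else:
            def factory(s):
                return BatmanNet(cfg, seed=s)
        res = finetune(factory, table, task, split=split, seeds=(seed,),
                       epochs=finetune_epochs)
        val = res.summary["y"][0]
        return val if isinstance(val, float) else np.nan

    for branches in (("node", "edge"), ("node",), ("edge",)):
        for pretrained in (True, False):
            auc = run(branches, pretrained, mask_ratio)
            rows.append({"branches": "+".join(branches),
                         "pretrained": pretrained,
                         "mask_ratio": mask_ratio if pretrained else np.nan,
                         "roc_auc": auc})
    for ratio in (mask_ratios or ()):
        auc = run(("node", "edge"), True, ratio)
        rows.append({"branches": "node+edge", "pretrained": True,
                     "mask_ratio": ratio, "roc_auc": auc})
    return pd.DataFrame(rows)
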