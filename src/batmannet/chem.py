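"""Molecular graphs and their directed duals.

A molecule is represented twice:

* the node graph ``G_N`` — heavy atoms as nodes, bonds as edges, with every
  bond enumerated as the two directed edges ``(u, v)`` and ``(v, u)``;
* the dual (line) graph ``G_E`` — one node per *directed* bond, where the
  predecessors of the directed bond ``(v, w)`` are the directed bonds
  ``(u, v)`` with ``u ∈ N(v) \\ {w}``, so that messages never bounce straight
  back along the reverse edge.

All features are ordered concatenations of categorical one-hot blocks; the
same encoding doubles as the reconstruction target of the masked autoencoder.
Atom order is the parser's emission order and is fixed before any masking —
it is what positional encodings index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import ParseError, SchemaError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FeatureSchema", "MoleculeGraph", "DualGraph",
    "default_atom_schema", "default_bond_schema",
    "parse_molecule", "featurize_atoms", "featurize_bonds",
    "build_dual_graph", "featurize", "degree_block_consistent",
]


# --------------------------------------------------------------------- schema
@dataclass(frozen=True)
class FeatureSchema:
    """Ordered categorical one-hot blocks; block order is fixed and serialized
    with checkpoints so a model can refuse mismatched inputs."""

    role: str                           # "atom" or "bond"
    blocks: tuple                       # of (name, tuple-of-category-labels)

    @property
    def total_dim(self) -> int:
        return sum(len(cats) for _, cats in self.blocks)

    @property
    def block_slices(self):
        """[(name, start, stop)] column ranges of each block."""
        out, off = [], 0
        for name, cats in self.blocks:
            out.append((name, off, off + len(cats)))
            off += len(cats)
        return out

    def block_index(self, name: str, value) -> int:
        """Category index for `value` in block `name`; unknown values map to
        the block's final ("other") slot."""
        for bname, cats in self.blocks:
            if bname == name:
                try:
                    return cats.index(value)
                except ValueError:
                    return len(cats) - 1
        raise SchemaError(f"no block named {name!r} in {self.role} schema")

    def to_json(self) -> str:
        return json.dumps({"role": self.role,
                           "blocks": [[n, list(c)] for n, c in self.blocks]})

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        doc = json.loads(text)
        return cls(role=doc["role"],
                   blocks=tuple((n, tuple(c)) for n, c in doc["blocks"]))


_ELEMENTS = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I", "other")


def default_atom_schema() -> FeatureSchema:
    return FeatureSchema(role="atom", blocks=(
        ("element", _ELEMENTS),
        ("degree", (0, 1, 2, 3, 4, 5, "other")),
        ("formal_charge", (-2, -1, 0, 1, 2, "other")),
        ("chirality", ("none", "cw", "ccw", "other")),
        ("num_h", (0, 1, 2, 3, 4, "other")),
        ("hybridization", ("s", "sp", "sp2", "sp3", "sp3d", "sp3d2", "other")),
        ("aromatic", (False, True)),
        ("in_ring", (False, True)),
    ))


def default_bond_schema() -> FeatureSchema:
    return FeatureSchema(role="bond", blocks=(
        ("bond_type", ("single", "double", "triple", "aromatic", "other")),
        ("conjugated", (False, True)),
        ("in_ring", (False, True)),
        ("stereo", ("none", "z", "e", "cis", "trans", "other")),
    ))


# ---------------------------------------------------------------------- types
@dataclass
class MoleculeGraph:
    """Heavy-atom node graph with a fixed directed-edge enumeration:
    for each bond in parser order, (u, v) then (v, u)."""

    smiles: str
    n_atoms: int
    directed_edges: np.ndarray          # (n_directed_edges, 2) int64, [tail, head]
    neighbor_lists: list                # list of sorted neighbor index lists
    atom_features: np.ndarray | None = None
    bond_features: np.ndarray | None = None
    _mol: object = field(default=None, repr=False, compare=False)

    @property
    def n_directed_edges(self) -> int:
        return int(self.directed_edges.shape[0])

    def degree(self, v: int) -> int:
        return len(self.neighbor_lists[v])


@dataclass
class DualGraph:
    """Directed line graph: one node per directed bond of the source graph."""

    n_dual_nodes: int
    dual_node_features: np.ndarray      # (n_dual, atom_dim + bond_dim)
    predecessors: list                  # per dual node, list of dual-node indices
    source_edge_index: np.ndarray       # (n_dual, 2) copy of directed edges


# ----------------------------------------------------------------- operations
def parse_molecule(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string into its heavy-atom graph.

    Atom indices are the parser's emission order; hydrogens stay implicit.
    Raises :class:`ParseError` on empty or unparsable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((u, v))
        edges.append((v, u))
    directed = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    nbrs = [sorted(a.GetIdx() for a in mol.GetAtomWithIdx(i).GetNeighbors())
            for i in range(n)]
    return MoleculeGraph(smiles=smiles, n_atoms=n, directed_edges=directed,
                         neighbor_lists=nbrs, _mol=mol)


_HYBRID = {
    Chem.HybridizationType.S: "s",
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP3D: "sp3d",
    Chem.HybridizationType.SP3D2: "sp3d2",
}

_CHIRAL = {
    Chem.ChiralType.CHI_UNSPECIFIED: "none",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "cw",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "ccw",
}

_BOND_TYPE = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

_STEREO = {
    Chem.BondStereo.STEREONONE: "none",
    Chem.BondStereo.STEREOZ: "z",
    Chem.BondStereo.STEREOE: "e",
    Chem.BondStereo.STEREOCIS: "cis",
    Chem.BondStereo.STEREOTRANS: "trans",
}


def featurize_atoms(graph: MoleculeGraph, schema: FeatureSchema) -> np.ndarray:
    """One-hot atom feature matrix (n_atoms x schema.total_dim); also stored
    on the graph.  Unknown category values land in each block's "other" slot."""
    if schema.role != "atom":
        raise SchemaError("featurize_atoms requires the atom schema")
    if graph._mol is None:
        raise SchemaError("graph lost its parser handle; re-parse the SMILES")
    X = np.zeros((graph.n_atoms, schema.total_dim), dtype=np.float64)
    for i in range(graph.n_atoms):
        a = graph._mol.GetAtomWithIdx(i)
        vals = {
            "element": a.GetSymbol(),
            "degree": a.GetDegree(),
            "formal_charge": a.GetFormalCharge(),
            "chirality": _CHIRAL.get(a.GetChiralTag(), "other"),
            "num_h": a.GetTotalNumHs(),
            "hybridization": _HYBRID.get(a.GetHybridization(), "other"),
            "aromatic": bool(a.GetIsAromatic()),
            "in_ring": bool(a.IsInRing()),
        }
        for name, start, _stop in schema.block_slices:
            X[i, start + schema.block_index(name, vals[name])] = 1.0
    graph.atom_features = X
    return X


def featurize_bonds(graph: MoleculeGraph, schema: FeatureSchema) -> np.ndarray:
    """One-hot bond feature matrix aligned with the directed-edge list; the
    rows for (u, v) and (v, u) are identical (bond properties are undirected)."""
    if schema.role != "bond":
        raise SchemaError("featurize_bonds requires the bond schema")
    if graph._mol is None:
        raise SchemaError("graph lost its parser handle; re-parse the SMILES")
    E = np.zeros((graph.n_directed_edges, schema.total_dim), dtype=np.float64)
    for b_idx, bond in enumerate(graph._mol.GetBonds()):
        vals = {
            "bond_type": _BOND_TYPE.get(bond.GetBondType(), "other"),
            "conjugated": bool(bond.GetIsConjugated()),
            "in_ring": bool(bond.IsInRing()),
            "stereo": _STEREO.get(bond.GetStereo(), "other"),
        }
        row = np.zeros(schema.total_dim)
        for name, start, _stop in schema.block_slices:
            row[start + schema.block_index(name, vals[name])] = 1.0
        E[2 * b_idx] = row
        E[2 * b_idx + 1] = row
    graph.bond_features = E
    return E


def build_dual_graph(graph: MoleculeGraph) -> DualGraph:
    """Directed line graph of a featurized molecule.

    Dual node ``(u, v)`` carries the features of its starting atom ``u``
    concatenated with the bond features of ``(u, v)``.  The predecessors of
    dual node ``(v, w)`` are the dual nodes ``(u, v)`` with ``u ∈ N(v)\\{w}``.
    """
    if graph.atom_features is None or graph.bond_features is None:
        raise SchemaError("featurize the graph before building its dual")
    n_dual = graph.n_directed_edges
    edges = graph.directed_edges
    # index of directed edge (u, v) for predecessor lookup
    edge_id = {(int(u), int(v)): i for i, (u, v) in enumerate(edges)}
    preds = []
    for v, w in edges:
        v, w = int(v), int(w)
        preds.append([edge_id[(u, v)] for u in graph.neighbor_lists[v] if u != w])
    feats = (np.concatenate([graph.atom_features[edges[:, 0]],
                             graph.bond_features], axis=1)
             if n_dual else
             np.zeros((0, graph.atom_features.shape[1] + graph.bond_features.shape[1])))
    return DualGraph(n_dual_nodes=n_dual, dual_node_features=feats,
                     predecessors=preds, source_edge_index=edges.copy())


def featurize(smiles: str,
              atom_schema: FeatureSchema | None = None,
              bond_schema: FeatureSchema | None = None):
    """Parse + featurize + dual in one call; returns (MoleculeGraph, DualGraph)."""
    atom_schema = atom_schema or default_atom_schema()
    bond_schema = bond_schema or default_bond_schema()
    g = parse_molecule(smiles)
    featurize_atoms(g, atom_schema)
    featurize_bonds(g, bond_schema)
    return g, build_dual_graph(g)


def degree_block_consistent(atom_features: np.ndarray, graph: MoleculeGraph,
                            schema: FeatureSchema | None = None) -> bool:
    """True iff every atom's degree-block category agrees with its adjacency
    degree.  All honestly featurized molecules pass; the structural
    perturbations used to manufacture "invalid" molecules break it."""
    schema = schema or default_atom_schema()
    for name, start, stop in schema.block_slices:
        if name == "degree":
            cats = dict(schema.blocks)["degree"]
            for v in range(graph.n_atoms):
                cat_idx = int(np.argmax(atom_features[v, start:stop]))
                expected = schema.block_index("degree", graph.degree(v))
                if cat_idx != expected:
                    return False
            return True
    raise SchemaError("atom schema has no degree block")
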