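"""Synthetic corpora, structural perturbations, and file I/O.

The fixture generator enumerates simple organic chemotypes (alkanes,
alcohols, amines, ethers, halides, branched chains, benzene and pyridine
derivatives) so that validity is guaranteed by construction — it stands in
for a large pre-training corpus at desk scale.  The perturbation routine
manufactures "invalid" molecules by shuffling atom-feature rows against a
fixed topology, producing graphs whose degree annotations contradict their
adjacency; such graphs have no SMILES serialisation, which is exactly what
makes them structurally invalid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import (MoleculeGraph, default_atom_schema, degree_block_consistent,
                   parse_molecule)
from .errors import FormatError, PerturbError

__all__ = ["FixtureSet", "PerturbedMolecule", "generate_fixtures",
           "perturb_invalid", "read_smiles", "read_property_table",
           "write_smiles"]


@dataclass(frozen=True)
class FixtureSet:
    """Deterministic list of valid SMILES with >= 2 heavy atoms."""

    smiles: tuple
    seed: int
    recipe: str = "organic-templates-v1"

    def __len__(self):
        return len(self.smiles)

    def __iter__(self):
        return iter(self.smiles)


@dataclass
class PerturbedMolecule:
    """A featurized molecule whose atom-feature rows were shuffled against
    its topology; always fails the degree-consistency check."""

    base: MoleculeGraph
    atom_features: np.ndarray
    permutation: np.ndarray
    seed: int
    valid: bool = False


def _template_smiles():
    """Combinatorial enumeration over organic templates; canonical, unique,
    deterministic order."""
    out = []
    chains = ["C" * k for k in range(2, 11)]                      # ethane..decane
    out += chains
    suffixes = ["O", "N", "OC", "F", "Cl", "Br", "I", "C(C)C", "C(=O)O", "C#N"]
    for k in range(1, 9):
        for s in suffixes:
            out.append("C" * k + s)
    for b, k in itertools.product(["C", "CC", "O", "N", "Cl"], range(1, 7)):
        out.append(f"CC({b})" + "C" * k)                          # mid-chain branch
    subs = ["", "C", "CC", "CCC", "O", "N", "OC", "F", "Cl", "Br", "C(C)C"]
    for s in subs:
        out.append(f"{s}c1ccccc1")
        out.append(f"{s}c1ccncc1")
    nonempty = [s for s in subs if s]
    for a, b in itertools.product(nonempty, nonempty):
        out.append(f"{a}c1ccc({b})cc1")                           # para
        out.append(f"{a}c1cccc({b})c1")                           # meta
    # canonicalise + dedupe, keeping first-seen order
    seen, uniq = set(), []
    for smi in out:
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() < 2:
            continue
        can = Chem.MolToSmiles(mol)
        if can not in seen:
            seen.add(can)
            uniq.append(can)
    return uniq


def generate_fixtures(n: int, seed: int = 0) -> FixtureSet:
    """`n` unique, parseable SMILES, shuffled deterministically by `seed`.
    If `n` exceeds the recipe's capacity the list is capped with a warning."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = _template_smiles()
    if n > len(pool):
        warnings.warn(f"fixture recipe capacity is {len(pool)}; capping n={n}")
        n = len(pool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 271828]))
    order = rng.permutation(len(pool))
    return FixtureSet(smiles=tuple(pool[i] for i in order[:n]), seed=seed)


def perturb_invalid(graph: MoleculeGraph, seed: int = 0,
                    max_tries: int = 32) -> PerturbedMolecule:
    """Shuffle atom-feature rows by a non-identity permutation, guaranteeing
    that at least one atom's degree block contradicts its adjacency degree.

    If every sampled permutation happens to preserve consistency (possible
    for highly symmetric molecules such as benzene, where all feature rows
    are equal), the degree block of one atom is cyclically shifted instead —
    still a pure feature corruption against a fixed topology.
    """
    if graph.atom_features is None:
        raise PerturbError("featurize the graph before perturbing it")
    n = graph.n_atoms
    if n < 2:
        raise PerturbError("cannot perturb a single-atom molecule")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 314159]))
    schema = default_atom_schema()
    perm = np.arange(n)
    feats = graph.atom_features.copy()
    for _ in range(max_tries):
        cand = rng.permutation(n)
        if np.array_equal(cand, np.arange(n)):
            continue
        cand_feats = graph.atom_features[cand]
        if not degree_block_consistent(cand_feats, graph, schema):
            perm, feats = cand, cand_feats
            break
    else:
        # symmetric fallback: corrupt one atom's degree block directly
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        feats = graph.atom_features[perm]
        name_slices = {nm: (s, e) for nm, s, e in schema.block_slices}
        s, e = name_slices["degree"]
        v = int(rng.integers(n))
        feats[v, s:e] = np.roll(feats[v, s:e], 1)
    assert not degree_block_consistent(feats, graph, schema)
    return PerturbedMolecule(base=graph, atom_features=feats,
                             permutation=perm, seed=seed)


# ------------------------------------------------------------------- file i/o
def read_smiles(path) -> list:
    """One SMILES per line; blank lines and '#' comments ignored."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def write_smiles(path, smiles_list, header: str | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        for smi in smiles_list:
            fh.write(smi + "\n")


def read_property_table(path) -> pd.DataFrame:
    """Property CSV: header row with a `smiles` column plus one column per
    task; empty cells are missing labels (NaN)."""
    df = pd.read_csv(path)
    if "smiles" not in df.columns:
        raise FormatError(f"{path}: property table must have a 'smiles' column")
    return df
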