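"""Numeric featurization of a reaction into paired reactant/product graphs.

Every atom vector concatenates molecule-level descriptors (element, degree,
charge, aromaticity, hydrogen count, ring membership) with reaction-change
descriptors derived from the atom map (reaction-center flag, number of
reacted atoms in the neighborhood, leaving-group flag and leaving-group
size).  Bond vectors carry order, ring/conjugation flags and a changed-bond
flag.  The reactant fragments are merged into one disconnected graph; the
product is a second graph with the same schema, so the same encoder weights
apply to both sides while the change features still distinguish different
candidate reactant sets for an identical product.

The schema is declared data (ordered ``(name, width)`` entries) rather than
hard-coded widths, and its hash is stored in model checkpoints so a trained
model can refuse features it was not trained on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import MappedMolecule, ReactionRecord
from .errors import UsageError
from .reaction_change import ChangeAnnotation

ELEMENTS = [
    "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B",
    "Si", "Se", "Sn", "Li", "Na", "K", "Mg", "Zn", "Cu", "Fe",
]
BOND_ORDERS = ["single", "double", "triple", "aromatic"]
MAX_DEGREE = 5
MAX_H = 4
MAX_NEIGHBOR_COUNT = 4  # reacted-neighbor one-hot clipped at 4+
MAX_LEAVING_SIZE = 4    # leaving-group size one-hot clipped at 4+

ATOM_SCHEMA: list[tuple[str, int]] = [
    ("element", len(ELEMENTS) + 1),          # + "other" bucket
    ("degree", MAX_DEGREE + 1),
    ("formal_charge", 1),
    ("aromatic", 1),
    ("num_h", MAX_H + 1),
    ("in_ring", 1),
    ("is_center", 1),
    ("reacted_neighbors", MAX_NEIGHBOR_COUNT + 1),
    ("is_leaving", 1),
    ("leaving_size", MAX_LEAVING_SIZE + 1),
]
BOND_SCHEMA: list[tuple[str, int]] = [
    ("order", len(BOND_ORDERS)),
    ("in_ring", 1),
    ("conjugated", 1),
    ("is_changed", 1),
]

ATOM_DIM = sum(w for _n, w in ATOM_SCHEMA)
BOND_DIM = sum(w for _n, w in BOND_SCHEMA)


def schema_json() -> str:
    return json.dumps({"atom": ATOM_SCHEMA, "bond": BOND_SCHEMA})


def schema_hash() -> str:
    """Stable digest of the feature schema, stored inside checkpoints."""
    return hashlib.sha256(schema_json().encode()).hexdigest()[:16]


def _one_hot(value: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[min(value, width - 1)] = 1.0
    return v


def _element_one_hot(symbol: str) -> np.ndarray:
    v = np.zeros(len(ELEMENTS) + 1)
    try:
        v[ELEMENTS.index(symbol)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def atom_feature_vector(
    molecule: MappedMolecule,
    atom_index: int,
    annotation: ChangeAnnotation,
    side: str,
    mol_index: int = 0,
) -> np.ndarray:
    """Feature vector for one atom on one side of the reaction.

    ``side`` is ``"reactant"`` or ``"product"``; ``mol_index`` selects the
    reactant fragment (always 0 on the product side).  Leaving-group slots
    are structurally zero on the product side.
    """
    if side not in ("reactant", "product"):
        raise UsageError(f"side must be 'reactant' or 'product', got {side!r}")
    if not (0 <= atom_index < len(molecule.atoms)):
        raise UsageError(f"atom index {atom_index} out of range")
    symbol, charge, num_h, aromatic, map_num = molecule.atoms[atom_index]
    rd_atom = molecule.rdmol.GetAtomWithIdx(atom_index)

    is_center = float(map_num > 0 and map_num in annotation.center_atoms)
    n_reacted = annotation.neighborhood_counts[side][mol_index][atom_index]
    if side == "reactant":
        key = (mol_index, atom_index)
        is_leaving = float(key in annotation.leaving_atoms)
        leaving_size = annotation.leaving_component_sizes.get(key, 0)
    else:
        is_leaving = 0.0
        leaving_size = 0

    parts = [
        _element_one_hot(symbol),
        _one_hot(rd_atom.GetDegree(), MAX_DEGREE + 1),
        np.array([float(charge)]),
        np.array([float(aromatic)]),
        _one_hot(num_h, MAX_H + 1),
        np.array([float(rd_atom.IsInRing())]),
        np.array([is_center]),
        _one_hot(n_reacted, MAX_NEIGHBOR_COUNT + 1),
        np.array([is_leaving]),
        _one_hot(leaving_size, MAX_LEAVING_SIZE + 1),
    ]
    return np.concatenate(parts)


def bond_feature_vector(
    molecule: MappedMolecule,
    bond_index: int,
    annotation: ChangeAnnotation,
) -> np.ndarray:
    """Feature vector for one bond, including the changed-bond flag."""
    if not (0 <= bond_index < len(molecule.bonds)):
        raise UsageError(f"bond index {bond_index} out of range")
    a, b, order = molecule.bonds[bond_index]
    rd_bond = molecule.rdmol.GetBondBetweenAtoms(a, b)
    ma = molecule.atoms[a][4]
    mb = molecule.atoms[b][4]
    changed = False
    if ma > 0 and mb > 0:
        key = (min(ma, mb), max(ma, mb))
        changed = (
            key in annotation.broken_bonds
            or key in annotation.formed_bonds
            or key in annotation.order_changed_bonds
        )
    parts = [
        _one_hot(BOND_ORDERS.index(order), len(BOND_ORDERS)),
        np.array([float(rd_bond.IsInRing())]),
        np.array([float(rd_bond.GetIsConjugated())]),
        np.array([float(changed)]),
    ]
    return np.concatenate(parts)


@dataclass
class GraphData:
    """One side of a featurized reaction: a (possibly disconnected) graph."""

    node_features: np.ndarray  # (n_atoms, ATOM_DIM)
    edge_features: np.ndarray  # (n_bonds, BOND_DIM)
    edges: np.ndarray          # (n_bonds, 2) undirected atom-index pairs

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]


@dataclass
class FeaturizedReactionGraph:
    """Paired reactant/product graphs sharing one feature schema."""

    reactant_graph: GraphData
    product_graph: GraphData
    feature_schema: list[tuple[str, int]] = field(default_factory=lambda: list(ATOM_SCHEMA))
    schema_hash: str = field(default_factory=schema_hash)


def _featurize_side(
    molecules: list[MappedMolecule], annotation: ChangeAnnotation, side: str
) -> GraphData:
    node_rows, edge_rows, edge_pairs = [], [], []
    offset = 0
    for mi, mol in enumerate(molecules):
        for i in range(len(mol.atoms)):
            node_rows.append(atom_feature_vector(mol, i, annotation, side, mol_index=mi))
        for bi, (a, b, _order) in enumerate(mol.bonds):
            edge_rows.append(bond_feature_vector(mol, bi, annotation))
            edge_pairs.append((a + offset, b + offset))
        offset += len(mol.atoms)
    nodes = np.array(node_rows) if node_rows else np.zeros((0, ATOM_DIM))
    edges_f = np.array(edge_rows) if edge_rows else np.zeros((0, BOND_DIM))
    pairs = np.array(edge_pairs, dtype=np.int64) if edge_pairs else np.zeros((0, 2), dtype=np.int64)
    return GraphData(node_features=nodes, edge_features=edges_f, edges=pairs)


def build_reaction_graphs(
    record: ReactionRecord, annotation: ChangeAnnotation
) -> FeaturizedReactionGraph:
    """Merge the reactant fragments and featurize both sides of a reaction."""
    reactant_graph = _featurize_side(record.reactants, annotation, "reactant")
    product_graph = _featurize_side([record.product], annotation, "product")
    return FeaturizedReactionGraph(
        reactant_graph=reactant_graph, product_graph=product_graph
    )
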