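"""Shared fixtures: reference reactions, independent oracles, helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest
from rdkit import Chem

from retroranker import (
    MappedMolecule,
    ReactionRecord,
    SynthConfig,
    generate_dataset,
    parse_mapped_reaction,
)

# Reference mapped reactions used across modules.
IDENTITY = "[CH3:1][OH:2]>>[CH3:1][OH:2]"
ESTERIFICATION = "[CH3:1][OH:2].[CH3:3][C:4](=[O:5])[OH:6]>>[CH3:1][O:2][C:4](=[O:5])[CH3:3]"
AMINATION = "[CH2:1]([CH3:4])[Br:2].[NH2:3][CH3:5]>>[CH2:1]([CH3:4])[NH:3][CH3:5]"
KETO_ENOL = "[CH3:1][C:2](=[O:3])[CH3:4]>>[CH2:1]=[C:2]([OH:3])[CH3:4]"

FIXTURE_REACTIONS = {
    "identity": IDENTITY,
    "esterification": ESTERIFICATION,
    "amination": AMINATION,
    "keto_enol": KETO_ENOL,
}


@pytest.fixture(scope="session")
def fixture_records() -> dict[str, ReactionRecord]:
    return {name: parse_mapped_reaction(s) for name, s in FIXTURE_REACTIONS.items()}


def bond_diff_oracle(rxn_smiles: str) -> dict[str, set]:
    """Independent change oracle: map-keyed bond dictionaries, diffed.

    Parses the two sides directly with RDKit and compares bonds between
    mapped atoms, without going through the package's record types.
    """
    left, _, right = rxn_smiles.partition(">>")

    def side_bonds(smiles: str) -> dict[frozenset, str]:
        mol = Chem.MolFromSmiles(smiles)
        out = {}
        for bond in mol.GetBonds():
            ma = bond.GetBeginAtom().GetAtomMapNum()
            mb = bond.GetEndAtom().GetAtomMapNum()
            if ma and mb:
                out[frozenset((ma, mb))] = str(bond.GetBondType())
        return out

    rb = side_bonds(left)
    pb = side_bonds(right)
    broken = {tuple(sorted(k)) for k in rb if k not in pb}
    formed = {tuple(sorted(k)) for k in pb if k not in rb}
    order_changed = {
        tuple(sorted(k)) for k in rb if k in pb and rb[k] != pb[k]
    }
    center = set()
    for pair in broken | formed | order_changed:
        center.update(pair)
    return {
        "broken": broken,
        "formed": formed,
        "order_changed": order_changed,
        "center": center,
    }


def relabel_maps(record: ReactionRecord, permutation: dict[int, int]) -> ReactionRecord:
    """Apply a map-number permutation to every molecule of a record."""

    def relabel(mol: MappedMolecule) -> MappedMolecule:
        copy = Chem.Mol(mol.rdmol)
        for atom in copy.GetAtoms():
            m = atom.GetAtomMapNum()
            if m:
                atom.SetAtomMapNum(permutation[m])
        return MappedMolecule.from_rdkit(copy)

    out = ReactionRecord(
        product=relabel(record.product),
        reactants=[relabel(r) for r in record.reactants],
        original_rank=record.original_rank,
        is_recorded=record.is_recorded,
    )
    out.validate()
    return out


def permute_atoms(mol: MappedMolecule, rng: np.random.Generator) -> MappedMolecule:
    """Renumber the atoms of a molecule (graph unchanged, order shuffled)."""
    order = [int(i) for i in rng.permutation(mol.rdmol.GetNumAtoms())]
    return MappedMolecule.from_rdkit(Chem.RenumberAtoms(mol.rdmol, order))


@pytest.fixture(scope="session")
def small_dataset():
    """A shared 60-product dataset with the default decoy mix."""
    return generate_dataset(SynthConfig(n_products=60, seed=7))


@pytest.fixture(scope="session")
def separable_config() -> SynthConfig:
    """Study conditions where recorded candidates are separable by change
    features (no wrong-site decoys, which are feature-identical)."""
    return SynthConfig(
        n_products=100,
        decoy_weights={"wrong_site": 0.0, "spurious": 0.4, "noop": 0.2, "overlarge": 0.4},
        seed=21,
    )
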