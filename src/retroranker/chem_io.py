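"""Parsing and serialization of atom-mapped reactions and prediction files.

A retrosynthesis prediction is a product molecule plus an ordered list of
candidate reactant sets.  Candidates arrive as reaction SMILES
(``reactants>>product``) whose atom maps (``[CH3:1]``) link every product
atom to its originating reactant atom; reactant atoms without a counterpart
in the product are leaving-group atoms.  This module turns those strings
into light graph records, decides which candidate is the recorded
(ground-truth) one by canonical-SMILES identity, and reads/writes the
JSON-Lines prediction format used throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

from .errors import FormatError, MappingError, ParseError

RDLogger.DisableLog("rdApp.*")

BOND_ORDER_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass
class MappedMolecule:
    """A molecular graph whose atoms optionally carry atom-map numbers.

    Heavy atoms only; hydrogens are implicit.  ``atoms`` holds tuples of
    ``(element, formal_charge, total_h, is_aromatic, map_number)`` with
    ``map_number == 0`` meaning unmapped.  ``bonds`` holds
    ``(atom_i, atom_j, order)`` with ``order`` one of single / double /
    triple / aromatic.
    """

    atoms: list[tuple[str, int, int, bool, int]]
    bonds: list[tuple[int, int, str]]
    source_smiles: str
    # RDKit mol with atom order matching `atoms`; kept for featurization.
    rdmol: Chem.Mol = field(repr=False, compare=False, default=None)

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, source_smiles: str | None = None) -> "MappedMolecule":
        atoms = [
            (
                a.GetSymbol(),
                a.GetFormalCharge(),
                a.GetTotalNumHs(),
                a.GetIsAromatic(),
                a.GetAtomMapNum(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), BOND_ORDER_NAMES[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        smi = source_smiles if source_smiles is not None else Chem.MolToSmiles(mol)
        out = cls(atoms=atoms, bonds=bonds, source_smiles=smi, rdmol=mol)
        out.validate()
        return out

    @classmethod
    def from_smiles(cls, smiles: str) -> "MappedMolecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {smiles!r}")
        return cls.from_rdkit(mol, source_smiles=smiles)

    def validate(self) -> None:
        n = len(self.atoms)
        seen_pairs: set[tuple[int, int]] = set()
        for a, b, _order in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ParseError(f"invalid bond ({a}, {b}) in {self.source_smiles!r}")
            key = (min(a, b), max(a, b))
            if key in seen_pairs:
                raise ParseError(f"duplicate bond ({a}, {b}) in {self.source_smiles!r}")
            seen_pairs.add(key)
        maps = [m for *_rest, m in self.atoms if m > 0]
        if len(maps) != len(set(maps)):
            raise MappingError(f"duplicate atom-map numbers in {self.source_smiles!r}")

    @property
    def map_numbers(self) -> set[int]:
        """Nonzero atom-map numbers present in this molecule."""
        return {m for *_rest, m in self.atoms if m > 0}

    @property
    def num_heavy_atoms(self) -> int:
        return len(self.atoms)

    def to_smiles(self) -> str:
        """Canonical SMILES preserving atom maps."""
        return Chem.MolToSmiles(self.rdmol)


@dataclass
class ReactionRecord:
    """One candidate: a product plus one predicted reactant set.

    ``unscorable`` marks candidates whose reactant SMILES failed to parse or
    map; they stay in the list (so re-ranking remains a permutation of the
    original candidates) and always receive the minimum re-ranking score.
    For those, ``reactants`` is empty and ``raw_reactants`` keeps the text.
    """

    product: MappedMolecule
    reactants: list[MappedMolecule]
    original_rank: int = 1
    upstream_score: float | None = None
    is_recorded: bool | None = None
    unscorable: bool = False
    raw_reactants: str | None = None

    def validate(self) -> None:
        if self.unscorable:
            return
        if not self.reactants:
            raise MappingError("a scorable record needs at least one reactant")
        prod_maps = self.product.map_numbers
        if not prod_maps:
            raise MappingError(
                f"product has no mapped atoms: {self.product.source_smiles!r}"
            )
        counts: dict[int, int] = {}
        for r in self.reactants:
            for m in r.map_numbers:
                counts[m] = counts.get(m, 0) + 1
        for m in sorted(prod_maps):
            if counts.get(m, 0) != 1:
                raise MappingError(
                    f"product map {m} appears {counts.get(m, 0)} times in reactants"
                )

    def reaction_smiles(self) -> str:
        left = ".".join(r.to_smiles() for r in self.reactants)
        return f"{left}>>{self.product.to_smiles()}"


@dataclass
class PredictionList:
    """The ordered candidate list for one product, ranks 1..n contiguous."""

    product_smiles: str
    candidates: list[ReactionRecord]

    def validate(self) -> None:
        ranks = [c.original_rank for c in self.candidates]
        if ranks != list(range(1, len(ranks) + 1)):
            raise FormatError(
                f"ranks must be 1..n with no gaps, got {ranks} for {self.product_smiles!r}"
            )
        n_recorded = sum(1 for c in self.candidates if c.is_recorded)
        if n_recorded > 1:
            raise FormatError(
                f"more than one recorded candidate for {self.product_smiles!r}"
            )

    @property
    def recorded_rank(self) -> int | None:
        """Original rank of the recorded candidate, or None if absent."""
        for c in self.candidates:
            if c.is_recorded:
                return c.original_rank
        return None


def _split_reaction(rxn_smiles: str) -> tuple[str, str]:
    parts = rxn_smiles.strip().split(">")
    if len(parts) == 3:  # reactants > reagents > product; reagents dropped
        return parts[0], parts[2]
    if len(parts) == 2:
        raise ParseError(f"malformed reaction separator in {rxn_smiles!r}")
    raise ParseError(f"expected 'reactants>>product', got {rxn_smiles!r}")


def _parse_side(smiles: str) -> list[MappedMolecule]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    return [MappedMolecule.from_rdkit(f) for f in frags]


def parse_mapped_reaction(rxn_smiles: str) -> ReactionRecord:
    """Parse an atom-mapped reaction SMILES into a :class:`ReactionRecord`.

    The product must be fully linked to the reactants: every nonzero product
    map number must occur in exactly one reactant, and the product must have
    at least one mapped atom (raises :class:`MappingError` otherwise).
    Reagents in a three-part ``a>b>c`` string are discarded.
    """
    left, right = _split_reaction(rxn_smiles)
    reactants = _parse_side(left)
    products = _parse_side(right)
    if len(products) != 1:
        raise ParseError(
            f"expected a single product molecule, got {len(products)} in {rxn_smiles!r}"
        )
    record = ReactionRecord(product=products[0], reactants=reactants)
    record.validate()
    return record


def canonical_candidate_key(reactants: Sequence[MappedMolecule] | Sequence[str]) -> str:
    """Order- and map-invariant identity key for a reactant set.

    Atom maps are stripped, each fragment is canonicalized by RDKit, and the
    fragments are sorted and dot-joined, so equal multisets of molecules give
    equal keys regardless of input order or numbering.
    """
    frags: list[str] = []
    for r in reactants:
        smi = r if isinstance(r, str) else r.source_smiles
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"unparseable SMILES: {smi!r}")
        for sub in Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True):
            for atom in sub.GetAtoms():
                atom.SetAtomMapNum(0)
            frags.append(Chem.MolToSmiles(sub))
    return ".".join(sorted(frags))


def _candidate_from_json(obj: dict, product_smiles: str, recorded_key: str | None) -> ReactionRecord:
    rank = int(obj["rank"])
    score = obj.get("score")
    score = None if score is None else float(score)
    reactant_smiles = obj["reactants"]
    rxn = f"{reactant_smiles}>>{product_smiles}"
    try:
        record = parse_mapped_reaction(rxn)
    except (ParseError, MappingError):
        # Kept with a sentinel so re-ranking stays a permutation of the
        # original list; scored at the documented minimum downstream.
        product = MappedMolecule.from_smiles(product_smiles)
        return ReactionRecord(
            product=product,
            reactants=[],
            original_rank=rank,
            upstream_score=score,
            is_recorded=False,
            unscorable=True,
            raw_reactants=reactant_smiles,
        )
    record.original_rank = rank
    record.upstream_score = score
    if recorded_key is None:
        record.is_recorded = None
    else:
        record.is_recorded = canonical_candidate_key(record.reactants) == recorded_key
    return record


def read_predictions(path: str | Path) -> list[PredictionList]:
    """Read a JSON-Lines prediction file.

    One product per line:
    ``{"product": smiles, "recorded": smiles-or-null,
    "candidates": [{"rank": int, "reactants": smiles, "score": float-or-null}, ...]}``.
    ``is_recorded`` is assigned by canonical-key match against ``recorded``.
    """
    lists: list[PredictionList] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"line {line_no}: invalid JSON ({exc})") from exc
            product_smiles = obj["product"]
            recorded = obj.get("recorded")
            recorded_key = None if recorded is None else canonical_candidate_key([recorded])
            cands = [
                _candidate_from_json(c, product_smiles, recorded_key)
                for c in obj["candidates"]
            ]
            cands.sort(key=lambda c: c.original_rank)
            plist = PredictionList(product_smiles=product_smiles, candidates=cands)
            try:
                plist.validate()
            except FormatError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
            lists.append(plist)
    return lists


def write_predictions(lists: Iterable[PredictionList], path: str | Path) -> None:
    """Write prediction lists in the JSON-Lines dialect of :func:`read_predictions`."""
    with open(path, "w") as fh:
        for plist in lists:
            recorded = None
            for c in plist.candidates:
                if c.is_recorded and not c.unscorable:
                    recorded = ".".join(r.to_smiles() for r in c.reactants)
            cands = []
            for c in plist.candidates:
                if c.unscorable:
                    reactants = c.raw_reactants
                else:
                    reactants = ".".join(r.to_smiles() for r in c.reactants)
                cands.append(
                    {"rank": c.original_rank, "reactants": reactants, "score": c.upstream_score}
                )
            fh.write(
                json.dumps(
                    {"product": plist.product_smiles, "recorded": recorded, "candidates": cands}
                )
                + "\n"
            )


def read_reaction_lines(path: str | Path) -> list[ReactionRecord]:
    """Read a plain-text fixture file, one mapped reaction SMILES per line.

    Blank lines and ``#`` comments are skipped.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                records.append(parse_mapped_reaction(line))
    return records
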