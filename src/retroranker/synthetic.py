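"""Seeded generator of toy retrosynthesis prediction lists.

Each product is assembled from two random carbon substituents joined
through one of four disconnection templates (ester hydrolysis, amide
cleavage, N-alkylation cleavage, C-C disconnection).  The recorded
reactant set is obtained by undoing the template with atom maps assigned
at rewrite time, so the maps are correct by construction and no external
atom-mapping model is needed.  Decoys are chemical perturbations of the
product or of the recorded reactants:

* ``wrong_site`` — a different bond of the product is disconnected
  (selectivity failure; chemically as plausible-looking as the recorded
  disconnection),
* ``spurious`` — the recorded reactants with an extra unmapped substituent
  that would have to leave for no reason,
* ``noop`` — the product offered as its own reactant (zero changed bonds),
* ``overlarge`` — the recorded disconnection but with an implausibly large
  leaving group.

Original ranks emulate the frequency bias of data-driven single-step
models: every candidate gets an upstream score ``f ** beta * exp(sigma*g)``
where ``f`` is the frequency of the reaction pattern the candidate mimics
(decoys mimic patterns drawn proportionally to frequency, i.e. they look
like frequent chemistry) and ``g`` is standard normal noise.  With high
``beta`` the recorded reactants of rare templates land at low ranks —
exactly the failure mode re-ranking is meant to fix.  ``beta = 0`` removes
the bias entirely: ranks become uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import MappedMolecule, PredictionList, ReactionRecord, canonical_candidate_key
from .errors import GenerationError, SkipSignal, UsageError

# Substituents are written so that plain string concatenation
# prefix + core + suffix is a valid SMILES; the core's atom indices in the
# parsed product are then known from the prefix's heavy-atom count.
R_GROUPS = ["C", "CC", "CCC", "C(C)C", "CCCC", "CC(C)C", "Cc1ccccc1", "CCc1ccccc1"]
#: substituent that itself contains an ester, enabling wrong-site decoys
#: that cleave "the other" ester of a diester product
R_GROUPS_ESTER = ["CCOC(=O)CC", "COC(=O)CC"]


@dataclass(frozen=True)
class _Template:
    name: str
    core: str            # SMILES fragment spliced between the substituents
    bond_offset: tuple[int, int]  # disconnection bond, relative to core start
    leaving_a: str | None  # leaving group attached to the first bond atom
    leaving_b: str | None  # ... and to the second
    overlarge_a: str | None  # over-large variant of leaving_a
    smarts: str          # pattern locating this motif for wrong-site decoys
    smarts_bond: tuple[int, int]  # disconnection bond within the match


TEMPLATES: dict[str, _Template] = {
    "ester": _Template(
        "ester", "C(=O)O", (0, 2), "O", None, "OCc1ccccc1",
        "[CX3;!$(C-N)](=O)[OX2][#6]", (0, 2),
    ),
    "amide": _Template(
        "amide", "C(=O)N", (0, 2), "O", None, "OCc1ccccc1",
        "[CX3](=O)[NX3][#6]", (0, 2),
    ),
    "n_alkylation": _Template(
        "n_alkylation", "CN", (0, 1), "Br", None, "OS(=O)(=O)c1ccccc1",
        "[CX4;!$(C-C=O)][NX3]", (0, 1),
    ),
    "cc_coupling": _Template(
        "cc_coupling", "CC", (0, 1), "Br", "Br", "OS(=O)(=O)c1ccccc1",
        "[CX4;!R]-[CX4;!R]", (0, 1),
    ),
}

DECOY_OPERATORS = ("wrong_site", "spurious", "noop", "overlarge")


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_products: int = 100
    n_candidates: int = 10
    template_weights: dict[str, float] = field(
        default_factory=lambda: {
            "ester": 0.45, "amide": 0.30, "n_alkylation": 0.15, "cc_coupling": 0.10
        }
    )
    decoy_weights: dict[str, float] = field(
        default_factory=lambda: {
            "wrong_site": 0.25, "spurious": 0.30, "noop": 0.15, "overlarge": 0.30
        }
    )
    bias_beta: float = 1.5
    noise_sigma: float = 1.0
    #: probability that a substituent carries its own ester motif, giving
    #: products with a second disconnectable site
    ester_substituent_prob: float = 0.15
    seed: int = 0
    max_retries: int = 20

    def validate(self) -> None:
        if self.n_products < 1 or self.n_candidates < 2:
            raise UsageError("need n_products >= 1 and n_candidates >= 2")
        if not self.template_weights or min(self.template_weights.values()) < 0:
            raise UsageError("template weights must be nonnegative, at least one template")
        if sum(self.template_weights.values()) <= 0:
            raise UsageError("template weights must not all be zero")
        unknown = set(self.template_weights) - set(TEMPLATES)
        if unknown:
            raise UsageError(f"unknown templates: {sorted(unknown)}")
        unknown = set(self.decoy_weights) - set(DECOY_OPERATORS)
        if unknown:
            raise UsageError(f"unknown decoy operators: {sorted(unknown)}")
        if sum(self.decoy_weights.values()) <= 0:
            raise UsageError("decoy weights must not all be zero")
        if self.bias_beta < 0 or self.noise_sigma < 0:
            raise UsageError("bias strength and noise scale must be nonnegative")


# ---------------------------------------------------------------------------
# molecule construction helpers


def _mapped_product(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - templates always produce valid SMILES
        raise GenerationError(f"template produced invalid SMILES {smiles!r}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    return mol


def _attach_leaving(rw: Chem.RWMol, join_idx: int, leaving_smiles: str) -> None:
    """Graft an unmapped leaving fragment onto `join_idx` via its first atom."""
    frag = Chem.MolFromSmiles(leaving_smiles)
    offset = rw.GetNumAtoms()
    for atom in frag.GetAtoms():
        a = Chem.Atom(atom.GetSymbol())
        a.SetFormalCharge(atom.GetFormalCharge())
        a.SetIsAromatic(atom.GetIsAromatic())
        rw.AddAtom(a)
    for bond in frag.GetBonds():
        rw.AddBond(
            bond.GetBeginAtomIdx() + offset,
            bond.GetEndAtomIdx() + offset,
            bond.GetBondType(),
        )
    rw.AddBond(join_idx, offset, Chem.BondType.SINGLE)


def _disconnect(
    product_mol: Chem.Mol,
    bond: tuple[int, int],
    leaving_a: str | None,
    leaving_b: str | None,
) -> list[MappedMolecule]:
    """Break one product bond and graft leaving groups; return the reactants."""
    rw = Chem.RWMol(product_mol)
    a, b = bond
    rw.RemoveBond(a, b)
    if leaving_a:
        _attach_leaving(rw, a, leaving_a)
    if leaving_b:
        _attach_leaving(rw, b, leaving_b)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    return [MappedMolecule.from_rdkit(f) for f in frags]


def _count_unmapped(reactants: list[MappedMolecule]) -> int:
    return sum(
        1 for mol in reactants for *_rest, m in mol.atoms if m == 0
    )


# ---------------------------------------------------------------------------
# recorded candidate


def _build_product(template: _Template, rng: np.random.Generator, config: SynthConfig):
    """Random product for a template; returns (mol, recorded disconnection bond)."""
    pool_a = list(R_GROUPS)
    if rng.random() < config.ester_substituent_prob:
        pool_a += R_GROUPS_ESTER
    r1 = str(rng.choice(pool_a))
    r2 = str(rng.choice(R_GROUPS))
    n_prefix = Chem.MolFromSmiles(r1).GetNumAtoms()
    smiles = r1 + template.core + r2
    mol = _mapped_product(smiles)
    off_a, off_b = template.bond_offset
    return mol, (n_prefix + off_a, n_prefix + off_b)


def _recorded_record(
    template: _Template, product_mol: Chem.Mol, bond: tuple[int, int]
) -> ReactionRecord:
    reactants = _disconnect(product_mol, bond, template.leaving_a, template.leaving_b)
    record = ReactionRecord(
        product=MappedMolecule.from_rdkit(Chem.Mol(product_mol)),
        reactants=reactants,
        is_recorded=True,
    )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# perturbation operators


def _wrong_site(
    record: ReactionRecord, recorded_bond: tuple[int, int], rng: np.random.Generator
) -> tuple[ReactionRecord, int]:
    """Disconnect a different product bond using any template motif."""
    product_mol = record.product.rdmol
    options: list[tuple[_Template, tuple[int, int]]] = []
    for template in TEMPLATES.values():
        pattern = Chem.MolFromSmarts(template.smarts)
        for match in product_mol.GetSubstructMatches(pattern):
            a = match[template.smarts_bond[0]]
            b = match[template.smarts_bond[1]]
            pair = (min(a, b), max(a, b))
            if pair != tuple(sorted(recorded_bond)):
                options.append((template, (a, b)))
    if not options:
        raise SkipSignal("no alternative disconnectable site")
    template, bond = options[int(rng.integers(len(options)))]
    reactants = _disconnect(
        Chem.Mol(product_mol), bond, template.leaving_a, template.leaving_b
    )
    decoy = ReactionRecord(
        product=MappedMolecule.from_rdkit(Chem.Mol(product_mol)),
        reactants=reactants,
        is_recorded=False,
    )
    decoy.validate()
    return decoy, 1


def perturb_wrong_site(record: ReactionRecord, seed: int) -> ReactionRecord:
    """Public wrong-site operator: cleave a different site of the product.

    The recorded disconnection is inferred from the record's formed bonds,
    so this also applies to externally supplied records.  Raises
    :class:`SkipSignal` when the product has no alternative site.
    """
    from .reaction_change import annotate_changes

    annotation = annotate_changes(record)
    # map the formed bond back to product atom indices
    map_to_idx = {m: i for i, (*_r, m) in enumerate(record.product.atoms) if m > 0}
    if annotation.formed_bonds:
        ma, mb = next(iter(sorted(annotation.formed_bonds)))
        recorded_bond = (map_to_idx[ma], map_to_idx[mb])
    else:
        recorded_bond = (-1, -1)
    rng = np.random.default_rng(seed)
    decoy, _count = _wrong_site(record, recorded_bond, rng)
    if canonical_candidate_key(decoy.reactants) == canonical_candidate_key(record.reactants):
        raise SkipSignal("alternative site yields the recorded reactants")
    return decoy


def _spurious(record: ReactionRecord, rng: np.random.Generator) -> tuple[ReactionRecord, int]:
    """Recorded reactants plus one extra unmapped substituent."""
    extras = ["Cl", "Br", "C", "O"]
    candidates = []
    for ri, mol in enumerate(record.reactants):
        for ai, atom in enumerate(mol.rdmol.GetAtoms()):
            if atom.GetSymbol() == "C" and atom.GetTotalNumHs() >= 1 and not atom.GetIsAromatic():
                candidates.append((ri, ai))
    if not candidates:
        raise SkipSignal("no substitutable carbon")
    ri, ai = candidates[int(rng.integers(len(candidates)))]
    extra = extras[int(rng.integers(len(extras)))]
    reactants = []
    for i, mol in enumerate(record.reactants):
        if i != ri:
            reactants.append(mol)
            continue
        rw = Chem.RWMol(mol.rdmol)
        _attach_leaving(rw, ai, extra)
        new = rw.GetMol()
        Chem.SanitizeMol(new)
        reactants.append(MappedMolecule.from_rdkit(new))
    decoy = ReactionRecord(product=record.product, reactants=reactants, is_recorded=False)
    decoy.validate()
    return decoy, 1


def _noop(record: ReactionRecord) -> tuple[ReactionRecord, int]:
    """The product offered as its own precursor: zero changed bonds."""
    decoy = ReactionRecord(
        product=record.product, reactants=[record.product], is_recorded=False
    )
    decoy.validate()
    return decoy, 0


def _overlarge(
    template: _Template, product_mol: Chem.Mol, bond: tuple[int, int]
) -> tuple[ReactionRecord, int]:
    """Recorded disconnection with an implausibly large leaving group."""
    reactants = _disconnect(
        Chem.Mol(product_mol), bond, template.overlarge_a, template.leaving_b
    )
    decoy = ReactionRecord(
        product=MappedMolecule.from_rdkit(Chem.Mol(product_mol)),
        reactants=reactants,
        is_recorded=False,
    )
    decoy.validate()
    return decoy, 1


# ---------------------------------------------------------------------------
# dataset generation


def _sample_key(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    probs = np.array([weights[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def generate_dataset(config: SynthConfig) -> tuple[list[PredictionList], pd.DataFrame]:
    """Generate prediction lists plus a per-candidate ground-truth table.

    The returned DataFrame has one row per candidate with columns
    ``product_index, original_rank, category, template,
    planted_changed_bonds, planted_leaving_atoms``; the generator's planted
    values double as an oracle for the change-annotation code.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lists: list[PredictionList] = []
    truth_rows = []
    freq = {
        name: w / sum(config.template_weights.values())
        for name, w in config.template_weights.items()
    }
    for product_index in range(config.n_products):
        for _attempt in range(config.max_retries):
            try:
                plist, rows = _generate_product(product_index, config, rng, freq)
                break
            except SkipSignal:
                continue
        else:
            raise GenerationError(
                f"could not generate product {product_index} within retry budget"
            )
        lists.append(plist)
        truth_rows.extend(rows)
    return lists, pd.DataFrame(truth_rows)


def _generate_product(
    product_index: int,
    config: SynthConfig,
    rng: np.random.Generator,
    freq: dict[str, float],
):
    template = TEMPLATES[_sample_key(rng, config.template_weights)]
    product_mol, bond = _build_product(template, rng, config)
    recorded = _recorded_record(template, product_mol, bond)
    recorded_key = canonical_candidate_key(recorded.reactants)

    candidates = [("recorded", recorded, 1, template.name)]
    used_keys = {recorded_key}
    exhausted: set[str] = set()
    budget = config.max_retries * config.n_candidates
    while len(candidates) < config.n_candidates:
        if budget <= 0:
            raise SkipSignal("decoy retry budget exhausted")
        budget -= 1
        weights = {
            k: v for k, v in config.decoy_weights.items()
            if v > 0 and k not in exhausted
        }
        if not weights:
            raise SkipSignal("all decoy operators exhausted")
        op = _sample_key(rng, weights)
        try:
            if op == "wrong_site":
                decoy, planted = _wrong_site(recorded, bond, rng)
            elif op == "spurious":
                decoy, planted = _spurious(recorded, rng)
            elif op == "noop":
                decoy, planted = _noop(recorded)
                exhausted.add("noop")  # key is always the product itself
            else:
                decoy, planted = _overlarge(template, product_mol, bond)
                exhausted.add("overlarge")
        except SkipSignal:
            exhausted.add(op)
            continue
        key = canonical_candidate_key(decoy.reactants)
        if key == recorded_key:
            continue
        if key in used_keys and budget > config.max_retries:
            continue  # prefer distinct candidates while budget is comfortable
        used_keys.add(key)
        candidates.append((op, decoy, planted, template.name))

    # frequency-biased original ranking: each candidate mimics a reaction
    # pattern; the recorded one mimics its true template, decoys mimic
    # patterns drawn proportionally to frequency (i.e. frequent chemistry)
    scores = []
    for category, _decoy, _planted, _tname in candidates:
        f = freq[template.name] if category == "recorded" else freq[_sample_key(rng, freq)]
        scores.append(
            config.bias_beta * np.log(f) + config.noise_sigma * rng.standard_normal()
        )
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranked = [candidates[i] for i in order]
    records = []
    rows = []
    for rank, (category, record, planted, tname) in enumerate(ranked, start=1):
        record.original_rank = rank
        record.upstream_score = float(np.exp(scores[order[rank - 1]]))
        records.append(record)
        rows.append(
            {
                "product_index": product_index,
                "original_rank": rank,
                "category": category,
                "template": tname,
                "planted_changed_bonds": planted,
                "planted_leaving_atoms": _count_unmapped(record.reactants),
            }
        )
    plist = PredictionList(
        product_smiles=Chem.MolToSmiles(product_mol), candidates=records
    )
    plist.validate()
    return plist, rows


def generate_splits(
    config: SynthConfig, sizes: tuple[int, int, int]
) -> tuple[tuple[list[PredictionList], pd.DataFrame], ...]:
    """Independent train/validation/test datasets from one base seed."""
    out = []
    for i, n in enumerate(sizes):
        cfg = SynthConfig(**{**config.__dict__, "n_products": n, "seed": config.seed + 1000 * i})
        out.append(generate_dataset(cfg))
    return tuple(out)
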