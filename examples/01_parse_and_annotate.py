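"""Parse an atom-mapped reaction and inspect its potential reaction changes.

The atom map links product atoms to reactant atoms, so diffing the bonds
on the two sides reveals what the reaction would do: which bonds break or
form, which atoms sit at the reaction center, and which reactant atoms
leave.  These are the chemistry signals the ranking model consumes.
"""

from retroranker import annotate_changes, changed_bond_count, parse_mapped_reaction

# Fischer esterification, written in the retrosynthesis direction:
# methanol + acetic acid are the predicted reactants for methyl acetate.
rxn = "[CH3:1][OH:2].[CH3:3][C:4](=[O:5])[OH:6]>>[CH3:1][O:2][C:4](=[O:5])[CH3:3]"
record = parse_mapped_reaction(rxn)
annotation = annotate_changes(record, radius=1)

print("reaction:           ", rxn)
print("broken bonds:       ", sorted(annotation.broken_bonds))
print("formed bonds:       ", sorted(annotation.formed_bonds))
print("order-changed bonds:", sorted(annotation.order_changed_bonds))
print("reaction center:    ", sorted(annotation.center_atoms))
print("leaving atoms:      ", sorted(annotation.leaving_atoms))
print("changed bonds:      ", changed_bond_count(annotation))

# Bonds are keyed by atom-map pairs: (4, 6) is the acid C-OH bond that
# breaks, (2, 4) the new ester C-O bond; atom 6 (the acid hydroxyl oxygen)
# is the single leaving heavy atom, reported as (reactant index, atom index).
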