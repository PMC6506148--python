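"""Tanimoto analog retrieval around a query fingerprint.

Uses abstract feature-set fingerprints; the strict Tc > 0.70 rule mirrors
the 'above 70% similarity' criterion used for vendor-database hit
expansion.  Swap in `fingerprint_from_smiles` (RDKit Morgan features) for
real molecules.
"""

from kinscreen import Fingerprint, analog_search, tanimoto

query = Fingerprint("hit_1", frozenset({1, 2, 3, 4, 5, 6, 7, 8}))
library = [
    query,
    Fingerprint("analog_a", frozenset({1, 2, 3, 4, 5, 6, 7})),      # Tc 7/8
    Fingerprint("analog_b", frozenset({1, 2, 3, 4, 5, 6, 9, 10})),  # Tc 6/10
    Fingerprint("scaffold_hop", frozenset({1, 2, 3, 11, 12})),      # Tc 3/10
    Fingerprint("unrelated", frozenset({20, 21, 22})),              # Tc 0
]

print(f"query {query.compound_id}: {len(query.bits)} features")
for fp, tc in analog_search(query, library, threshold=0.70):
    print(f"  {fp.compound_id}: Tc = {tc:.3f}")
print("below threshold (for context):")
for fp in library[2:]:
    print(f"  {fp.compound_id}: Tc = {tanimoto(query, fp):.3f}")
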