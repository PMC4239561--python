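"""Score fractionation resistance for a handful of homology sets.

Each homology set holds the surviving copies of one ancestral (pre-WGD)
gene across three species; F = N + 1 counts the species still carrying the
set in duplicate.
"""

from fracres import HomologySet, compute_all_F

sets = [
    HomologySet("anc_001", {"peachlike": ["p1"], "grapelike": ["g1"], "cocoalike": ["c1"]}),
    HomologySet("anc_002", {"peachlike": ["p2", "p3"], "grapelike": ["g2"], "cocoalike": []}),
    HomologySet("anc_003", {"peachlike": ["p4", "p5"], "grapelike": ["g3", "g4"], "cocoalike": ["c2", "c3", "c4"]}),
]
compute_all_F(sets)

for hs in sets:
    copies = {sp: len(g) for sp, g in hs.members.items()}
    print(f"{hs.set_id}: copies per species {copies} -> F = {hs.F}")

print()
print("F = 1 means fully fractionated (singleton or lost everywhere);")
print("F = 4 would mean all three species still carry the duplicate.")
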