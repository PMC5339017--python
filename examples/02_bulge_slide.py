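"""Slide a 2-nt bulge along the SBH stem and score every placement.

Bulges destabilize the stem so it separates more easily after cleavage
while still silencing the guide in the OFF state. This scans all 19
placements of a single 2-nt spacer-strand bulge and prints the free-energy
cost of each position.
"""

from sbhdesign import BulgeElement, SpacerRecord, default_engine, slide_bulges

spacer = SpacerRecord("demo", "GCAUGCAUGCAUGCAUGCAU")
report = slide_bulges(spacer, pattern=(BulgeElement(0, 2),), engine=default_engine())

print(f"{len(report)} placements; stem MFE per bulge depth:")
for entry in report.entries:
    print(f"  depth {entry.x_or_offset:2d}: {entry.stem_mfe:6.1f} kcal/mol")
print("\nEach entry also carries ready-to-order cloning oligos, e.g.:")
print("  top   ", report.entries[0].oligos.top)
print("  bottom", report.entries[0].oligos.bottom)
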