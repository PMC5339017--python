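"""Enumerate the SBH(x) series for one spacer.

Builds every spacer-blocking hairpin leaving x = 0..20 spacer nucleotides
free, folds each hairpin, and prints sequence, predicted structure and stem
MFE. Lower (more negative) MFE means a more stable stem, i.e. stronger
silencing of the guide; x = 20 is the degenerate native guide.
"""

from sbhdesign import SpacerRecord, default_engine, sbh_series

spacer = SpacerRecord("demo", "GCAUGCAUGCAUGCAUGCAU")
report = sbh_series(spacer, engine=default_engine())

print(f"{len(report)} constructs for spacer {spacer.name}\n")
for entry in report.entries[::5]:
    print(entry.label)
    print("  ", entry.fold.sequence)
    print("  ", entry.fold.structure, f"({entry.stem_mfe:.1f} kcal/mol)")
print("\nStem stability weakens as coverage shrinks; pick the x that")
print("balances OFF-state silencing against post-cleavage release.")
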