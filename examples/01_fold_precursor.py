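"""Fold a pre-miRNA-like hairpin and compute its screening statistics.

The screen keeps precursors with MFE <= -15 kcal/mol, MFEI <= -0.7 and GC
between 20 and 70 %; MFEI <= -0.85 additionally marks high confidence.
"""

from mirhunt.folding import fold
from mirhunt.screen import amfe, gc_percent, mfei

# a miR156-like mature, an A/C loop, and the complementary star arm
seq = ("UGACAGAAGAGAGUGAGCAC" "ACAACAAC" "GUGCUCACUCUCUUCUGUCA" "AC")
structure = fold(seq)

gc = gc_percent(seq)
print("sequence :", seq)
print("structure:", structure.pairing)
print(f"MFE  = {structure.mfe:.1f} kcal/mol   (negative = stable fold)")
print(f"AMFE = {amfe(structure.mfe, len(seq)):.1f} kcal/mol per 100 nt")
print(f"MFEI = {mfei(structure.mfe, len(seq), gc):.3f}   GC = {gc:.1f}%")
print("MFEI at or below -0.85 is considered strongly indicative of a real pre-miRNA.")
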