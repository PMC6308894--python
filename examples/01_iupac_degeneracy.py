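"""Degenerate-primer arithmetic on the built-in COI panel.

A primer written with IUPAC ambiguity codes is a pool of plain
oligonucleotides; its degeneracy is the pool size.  High degeneracy buys
taxonomic coverage at the cost of synthesis complexity and uneven
annealing, so the pool size is a primary design quantity.
"""

from ambiprime import BUILTIN_PANEL, degeneracy, expand, revcomp

for name in ("LepF1", "mlCOIintF", "jgHCO2198", "Sauron-S878"):
    p = BUILTIN_PANEL[name]
    print(f"{name:12s} {p.orientation:7s} {p.sequence}  degeneracy={p.degeneracy}")

sauron = BUILTIN_PANEL["Sauron-S878"]
pool = expand(sauron.sequence)
print(f"\n{sauron.name} expands to {len(pool)} distinct plain primers;")
print(f"counting without enumerating agrees: {degeneracy(sauron.sequence)}")
print(f"reverse complement (binding-site motif on the template's other "
      f"strand):\n  {revcomp(sauron.sequence)}")
# The pool size is what a synthesis order for the degenerate oligo mixes
# together in one tube; every template variant covered by a pool member
# can seed amplification.
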