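"""Redesigning a primer from site base frequencies, and vetting a tail.

Starting from the narrower forward primer's priming site, per-column base
frequencies are folded into the smallest IUPAC codes covering every base
above a frequency threshold.  Templates carrying a variant at the 3rd base
from the 3' end — a Y column in the narrower primer — mismatch it fatally
but match a primer degenerate (N) at that position.
"""

import numpy as np

from ambiprime import (
    check_tail,
    column_profiles,
    coverage_gain,
    expand,
    get_primer,
    mismatch_profile,
    propose_degenerate_primer,
)
from ambiprime.reference import ReferenceSet, SequenceRecord

old = get_primer("mlCOIintF")
base = sorted(expand(old.sequence))[0]

# synthetic site strings: 30% carry G at the primer's 3rd-from-3'-end Y
rng = np.random.default_rng(4)
sites = {}
for i in range(50):
    s = list(sorted(expand(old.sequence))[int(rng.integers(128))])
    if i < 15:
        s[len(s) - 3] = "G"
    sites[f"seq{i:02d}"] = "".join(s)

profiles = column_profiles(list(sites.values()))
result = propose_degenerate_primer(profiles, f_min=0.05, name="redesigned")
print(f"old primer: {old.sequence} (degeneracy {old.degeneracy})")
print(f"new primer: {result.primer.sequence} (degeneracy {result.primer.degeneracy})")

gain = coverage_gain(old, result.primer, sites, criterion=(0, 3))
print("\ncoverage under (0 mismatches 3', <=3 remainder):")
print(gain.by_group.round(3).to_string(index=False))
variant = [s for s in sites.values() if s[len(s) - 3] == "G"][0]
po, pn = mismatch_profile(old, variant), mismatch_profile(result.primer, variant)
print(f"\nvariant site vs old primer: (m3={po.m3}, m5={po.m5}) -> rejected")
print(f"variant site vs new primer: (m3={pn.m3}, m5={pn.m5}) -> amplifiable")

# a universal tail must fit poorly everywhere in the reference set
refs = ReferenceSet(
    [SequenceRecord(seq_id=f"r{i}", sequence="".join(rng.choice(list("ACGT"), 300)))
     for i in range(20)]
)
chk = check_tail("cacctgcttctaaat", refs)
print(f"\ntail check: max identity {chk.max_identity:.2f} "
      f"(threshold {chk.threshold}) -> {'PASS' if chk.passed else 'FAIL'}")
# PASS means the tail will stay unbound during early locus-specific cycles.
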