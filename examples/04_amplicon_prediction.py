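"""In silico PCR: predicting products of the reference primer pair.

Both strands of an unaligned template are scanned for windows matching
each primer under a zoned mismatch criterion; forward/reverse site pairs
in amplifiable configuration become predicted products.  Lengths include
both primer footprints, under which convention this pair yields a 313 bp
COI fragment (26 nt forward footprint + 261 nt insert + 26 nt reverse
footprint).
"""

import numpy as np

from ambiprime import expand, get_primer, predict_amplicons, revcomp

fwd, rev = get_primer("Sauron-S878"), get_primer("jgHCO2198")
rng = np.random.default_rng(313)
template = (
    sorted(expand(fwd.sequence))[0]
    + "".join(rng.choice(list("ACGT"), size=261))
    + revcomp(sorted(expand(rev.sequence))[0])
)

amps = predict_amplicons(fwd, rev, template, max_m3=0, max_m5=3, seq_id="demo")
for a in amps:
    print(
        f"amplicon {a.start}-{a.end} (0-based half-open), length {a.length} bp; "
        f"fwd site {a.fwd_site.offset}/{a.fwd_site.strand} "
        f"(m3={a.fwd_site.m3}, m5={a.fwd_site.m5}), "
        f"rev site {a.rev_site.offset}/{a.rev_site.strand} "
        f"(m3={a.rev_site.m3}, m5={a.rev_site.m5})"
    )
# One product of 313 bp: a length well suited to paired-end short-read
# sequencing with overlapping reads.
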