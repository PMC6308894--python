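"""Binding-site scanning and in silico amplicon prediction.

Unaligned templates are scanned exhaustively on both strands for windows
matching a degenerate primer under a zoned mismatch criterion (the same
3′-zone/remainder counting used for coverage evaluation), and plus/minus
site pairs in amplifiable configuration are combined into predicted
amplicons.  Amplicon length *includes both primer footprints* — the
convention under which the Sauron-S878/jgHCO2198 pair yields its ~313 bp
COI fragment — and every report states this.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import revcomp, symbols_match
from .primers import THREE_PRIME_ZONE, DegeneratePrimer

__all__ = ["BindingSite", "Amplicon", "find_binding_sites", "predict_amplicons"]


@dataclass(frozen=True)
class BindingSite:
    """One qualifying primer footprint on the plus strand of a template."""

    seq_id: str
    primer_name: str
    offset: int  # 0-based start of the footprint on the plus strand
    strand: str  # plus | minus
    m3: int
    m5: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, 0-based half-open on the plus strand.

    ``length = end - start`` counts both primer footprints.
    """

    seq_id: str
    start: int
    end: int
    fwd_site: BindingSite
    rev_site: BindingSite

    @property
    def length(self) -> int:
        return self.end - self.start


def _zoned(primer_seq: str, window: str, mode: str, zone: int) -> tuple[int, int]:
    mism = [
        not symbols_match(p, t, mode) for p, t in zip(primer_seq, window)
    ]
    return sum(mism[-zone:]), sum(mism[:-zone])


def find_binding_sites(
    primer: DegeneratePrimer,
    sequence: str,
    max_m3: int = 0,
    max_m5: int = 3,
    *,
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
    seq_id: str = "",
) -> list[BindingSite]:
    """Exhaustively scan both strands for qualifying primer footprints.

    A plus-strand site is a window reading as the primer 5′→3′; a
    minus-strand site is a window reading as its reverse complement (the
    primer binds the minus strand there).  Zoned mismatch counting is the
    shared implementation used throughout; all sites meeting
    ``m3 ≤ max_m3 and m5 ≤ max_m5`` are returned sorted by offset.
    """
    seq = sequence.upper()
    pseq = primer.locus_sequence
    L = len(pseq)
    if len(seq) < L:
        return []
    rc = revcomp(pseq)
    sites = []
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        # plus strand: window aligns to the primer directly
        m3, m5 = _zoned(pseq, window, mode, zone)
        if m3 <= max_m3 and m5 <= max_m5:
            sites.append(BindingSite(seq_id, primer.name, off, "plus", m3, m5))
        # minus strand: primer binds the complement; its footprint on the
        # plus strand reads as revcomp(primer), with the primer 3' zone at
        # the window start
        mism = [not symbols_match(p, t, mode) for p, t in zip(rc, window)]
        m3 = sum(mism[:zone])
        m5 = sum(mism[zone:])
        if m3 <= max_m3 and m5 <= max_m5:
            sites.append(BindingSite(seq_id, primer.name, off, "minus", m3, m5))
    return sites


def predict_amplicons(
    fwd: DegeneratePrimer,
    rev: DegeneratePrimer,
    sequence: str,
    max_m3: int = 0,
    max_m5: int = 3,
    min_len: int = 50,
    max_len: int = 2000,
    *,
    mode: str = "intersection",
    zone: int = THREE_PRIME_ZONE,
    seq_id: str = "",
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Pairs every plus-strand forward site with every downstream
    minus-strand reverse site, and symmetrically every plus-strand reverse
    site with every downstream minus-strand forward site (the template in
    the opposite sense).  Footprints must not overlap; only amplicons with
    length (both primers included) in ``[min_len, max_len]`` are emitted,
    sorted by start then length.
    """
    if fwd.orientation != "forward":
        raise ValueError(f"{fwd.name!r} is not a forward primer")
    if rev.orientation != "reverse":
        raise ValueError(f"{rev.name!r} is not a reverse primer")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")

    fwd_sites = find_binding_sites(
        fwd, sequence, max_m3, max_m5, mode=mode, zone=zone, seq_id=seq_id
    )
    rev_sites = find_binding_sites(
        rev, sequence, max_m3, max_m5, mode=mode, zone=zone, seq_id=seq_id
    )
    Lf, Lr = len(fwd.locus_sequence), len(rev.locus_sequence)

    out = []
    # canonical configuration: fwd on plus, rev on minus, rev downstream
    for f in (s for s in fwd_sites if s.strand == "plus"):
        for r in (s for s in rev_sites if s.strand == "minus"):
            if r.offset >= f.offset + Lf:
                length = r.offset + Lr - f.offset
                if min_len <= length <= max_len:
                    out.append(Amplicon(seq_id, f.offset, r.offset + Lr, f, r))
    # opposite sense: the product maps to the minus strand of this template
    for r in (s for s in rev_sites if s.strand == "plus"):
        for f in (s for s in fwd_sites if s.strand == "minus"):
            if f.offset >= r.offset + Lr:
                length = f.offset + Lf - r.offset
                if min_len <= length <= max_len:
                    out.append(Amplicon(seq_id, r.offset, f.offset + Lf, f, r))
    out.sort(key=lambda a: (a.start, a.length))
    return out
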