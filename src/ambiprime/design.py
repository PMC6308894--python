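"""Consensus-based degenerate primer design and universal-tail vetting.

A new degenerate primer is proposed from the per-column base frequencies of
a priming-site alignment: every base reaching a minimum frequency at a
column is folded into the smallest IUPAC symbol containing exactly that
set.  This is how extra degeneracy is incorporated into an existing primer
to rescue taxa that carry systematic variants (notably in the 3′ zone,
where a single mismatch can abolish amplification).  A degeneracy cap is
enforced greedily on the least informative columns so the designed pool
stays synthesizable.

Universal 5′ tails must bind *nowhere* in the reference set — they act as
priming sites only after being incorporated into early-cycle product — so
:func:`check_tail` scans every record, both strands, every offset for the
tail's best sequence identity and fails the tail if any match is too good.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import SYMBOL_FOR_SET, revcomp, symbols_match
from .primers import DegeneratePrimer
from .reference import ReferenceSet, SiteSpec, encode, extract_site

__all__ = [
    "ColumnProfile",
    "column_profiles",
    "propose_degenerate_primer",
    "DesignResult",
    "coverage_gain",
    "GainReport",
    "check_tail",
    "TailCheck",
]

_ACGT = ("A", "C", "G", "T")


@dataclass(frozen=True)
class ColumnProfile:
    """Base frequencies at one primer position over covering sequences.

    ``freq`` is over plain A/C/G/T only; gap or ambiguous template
    characters are excluded from it but counted in ``n_ambiguous``.
    """

    column: int
    freq: dict[str, float]
    n: int
    n_ambiguous: int = 0

    def entropy(self) -> float:
        """Shannon entropy (bits) of the column's base distribution."""
        return -sum(p * math.log2(p) for p in self.freq.values() if p > 0)


def column_profiles(
    refset_or_sites: ReferenceSet | list[str],
    site: SiteSpec | None = None,
    primer_length: int | None = None,
) -> list[ColumnProfile]:
    """Per-position base-frequency profiles of a priming site.

    Accepts either a list of plus-strand site strings, or an aligned
    :class:`ReferenceSet` with a :class:`SiteSpec` (site strings are then
    extracted, covered records only).  Designing a reverse primer is done
    by the caller on the reverse-complemented site strings.
    """
    if isinstance(refset_or_sites, ReferenceSet):
        if site is None:
            raise ValueError("a SiteSpec is required with a ReferenceSet input")
        site_seqs = [
            e.site_seq
            for e in (
                extract_site(r, site, primer_length) for r in refset_or_sites
            )
            if e.covered
        ]
    else:
        site_seqs = list(refset_or_sites)
    if not site_seqs:
        raise ValueError("no covering sequences: cannot profile the site")
    L = len(site_seqs[0])
    if any(len(s) != L for s in site_seqs):
        raise ValueError("site strings must share one length")

    profiles = []
    for j in range(L):
        counts = {b: 0 for b in _ACGT}
        ambiguous = 0
        for s in site_seqs:
            ch = s[j].upper()
            if ch in counts:
                counts[ch] += 1
            else:
                ambiguous += 1
        n = sum(counts.values())
        freq = {b: c / n for b, c in counts.items() if c} if n else {}
        profiles.append(
            ColumnProfile(column=j, freq=freq, n=n, n_ambiguous=ambiguous)
        )
    return profiles


@dataclass
class DesignResult:
    """A proposed primer plus the deterministic cap-enforcement log."""

    primer: DegeneratePrimer
    base_sets: list[frozenset[str]]
    adjustments: list[str] = field(default_factory=list)


def propose_degenerate_primer(
    profiles: list[ColumnProfile],
    f_min: float = 0.05,
    max_degeneracy: int = 1024,
    *,
    name: str = "designed",
    orientation: str = "forward",
) -> DesignResult:
    """Fold every base with frequency ≥ *f_min* into a degenerate primer.

    Per column, the included base set is encoded as the smallest IUPAC
    symbol containing exactly those bases.  If the product of set sizes
    would exceed *max_degeneracy*, degeneracy is pruned greedily: columns
    are visited in ascending entropy (ties by 5′ position) and their
    lowest-frequency included base is dropped, until the cap holds.  The
    pruning order is deterministic and recorded in the result.
    """
    if not 0 < f_min < 1:
        raise ValueError(f"f_min must be in (0, 1), got {f_min}")
    sets: list[set[str]] = []
    for prof in profiles:
        included = {b for b, f in prof.freq.items() if f >= f_min}
        if not included:
            raise ValueError(
                f"column {prof.column}: no base reaches f_min={f_min} "
                f"(freq={prof.freq})"
            )
        sets.append(included)

    adjustments: list[str] = []

    def total_degeneracy() -> int:
        d = 1
        for s in sets:
            d *= len(s)
        return d

    # prune the least informative columns first: ascending entropy,
    # ties by position from the 5' end
    order = sorted(range(len(profiles)), key=lambda j: (profiles[j].entropy(), j))
    while total_degeneracy() > max_degeneracy:
        pruned = False
        for j in order:
            if len(sets[j]) > 1:
                drop = min(sets[j], key=lambda b: (profiles[j].freq.get(b, 0.0), b))
                sets[j].discard(drop)
                adjustments.append(
                    f"column {j}: dropped {drop} "
                    f"(freq {profiles[j].freq.get(drop, 0.0):.4f}) to meet "
                    f"degeneracy cap {max_degeneracy}"
                )
                pruned = True
                break
        if not pruned:  # every column is a singleton; cannot prune further
            break

    sequence = "".join(SYMBOL_FOR_SET[frozenset(s)] for s in sets)
    primer = DegeneratePrimer(name=name, sequence=sequence, orientation=orientation)
    return DesignResult(
        primer=primer,
        base_sets=[frozenset(s) for s in sets],
        adjustments=adjustments,
    )


@dataclass
class GainReport:
    """Coverage difference between an old and a redesigned primer."""

    by_group: pd.DataFrame  # group, n, coverage_old, coverage_new, gain
    by_position: pd.DataFrame  # position, n_mismatch_old, n_mismatch_new, n_rescued
    criterion: tuple[int, int]


def coverage_gain(
    primer_old: DegeneratePrimer,
    primer_new: DegeneratePrimer,
    site_seqs: dict[str, str] | list[str],
    criterion: tuple[int, int] = (0, 3),
    *,
    taxonomy: dict[str, str] | None = None,
    mode: str = "intersection",
) -> GainReport:
    """Quantify what a redesigned primer gains over the original.

    Both primers are profiled on the same plus-strand site strings under
    the stated (max 3′, max remainder) criterion; coverage is reported per
    taxonomic class (when *taxonomy* maps seq_id → class) and overall,
    together with a per-position table of how many sequences mismatch each
    primer at each position and how many the new primer rescues there.
    """
    from .coverage import mismatch_profile  # local import to avoid a cycle

    if len(primer_old.locus_sequence) != len(primer_new.locus_sequence):
        raise ValueError("primers must have equal locus length")
    if primer_old.orientation != primer_new.orientation:
        raise ValueError("primers must share orientation")
    if isinstance(site_seqs, dict):
        items = list(site_seqs.items())
    else:
        items = [(str(i), s) for i, s in enumerate(site_seqs)]

    max_m3, max_m5 = criterion
    L = len(primer_old.locus_sequence)
    rows = []
    mm_old = np.zeros(L, dtype=int)
    mm_new = np.zeros(L, dtype=int)
    rescued = np.zeros(L, dtype=int)
    for seq_id, s in items:
        po = mismatch_profile(primer_old, s, seq_id=seq_id, mode=mode)
        pn = mismatch_profile(primer_new, s, seq_id=seq_id, mode=mode)
        ok_old = po.m3 <= max_m3 and po.m5 <= max_m5
        ok_new = pn.m3 <= max_m3 and pn.m5 <= max_m5
        group = (taxonomy or {}).get(seq_id, "OVERALL")
        rows.append((group, ok_old, ok_new))
        template = s if primer_old.orientation == "forward" else revcomp(s)
        for j in range(L):
            o = not symbols_match(primer_old.locus_sequence[j], template[j], mode)
            n_ = not symbols_match(primer_new.locus_sequence[j], template[j], mode)
            mm_old[j] += o
            mm_new[j] += n_
            rescued[j] += o and not n_

    df = pd.DataFrame(rows, columns=["group", "ok_old", "ok_new"])
    groups = []
    frames = [("OVERALL", df)] + [
        (g, sub) for g, sub in df.groupby("group") if g != "OVERALL" or taxonomy is None
    ]
    seen = set()
    for g, sub in frames:
        if g in seen:
            continue
        seen.add(g)
        groups.append(
            {
                "group": g,
                "n": len(sub),
                "coverage_old": sub["ok_old"].mean(),
                "coverage_new": sub["ok_new"].mean(),
                "gain": sub["ok_new"].mean() - sub["ok_old"].mean(),
            }
        )
    by_position = pd.DataFrame(
        {
            "position": np.arange(L),
            "n_mismatch_old": mm_old,
            "n_mismatch_new": mm_new,
            "n_rescued": rescued,
        }
    )
    return GainReport(
        by_group=pd.DataFrame(groups),
        by_position=by_position,
        criterion=criterion,
    )


@dataclass(frozen=True)
class TailCheck:
    """Best genome-wide match of a universal tail against a reference set."""

    tail: str
    max_identity: float
    seq_id: str | None
    offset: int | None
    strand: str | None
    threshold: float
    passed: bool


def check_tail(
    tail: str,
    refset: ReferenceSet,
    *,
    threshold: float = 0.85,
) -> TailCheck:
    """Verify a universal tail fits poorly everywhere in the reference set.

    Slides the tail (and its reverse complement) over every record at
    every ungapped offset, scoring the fraction of matching positions, and
    FAILs if the best identity exceeds *threshold*.  An empty reference
    set passes with a warning.
    """
    tail = tail.upper()
    if len(tail) < 8:
        raise ValueError(f"tail too short ({len(tail)} nt); need at least 8")
    if len(refset) == 0:
        warnings.warn("empty reference set: tail check passes vacuously")
        return TailCheck(tail, 0.0, None, None, None, threshold, True)

    probes = {"plus": encode(tail), "minus": encode(revcomp(tail))}
    L = len(tail)
    best = (-1.0, None, None, None)
    for rec in refset:
        arr = encode(rec.sequence)
        if arr.size < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, L)
        for strand, probe in probes.items():
            ident = ((win & probe) != 0).mean(axis=1)
            k = int(np.argmax(ident))
            if ident[k] > best[0]:
                best = (float(ident[k]), rec.seq_id, k, strand)
    max_ident, seq_id, offset, strand = best
    max_ident = max(max_ident, 0.0)
    return TailCheck(
        tail=tail,
        max_identity=max_ident,
        seq_id=seq_id,
        offset=offset,
        strand=strand,
        threshold=threshold,
        passed=max_ident <= threshold,
    )
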