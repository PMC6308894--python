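"""Reference sequences, taxonomy, species dereplication and priming sites.

A reference set joins nucleotide records (typically COI barcode sequences)
to a species/order/class taxonomy.  To avoid biasing primer-fit statistics
toward heavily sequenced species, the set is dereplicated to one — the
longest — representative per species before evaluation.  Priming sites are
column intervals of a multiple sequence alignment; a record *covers* a site
only if its degapped window is full length and indel-free, so per-primer
denominators count exactly the sequences on which the primer can be scored
position-by-position (COI is protein coding, so indel-free sites are the
norm).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .iupac import IUPAC_SETS, revcomp
from .primers import DegeneratePrimer

__all__ = [
    "SequenceRecord",
    "ReferenceSet",
    "SiteSpec",
    "SiteExtraction",
    "read_reference",
    "dereplicate_by_species",
    "locate_site",
    "extract_site",
]

GAP = "-"

# 4-bit encoding: one bit per base; ambiguity codes OR their bases, gaps
# and unknown characters encode to 0.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE = np.zeros(256, dtype=np.uint8)
for _sym, _bases in IUPAC_SETS.items():
    _val = sum(_BASE_BIT[b] for b in _bases)
    _CODE[ord(_sym)] = _val
    _CODE[ord(_sym.lower())] = _val
for _u in "Uu":
    _CODE[ord(_u)] = _BASE_BIT["T"]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array of base bitmasks."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SequenceRecord:
    """One reference sequence with its taxonomic annotation.

    ``aligned`` holds the gapped row of the source alignment when the input
    FASTA was aligned; ``sequence`` is always the degapped string.
    Taxonomy fields are empty strings when unknown, never absent.
    """

    seq_id: str
    sequence: str
    species: str = ""
    order: str = ""
    class_: str = ""
    aligned: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteSpec:
    """A priming site: an alignment column interval, 0-based half-open."""

    primer_name: str
    start: int
    end: int
    strand: str  # "plus" | "minus"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid site interval [{self.start}, {self.end})")
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"strand must be 'plus' or 'minus', got {self.strand!r}")


@dataclass(frozen=True)
class SiteExtraction:
    """Result of extracting one record's priming-site subsequence."""

    seq_id: str
    covered: bool
    site_seq: str | None = None
    reason: str | None = None  # terminal_gap | internal_indel | length_mismatch | invalid_character


class ReferenceSet:
    """An ordered collection of :class:`SequenceRecord` with a load report."""

    def __init__(self, records: list[SequenceRecord], report: dict | None = None):
        ids = [r.seq_id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_id(s): {dup[:5]}")
        self.records = list(records)
        self.report = dict(report or {})
        lengths = {len(r.aligned) for r in self.records if r.aligned is not None}
        if len(lengths) > 1:
            raise ValueError(f"aligned records have inconsistent lengths: {sorted(lengths)}")
        self.alignment_length = lengths.pop() if lengths else None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    @property
    def is_aligned(self) -> bool:
        return self.alignment_length is not None

    def taxonomy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seq_id": [r.seq_id for r in self.records],
                "species": [r.species for r in self.records],
                "order": [r.order for r in self.records],
                "class": [r.class_ for r in self.records],
            }
        )


def read_reference(
    sequences: str | Path,
    taxonomy: str | Path | None = None,
    *,
    aligned: bool | None = None,
) -> ReferenceSet:
    """Load a FASTA (aligned or unaligned) and join a taxonomy TSV.

    The taxonomy TSV must have a header ``seq_id  species  order  class``.
    Records missing from the taxonomy are retained with empty taxonomy
    fields and counted as unjoined in the load report.  When *aligned* is
    None the dialect is auto-detected from the presence of gap characters.
    """
    sequences = Path(sequences)
    _check_fasta_wellformed(sequences)
    tax: dict[str, tuple[str, str, str]] = {}
    if taxonomy is not None:
        tdf = pd.read_csv(taxonomy, sep="\t", dtype=str).fillna("")
        required = {"seq_id", "species", "order", "class"}
        if not required <= set(tdf.columns):
            raise ValueError(
                f"taxonomy {taxonomy}: expected columns {sorted(required)}, "
                f"got {list(tdf.columns)}"
            )
        tax = {
            r["seq_id"]: (r["species"], r["order"], r["class"])
            for _, r in tdf.iterrows()
        }

    raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(sequences), "fasta")]
    if aligned is None:
        # gap characters mean an alignment; an indel-free alignment (all
        # rows one length) is also accepted as aligned
        aligned = any(GAP in s for _, s in raw) or (
            len(raw) > 1 and len({len(s) for _, s in raw}) == 1
        )

    records: list[SequenceRecord] = []
    unjoined = 0
    for seq_id, seq in raw:
        species, order, class_ = tax.get(seq_id, ("", "", ""))
        if seq_id not in tax and tax:
            unjoined += 1
        records.append(
            SequenceRecord(
                seq_id=seq_id,
                sequence=seq.replace(GAP, "").upper(),
                species=species,
                order=order,
                class_=class_,
                aligned=seq.upper() if aligned else None,
            )
        )
    if not records:
        warnings.warn(f"{sequences}: empty FASTA, reference set is empty")
    report = {
        "n_records": len(records),
        "n_unjoined": unjoined,
        "aligned": bool(aligned),
        "source": str(sequences),
    }
    return ReferenceSet(records, report)


def _check_fasta_wellformed(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, expected '>' header at line {lineno}"
                    )
                return


_WS = re.compile(r"\s+")
_SP_KEY = re.compile(r"\bsp\.?$")


def species_key(species: str) -> str:
    """Whitespace-normalized, case-folded species key for dereplication."""
    return _WS.sub(" ", species.strip()).casefold()


def dereplicate_by_species(
    refset: ReferenceSet, *, drop_unidentified: bool = False
) -> ReferenceSet:
    """Reduce to one (the longest) representative per unique species.

    Ties on ungapped length are broken by lexicographically smallest
    ``seq_id``; records with an empty species are dropped and counted.
    With ``drop_unidentified`` entries like ``"Genus sp."`` are dropped too
    (by default they are kept as distinct species keys).  Idempotent.
    """
    best: dict[str, SequenceRecord] = {}
    dropped_empty = 0
    dropped_sp = 0
    for rec in refset:
        key = species_key(rec.species)
        if not key:
            dropped_empty += 1
            continue
        if drop_unidentified and _SP_KEY.search(key):
            dropped_sp += 1
            continue
        cur = best.get(key)
        if (
            cur is None
            or rec.length > cur.length
            or (rec.length == cur.length and rec.seq_id < cur.seq_id)
        ):
            best[key] = rec
    kept = sorted(best.values(), key=lambda r: r.seq_id)
    report = dict(refset.report)
    report.update(
        {
            "n_records": len(kept),
            "n_species": len(best),
            "n_dropped_empty_species": dropped_empty,
            "n_dropped_unidentified": dropped_sp,
        }
    )
    return ReferenceSet(kept, report)


def _site_probe(primer: DegeneratePrimer) -> str:
    """Plus-strand template motif the primer footprint should read as."""
    seq = primer.locus_sequence
    return seq if primer.orientation == "forward" else revcomp(seq)


def locate_site(
    refset: ReferenceSet,
    primer: DegeneratePrimer,
    *,
    subsample: int | None = 1000,
    seed: int = 0,
) -> SiteSpec:
    """Find the alignment window where a primer fits best.

    Scans every window of L alignment columns (L = locus primer length),
    comparing the primer — reverse primers via their reverse complement —
    against each record's window, and returns the window maximizing the
    mean fraction of matching positions over records whose window is
    gap-free and full length.  Ties go to the leftmost window.  For speed
    the mean is taken over a seeded random subsample of records
    (default 1,000; pass ``subsample=None`` for the exact mode using every
    record).
    """
    if not refset.is_aligned:
        raise ValueError("locate_site requires an aligned reference set")
    if len(refset) == 0:
        raise ValueError("locate_site requires a nonempty reference set")
    probe = _site_probe(primer)
    L = len(probe)
    A = refset.alignment_length
    if A < L:
        raise ValueError(f"alignment length {A} shorter than primer length {L}")

    records = refset.records
    if subsample is not None and len(records) > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(records), size=subsample, replace=False)
        records = [records[i] for i in sorted(idx)]

    M = np.vstack([encode(r.aligned) for r in records])  # (n, A) bitmasks
    pmask = encode(probe)  # (L,)

    best_score, best_start = -1.0, 0
    for c in range(A - L + 1):
        sub = M[:, c : c + L]
        valid = (sub != 0).all(axis=1)
        if not valid.any():
            continue
        frac = ((sub[valid] & pmask) != 0).mean(axis=1)
        score = float(frac.mean())
        if score > best_score + 1e-12:
            best_score, best_start = score, c
    strand = "plus" if primer.orientation == "forward" else "minus"
    return SiteSpec(primer_name=primer.name, start=best_start, end=best_start + L, strand=strand)


_VALID_CHARS = set(IUPAC_SETS) | {GAP}


def extract_site(
    record: SequenceRecord, site: SiteSpec, primer_length: int | None = None
) -> SiteExtraction:
    """Extract one record's site subsequence, or classify why it cannot be.

    Takes the aligned columns ``[start, end)``, removes gaps, and returns
    the string iff it is exactly primer length with no characters outside
    the IUPAC alphabet.  Otherwise the record does not cover the site and a
    reason code is returned: ``terminal_gap`` (window starts/ends in a gap,
    i.e. the record does not span the site), ``internal_indel``,
    ``length_mismatch`` (a wider-than-primer window without the right
    number of bases) or ``invalid_character``.
    """
    if record.aligned is None:
        raise ValueError(f"record {record.seq_id}: no aligned sequence")
    if site.end > len(record.aligned):
        raise ValueError(
            f"site [{site.start}, {site.end}) out of bounds for alignment "
            f"length {len(record.aligned)}"
        )
    if primer_length is None:
        primer_length = site.end - site.start
    window = record.aligned[site.start : site.end]
    bad = set(window) - _VALID_CHARS
    if bad:
        return SiteExtraction(record.seq_id, False, reason="invalid_character")
    if window.startswith(GAP) or window.endswith(GAP):
        return SiteExtraction(record.seq_id, False, reason="terminal_gap")
    degapped = window.replace(GAP, "")
    if GAP in window:
        return SiteExtraction(record.seq_id, False, reason="internal_indel")
    if len(degapped) != primer_length:
        return SiteExtraction(record.seq_id, False, reason="length_mismatch")
    return SiteExtraction(record.seq_id, True, site_seq=degapped)
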