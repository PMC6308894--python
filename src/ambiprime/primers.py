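"""Degenerate primer records and the built-in COI metabarcoding panel.

A :class:`DegeneratePrimer` is a named 5′→3′ IUPAC string with an
orientation (forward/reverse), a role, and an optional universal-tail
annotation.  By the panel-file convention, a lowercase prefix of the input
sequence marks a 5′ universal tail — a region deliberately non-complementary
to the template that serves as an identical priming site in later PCR
cycles; case never affects matching.

The built-in panel collects widely used COI barcoding/metabarcoding primers
(Folmer-region minibarcode and Leray-fragment primers) together with the
highly degenerate Sauron-S878 forward primer and its tailed derivatives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .iupac import degeneracy, nt_set

__all__ = ["DegeneratePrimer", "BUILTIN_PANEL", "load_panel", "get_primer"]

ORIENTATIONS = ("forward", "reverse")
ROLES = ("locus", "tail1", "tail2", "sequencing")

#: Width (nt) of the 3′ terminal zone whose mismatches disproportionately
#: block polymerase extension.
THREE_PRIME_ZONE = 4


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC-degenerate oligonucleotide, written 5′→3′.

    ``tail``, if present, is the 5′ prefix annotated as a universal tail;
    ``sequence`` stores the full uppercase string including the tail, and
    ``locus_sequence`` strips it.
    """

    name: str
    sequence: str
    orientation: str = "forward"
    role: str = "locus"
    tail: str | None = None

    def __post_init__(self) -> None:
        raw = self.sequence
        tail = self.tail
        if tail is None:
            # lowercase prefix convention: a leading run of lowercase letters
            # is the universal-tail annotation
            n = 0
            while n < len(raw) and raw[n].islower():
                n += 1
            if n:
                tail = raw[:n].upper()
        else:
            tail = tail.upper()
            if not raw.upper().startswith(tail) or tail == raw.upper():
                raise ValueError(
                    f"primer {self.name!r}: tail must be a strict prefix of sequence"
                )
        seq = raw.upper()
        for i, ch in enumerate(seq):
            nt_set(ch, position=i)  # raises on invalid symbols
        if len(seq) < THREE_PRIME_ZONE + 1:
            raise ValueError(
                f"primer {self.name!r}: length {len(seq)} < {THREE_PRIME_ZONE + 1}; "
                "the 3' zone plus at least one remainder base must exist"
            )
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"primer {self.name!r}: orientation must be one of {ORIENTATIONS}"
            )
        if self.role not in ROLES:
            raise ValueError(f"primer {self.name!r}: role must be one of {ROLES}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "tail", tail)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def locus_sequence(self) -> str:
        """Sequence with any 5′ universal tail stripped."""
        if self.tail:
            return self.sequence[len(self.tail):]
        return self.sequence

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)


def _p(name: str, seq: str, orientation: str, role: str = "locus") -> DegeneratePrimer:
    return DegeneratePrimer(name=name, sequence=seq, orientation=orientation, role=role)


#: Published COI primers plus the Sauron-S878 panel, sequences as printed.
BUILTIN_PANEL: dict[str, DegeneratePrimer] = {
    p.name: p
    for p in [
        _p("Uni-MinibarF1-d", "TCYACTAATCATAAAGATATTGGYAC", "forward"),
        _p("Uni-MinibarR1-d", "AAAATTATAATAAARGCRTGRGC", "reverse"),
        _p("ZBJ-ArtF1c", "AGATATTGGAACWTTATATTTTATTTTTGG", "forward"),
        _p("ZBJ-ArtR2c", "WACTAATCAATTWCCAAATCCTCC", "reverse"),
        _p("LepF1", "ATTCAACCAATCATAAAGATATTGG", "forward"),
        _p("mLepR1", "CCTGTTCCAGCTCCATTTT", "reverse"),
        _p("mlCOIintF", "GGWACWGGWTGAACWGTWTAYCCYCC", "forward"),
        _p("jgHCO2198", "TAIACYTCIGGRTGICCRAARAAYCA", "reverse"),
        _p("Sauron-S878", "GGDRCWGGWTGAACWGTWTAYCCNCC", "forward"),
        _p("Sauron-Tail-S879",
           "cacctgcttctaaatGGDRCWGGWTGAACWGTWTAYCCNCC", "forward", "tail1"),
        _p("jgHCO2198-Tail-A867",
           "cacttcgactctttacTANACYTCNGGRTGNCCRAARAAYCA", "reverse", "tail1"),
    ]
}

#: The locus-specific subset used for coverage evaluation.
LOCUS_PANEL: tuple[str, ...] = tuple(
    name for name, p in BUILTIN_PANEL.items() if p.role == "locus"
)


def get_primer(name: str) -> DegeneratePrimer:
    """Look up a primer in the built-in panel by name."""
    try:
        return BUILTIN_PANEL[name]
    except KeyError:
        raise KeyError(
            f"unknown primer {name!r}; built-in panel: {sorted(BUILTIN_PANEL)}"
        ) from None


def load_panel(path: str | Path) -> list[DegeneratePrimer]:
    """Read a primer panel from TSV or FASTA.

    TSV columns: ``name``, ``sequence``, ``orientation`` (forward/reverse)
    and optionally ``role``.  FASTA records use an id suffix convention:
    ``>name|forward`` or ``>name|reverse`` (default forward).  A lowercase
    5′ prefix in either format is recorded as the universal-tail annotation.
    """
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        primers = []
        for rec in SeqIO.parse(str(path), "fasta"):
            name, _, orient = rec.id.partition("|")
            primers.append(
                DegeneratePrimer(
                    name=name,
                    sequence=str(rec.seq),
                    orientation=orient or "forward",
                )
            )
        return primers
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "sequence", "orientation"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"primer panel {path}: TSV must have columns {sorted(required)}"
            )
        return [
            DegeneratePrimer(
                name=row["name"],
                sequence=row["sequence"],
                orientation=row["orientation"],
                role=row.get("role") or "locus",
            )
            for row in reader
        ]
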