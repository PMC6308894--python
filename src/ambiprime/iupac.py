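"""Nucleotide-set algebra for IUPAC-degenerate sequences.

A degenerate primer written with IUPAC ambiguity codes denotes a pool of
plain A/C/G/T oligonucleotides.  Every higher-level operation in this
package — zoned mismatch counting, binding-site scanning, consensus primer
design — reduces to set logic on the base sets behind each symbol, which is
what this module provides: symbol → base-set lookup, pool expansion and
counting, reverse complementation, and the primer-vs-template match
predicate.

Inosine (``I``) is treated as a universal base matching all four
nucleotides.  ``U`` is accepted on input and normalized to ``T``.  All
parsing is case-insensitive.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

__all__ = [
    "IUPAC_SETS",
    "SYMBOL_FOR_SET",
    "nt_set",
    "expand",
    "degeneracy",
    "complement_symbol",
    "revcomp",
    "symbols_match",
]

#: Base set behind each IUPAC symbol.  ``I`` (inosine) pairs with all four
#: bases by the universal-base convention.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "I": frozenset("ACGT"),
}

#: Canonical symbol for each base set.  ``{A,C,G,T}`` maps to ``N`` (not
#: ``I``), so re-encoding a set always yields a standard ambiguity code.
SYMBOL_FOR_SET: dict[frozenset[str], str] = {
    bases: sym for sym, bases in IUPAC_SETS.items() if sym != "I"
}

_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class InvalidSymbolError(ValueError):
    """Raised when a character is not a recognised IUPAC nucleotide code."""


def _normalize(symbol: str) -> str:
    s = symbol.upper()
    return "T" if s == "U" else s


def nt_set(symbol: str, position: int | None = None) -> frozenset[str]:
    """Return the base set for one IUPAC symbol (case-insensitive).

    Parameters
    ----------
    symbol
        A single character from the IUPAC nucleotide alphabet (``U`` is
        normalized to ``T``).
    position
        Optional 0-based position used only to improve the error message
        when the symbol is invalid.

    Raises
    ------
    InvalidSymbolError
        If *symbol* is not a recognised code.
    """
    s = _normalize(symbol)
    try:
        return IUPAC_SETS[s]
    except KeyError:
        ctx = "" if position is None else f" at position {position}"
        raise InvalidSymbolError(
            f"invalid IUPAC nucleotide symbol {symbol!r}{ctx}"
        ) from None


def _validate(sequence: str) -> str:
    """Uppercase, U→T, and check every character; returns the normal form."""
    out = []
    for i, ch in enumerate(sequence):
        s = _normalize(ch)
        if s not in IUPAC_SETS:
            raise InvalidSymbolError(
                f"invalid IUPAC nucleotide symbol {ch!r} at position {i}"
            )
        out.append(s)
    return "".join(out)


def degeneracy(sequence: str) -> int:
    """Number of distinct plain sequences the degenerate *sequence* encodes.

    The product over positions of the base-set sizes; equals
    ``len(expand(sequence))`` whenever expansion is feasible.
    """
    n = 1
    for i, ch in enumerate(sequence):
        n *= len(nt_set(ch, i))
    return n


def expand(sequence: str, cap: int = 10**6) -> set[str]:
    """Enumerate all plain A/C/G/T realizations of a degenerate sequence.

    Raises
    ------
    ValueError
        If the degeneracy exceeds *cap* (default one million); use
        :func:`degeneracy` to count without enumerating.
    """
    seq = _validate(sequence)
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds the expansion cap {cap}; "
            "use degeneracy() to count variants without enumerating them"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


@lru_cache(maxsize=None)
def complement_symbol(symbol: str) -> str:
    """Symbol whose base set is the Watson–Crick complement of *symbol*'s.

    Note that inosine complements to ``N`` (the canonical symbol for
    {A,C,G,T}); every other symbol round-trips exactly.
    """
    bases = nt_set(symbol)
    comp = frozenset(_COMPLEMENT_BASE[b] for b in bases)
    return SYMBOL_FOR_SET[comp]


def revcomp(sequence: str) -> str:
    """Reverse complement of a degenerate sequence (5′→3′ in, 5′→3′ out)."""
    seq = _validate(sequence)
    return "".join(complement_symbol(ch) for ch in reversed(seq))


@lru_cache(maxsize=None)
def symbols_match(
    primer_symbol: str, template_symbol: str, mode: str = "intersection"
) -> bool:
    """Does a primer symbol match a template symbol?

    ``intersection`` mode (default): true iff the two base sets share at
    least one base — the behaviour of ambiguity-aware pattern matching with
    both pattern and subject ambiguity honoured.  Under this mode a template
    ``N`` matches any primer symbol, which inflates coverage on reference
    records with undetermined stretches.

    ``subset`` mode: true iff the template's base set is contained in the
    primer's, i.e. *every* template variant is matched.  Stricter:
    subset ⇒ intersection for all symbol pairs.
    """
    p = nt_set(primer_symbol)
    t = nt_set(template_symbol)
    if mode == "intersection":
        return bool(p & t)
    if mode == "subset":
        return t <= p
    raise ValueError(f"unknown match mode {mode!r}; use 'intersection' or 'subset'")
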