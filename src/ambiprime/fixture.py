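"""Synthetic COI-like reference fixtures with known ground truth.

Real primer-coverage studies run against hundreds of thousands of curated
barcode sequences; desk-scale testing instead uses generated alignments in
which every primer's binding site is planted at a known offset and
per-class mismatches are injected under explicit rules.  Because each
record's site starts as an exact realization of the degenerate primer
(reverse primers: of its reverse complement) and every injected
substitution is chosen outside the primer's base set at that position, the
zoned mismatch profile of every (sequence, primer) pair is known *by
construction* and emitted as a machine-readable truth table — the oracle
against which the coverage pipeline is checked exactly.

The alignment is indel-free (COI is protein coding; the emulated reference
set aligns without indels at conserved priming sites) and the inter-site
backbone diverges from a shared ancestor at a configurable per-site
mutation rate, so located sites are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iupac import nt_set, revcomp
from .primers import THREE_PRIME_ZONE, DegeneratePrimer, get_primer
from .reference import ReferenceSet, SequenceRecord, SiteSpec

__all__ = [
    "PlantRule",
    "FixtureSpec",
    "FixtureData",
    "generate_fixture",
    "demo_spec",
]

_BASES = ("A", "C", "G", "T")

_CLASS_NAMES = (
    "Insecta",
    "Arachnida",
    "Mammalia",
    "Actinopterygii",
    "Aves",
    "Amphibia",
    "Gastropoda",
    "Malacostraca",
)


@dataclass(frozen=True)
class PlantRule:
    """Inject mismatches for a fraction of one class at one primer site.

    ``zone`` is ``"3prime"`` (the terminal 4-base zone) or ``"remainder"``;
    ``count`` substitutions are placed at eligible positions of the zone
    (positions where the primer symbol is not fully degenerate, so a
    guaranteed-mismatching base exists).
    """

    class_: str
    primer: str
    zone: str
    fraction: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.zone not in ("3prime", "remainder"):
            raise ValueError(f"zone must be '3prime' or 'remainder', got {self.zone!r}")
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"fraction must be in [0, 1], got {self.fraction}")
        if self.count < 1:
            raise ValueError("count must be at least 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic reference fixture.  Seed is mandatory."""

    seed: int
    n_classes: int = 4
    n_species_per_class: int = 15
    length: int = 400
    site_offsets: dict[str, int] = field(
        default_factory=lambda: {"Sauron-S878": 40, "jgHCO2198": 327}
    )
    rules: tuple[PlantRule, ...] = ()
    mutation_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.n_classes < 1 or self.n_species_per_class < 1:
            raise ValueError("need at least one class and one species per class")


@dataclass
class FixtureData:
    """A generated fixture: reference set, sites, and the truth table."""

    refset: ReferenceSet
    sites: dict[str, SiteSpec]
    truth: pd.DataFrame  # seq_id, primer, m3, m5
    spec: FixtureSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write fixture.fasta, taxonomy.tsv, truth.tsv and sites.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "fixture.fasta",
            "taxonomy": outdir / "taxonomy.tsv",
            "truth": outdir / "truth.tsv",
            "sites": outdir / "sites.json",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.refset:
                fh.write(f">{rec.seq_id}\n{rec.aligned}\n")
        self.refset.taxonomy_frame().to_csv(paths["taxonomy"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["sites"], "w") as fh:
            json.dump(
                {
                    name: {"start": s.start, "end": s.end, "strand": s.strand}
                    for name, s in sorted(self.sites.items())
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        return paths


def _plus_strand_motif(primer: DegeneratePrimer) -> str:
    seq = primer.locus_sequence
    return seq if primer.orientation == "forward" else revcomp(seq)


def _zone_columns(primer: DegeneratePrimer, offset: int, zone: str) -> list[int]:
    """Alignment columns of a primer zone, with the primer-position order.

    For a forward primer the 3′ zone occupies the *last* columns of the
    site; for a reverse primer (site = reverse complement on the plus
    strand) it occupies the first.
    """
    L = len(primer.locus_sequence)
    if zone == "3prime":
        pidx = range(L - THREE_PRIME_ZONE, L)
    else:
        pidx = range(0, L - THREE_PRIME_ZONE)
    if primer.orientation == "forward":
        return [offset + i for i in pidx]
    return [offset + (L - 1 - i) for i in pidx]


def _eligible_columns(primer: DegeneratePrimer, offset: int, zone: str) -> list[int]:
    """Zone columns where a guaranteed mismatch can be planted."""
    cols = []
    seq = primer.locus_sequence
    L = len(seq)
    for col in _zone_columns(primer, offset, zone):
        i = col - offset if primer.orientation == "forward" else L - 1 - (col - offset)
        if len(nt_set(seq[i])) < 4:  # fully degenerate positions match anything
            cols.append(col)
    return cols


def generate_fixture(
    spec: FixtureSpec,
    primers: dict[str, DegeneratePrimer] | None = None,
) -> FixtureData:
    """Generate a synthetic aligned reference set with exact truth.

    Deterministic: the same spec (seed included) yields byte-identical
    outputs.  Raises on overlapping primer sites or rules that ask for
    more substitutions than a zone has eligible positions.
    """
    if primers is None:
        primers = {name: get_primer(name) for name in spec.site_offsets}
    rng = np.random.default_rng(spec.seed)

    # validate site geometry
    intervals = []
    for name, off in sorted(spec.site_offsets.items()):
        L = len(primers[name].locus_sequence)
        if off < 0 or off + L > spec.length:
            raise ValueError(f"site for {name} at {off} does not fit in length {spec.length}")
        intervals.append((off, off + L, name))
    intervals.sort()
    for (s1, e1, n1), (s2, e2, n2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping sites: {n1} [{s1},{e1}) and {n2} [{s2},{e2})")
    site_cols = {c for s, e, _ in intervals for c in range(s, e)}

    backbone = "".join(rng.choice(_BASES, size=spec.length))
    class_names = [
        _CLASS_NAMES[i] if i < len(_CLASS_NAMES) else f"Class{i + 1:02d}"
        for i in range(spec.n_classes)
    ]

    records: list[SequenceRecord] = []
    tax_rows = []
    truth: dict[tuple[str, str], list[int]] = {}  # (seq_id, primer) -> [m3, m5]
    seqs_by_class: dict[str, list[int]] = {c: [] for c in class_names}
    seq_chars_all: list[list[str]] = []

    idx = 0
    for ci, cname in enumerate(class_names):
        for si in range(spec.n_species_per_class):
            seq_id = f"SYN{idx + 1:04d}"
            chars = list(backbone)
            # backbone divergence outside priming sites
            for j in range(spec.length):
                if j in site_cols:
                    continue
                if rng.random() < spec.mutation_rate:
                    alt = [b for b in _BASES if b != chars[j]]
                    chars[j] = alt[int(rng.integers(3))]
            # plant an exact realization of each primer at its site
            for name, off in sorted(spec.site_offsets.items()):
                motif = _plus_strand_motif(primers[name])
                for k, sym in enumerate(motif):
                    bases = sorted(nt_set(sym))
                    chars[off + k] = bases[int(rng.integers(len(bases)))]
                truth[(seq_id, name)] = [0, 0]
            seq_chars_all.append(chars)
            seqs_by_class[cname].append(idx)
            tax_rows.append(
                {
                    "seq_id": seq_id,
                    "species": f"Genus{ci + 1:02d} species{si + 1:02d}",
                    "order": f"Order{ci + 1:02d}",
                    "class": cname,
                }
            )
            idx += 1

    # inject rule mismatches: round(fraction * n) sequences of the class,
    # chosen deterministically from the seed; a column is never substituted
    # twice for the same (sequence, primer) so truth counts stay exact
    used_cols: dict[tuple[int, str], set[int]] = {}
    for rule in spec.rules:
        if rule.class_ not in seqs_by_class:
            raise ValueError(f"rule references unknown class {rule.class_!r}")
        if rule.primer not in spec.site_offsets:
            raise ValueError(f"rule references unplanted primer {rule.primer!r}")
        primer = primers[rule.primer]
        off = spec.site_offsets[rule.primer]
        eligible = _eligible_columns(primer, off, rule.zone)
        if rule.count > len(eligible):
            raise ValueError(
                f"rule for {rule.primer}/{rule.zone}: {rule.count} substitutions "
                f"requested but only {len(eligible)} positions can mismatch"
            )
        members = seqs_by_class[rule.class_]
        k = round(rule.fraction * len(members))
        chosen = sorted(rng.choice(members, size=k, replace=False))
        L = len(primer.locus_sequence)
        for m in chosen:
            taken = used_cols.setdefault((m, rule.primer), set())
            free = [c for c in eligible if c not in taken]
            if rule.count > len(free):
                raise ValueError(
                    f"rules for {rule.primer}/{rule.zone} exhaust the zone's "
                    f"plantable positions for sequence index {m}"
                )
            cols = sorted(rng.choice(free, size=rule.count, replace=False))
            taken.update(cols)
            chars = seq_chars_all[m]
            for col in cols:
                i = (
                    col - off
                    if primer.orientation == "forward"
                    else L - 1 - (col - off)
                )
                allowed = nt_set(primer.locus_sequence[i])
                # the planted base must mismatch the primer symbol; on the
                # plus strand that means complement(base) not in the set for
                # reverse primers
                if primer.orientation == "forward":
                    bad = sorted(set(_BASES) - set(allowed))
                else:
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    bad = sorted(b for b in _BASES if comp[b] not in allowed)
                chars[col] = bad[int(rng.integers(len(bad)))]
            seq_id = f"SYN{m + 1:04d}"
            zone_idx = 0 if rule.zone == "3prime" else 1
            truth[(seq_id, rule.primer)][zone_idx] += rule.count

    for i, row in enumerate(tax_rows):
        seq = "".join(seq_chars_all[i])
        records.append(
            SequenceRecord(
                seq_id=row["seq_id"],
                sequence=seq,
                species=row["species"],
                order=row["order"],
                class_=row["class"],
                aligned=seq,  # indel-free alignment
            )
        )

    sites = {
        name: SiteSpec(
            primer_name=name,
            start=off,
            end=off + len(primers[name].locus_sequence),
            strand="plus" if primers[name].orientation == "forward" else "minus",
        )
        for name, off in spec.site_offsets.items()
    }
    truth_df = pd.DataFrame(
        [
            {"seq_id": sid, "primer": pname, "m3": v[0], "m5": v[1]}
            for (sid, pname), v in sorted(truth.items())
        ]
    )
    refset = ReferenceSet(records, report={"synthetic": True, "seed": spec.seed})
    return FixtureData(refset=refset, sites=sites, truth=truth_df, spec=spec)


def demo_spec(seed: int = 42) -> FixtureSpec:
    """The demo fixture shipped with the repository.

    Four animal classes x 15 species, COI-like geometry: the forward
    primer site at columns 41-66 (1-based) and the reverse site placed so
    the predicted product is 313 bp including both footprints.  A quarter
    of Arachnida carry one 3'-zone mismatch against the forward primer,
    40% of Mammalia carry two remainder mismatches against the reverse
    primer, and 20% of Insecta carry one forward-remainder mismatch.
    """
    return FixtureSpec(
        seed=seed,
        n_classes=4,
        n_species_per_class=15,
        length=400,
        site_offsets={"Sauron-S878": 40, "jgHCO2198": 327},
        rules=(
            PlantRule("Arachnida", "Sauron-S878", "3prime", 0.25, 1),
            PlantRule("Mammalia", "jgHCO2198", "remainder", 0.4, 2),
            PlantRule("Insecta", "Sauron-S878", "remainder", 0.2, 1),
        ),
    )
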