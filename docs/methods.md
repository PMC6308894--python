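# Methods

This note documents the models, conventions, defaults and known limits of
`ambiprime`, module by module.

## IUPAC set algebra (`ambiprime.iupac`)

Every symbol maps to its standard base set; inosine `I` is modeled as a
universal base matching {A,C,G,T}, since tailed variants of
inosine-containing primers conventionally substitute `N` for `I` and
inosine pairs with all four bases. `U` normalizes to `T`; parsing is
case-insensitive and lowercase in primer inputs is preserved only as the
5′ universal-tail annotation, never affecting matching.

Two match predicates are provided. **Intersection** (default): primer and
template symbols match iff their base sets share a base — the behavior of
ambiguity-aware pattern matching with ambiguity honored on both sides.
**Subset**: the template set must be contained in the primer set. The
difference only matters for ambiguous template characters: under
intersection a template `N` matches every primer symbol, which inflates
coverage on records with undetermined stretches; subset mode is the
conservative alternative. Both are exposed and every report records which
was used, because reference databases do not state how their ambiguity
codes should be read.

Reverse complementation maps each symbol to the symbol whose base set is
the complement of the original set. It is an involution on the canonical
15-symbol alphabet; `I` maps one-way to `N` (both denote {A,C,G,T}, and
`N` is the canonical spelling of that set).

## Reference handling (`ambiprime.reference`)

Dereplication keeps one record per species — the longest, ties broken by
lexicographically smallest id — so primer-fit statistics are not biased
toward heavily sequenced species. The species key is the
whitespace-normalized, case-folded species string; "Genus sp." entries
are kept as distinct keys by default (a flag drops them), since merging
or dropping them silently would change denominators.

A record **covers** a priming site only if the degapped site window is
exactly primer length, gap-free and within the IUPAC alphabet. COI is
protein coding, so indel-free priming sites are the biological norm;
records that overlap a site partially, or with an internal indel, cannot
be scored position-by-position and are excluded from denominators with a
reason code (`terminal_gap`, `internal_indel`, `length_mismatch`,
`invalid_character`) rather than being guessed at. This makes per-primer
denominators mean "sequences on which this primer can be evaluated",
which is also why each primer is evaluated independently rather than
restricting to sequences spanning both sites of a pair.

Site location scans every window of exactly L alignment columns and
returns the window maximizing the mean fraction of matching positions
over records whose window is gap-free (ties: leftmost; reverse primers
are located via their reverse complement). Windows wider than L columns
(gap columns inside the site) are not searched: on gappy alignments the
L-column scan still ranks the site region first because partial windows
are excluded from each window's mean, but heavily gapped priming regions
would need a realigned input. For speed the mean is taken over a seeded
random subsample (default 1,000 records); passing `subsample=None` gives
the exact mode. Internal coordinates are 0-based half-open; reports for
humans print 1-based inclusive, and BED output is 0-based half-open as
the format requires.

## Coverage evaluation (`ambiprime.coverage`)

The zoned counts compare primer and site index-to-index (no alignment
inside the site — excluded by the coverage contract above). The 3′ zone
is fixed at 4 bases by default but exposed as a parameter so the grid
logic is testable at other widths; the remainder axis always spans
0–4 maxima. Because positions are independent, per-position set-logic
counting equals the minimum zoned mismatch count over all literal
expansions of the primer; the test suite enforces this equivalence
against a brute-force oracle for every built-in locus primer.

Zero-denominator proportions are undefined and serialize as nulls, never
as 0, to avoid silently deflating coverage. Group tables satisfy the
conservation property that the overall proportion equals the
covering-count-weighted mean of class proportions.

`compare_primer_success` fits a logistic model of per-sequence success on
primer identity (statsmodels GLM), reporting log-odds contrasts against a
stated reference primer with Wald p-values, Holm-adjusted p-values across
contrasts, and a Fisher exact p-value per contrast. Complete separation
(a primer with all-identical outcomes) is detected and flagged; the exact
p-values are then authoritative. The comparison operates on per-sequence
binary outcomes (not per-class proportions), which weights classes by
their sequence counts.

## Primer design (`ambiprime.design`)

Column profiles count plain A/C/G/T at each site position over covering
sequences; ambiguous template characters are excluded from the
frequencies but tallied. `propose_degenerate_primer` includes every base
with frequency ≥ `f_min` (default 0.05 — low enough to pick up
systematic minor variants, high enough to ignore sequencing noise; no
published threshold exists for this step, so the default is this
package's choice) and encodes each column as the smallest IUPAC symbol
containing exactly the included set. If total degeneracy would exceed
`max_degeneracy` (default 1024, which admits the built-in 768-variant
forward primer), pruning is greedy and deterministic: columns in
ascending Shannon entropy (ties by 5′ position) lose their
lowest-frequency included base until the cap holds, and every step is
logged in the result. Lowering `f_min` never decreases coverage or
degeneracy; at `f_min → 0⁺` the proposed primer matches every indel-free
covering input exactly.

The universal-tail check operationalizes "poor fit everywhere" as
ungapped sliding sequence identity — both strands, every offset, every
record — with a FAIL above 0.85 identity by default. Thermodynamic
melting-temperature modeling is deliberately out of scope; identity is
the auditable proxy for annealing potential at this level.

## Amplicon prediction (`ambiprime.amplicon`)

Naive O(n·L) scanning of both strands under the same zoned counting as
the coverage module (one shared implementation); all qualifying windows
are returned. Amplicons pair plus-strand forward sites with downstream
minus-strand reverse sites (plus the strand-swapped configuration), with
non-overlapping footprints and length within [50, 2000] by default.
**Length includes both primer footprints** — the convention under which
the built-in pair's product is 313 bp — and output metadata states this
rather than leaving it implicit. Predictions on a reverse-complemented
template yield the same multiset of lengths.

## Detection simulator (`ambiprime.simulate`)

The simulated experiment mirrors a mock-community validation design:
a full factorial of extract sets × balance levels × replicates (3 × 2 × 3
= 18 libraries in the emulated design), communities of 85 extracts with
lognormal concentrations (median 2.5, log-sd 1.2 — spanning roughly two
orders of magnitude, like uncurated DNA extracts), balanced pooling that
caps concentrations at 5 units and leaves lower ones unaltered (low
concentrations cannot be measured precisely enough to adjust upward), 35
PCR cycles, and sequencing depths drawn log-uniformly from
10,000–55,000 — the span of quality-filtered per-library read counts in
the kind of MiSeq runs being emulated.

Two components are this package's own simplifications, parameterized in
one config block:

* **Efficiency model** `e = e_max · δ₃^m3 · δ₅^m5` with defaults
  e_max = 0.95, δ₃ = 0.3, δ₅ = 0.8: a 3′-zone mismatch is far more
  damaging per unit than a remainder mismatch, which is the qualitative
  behavior that motivates zoned evaluation. The defaults encode "one
  3′-zone mismatch roughly cripples amplification; remainder mismatches
  erode it" and are not calibrated to any measured polymerase kinetics.
* **Sequencing** is a single multinomial draw of `depth` reads over
  post-PCR proportions `wᵢ ∝ cᵢ(1+eᵢ)^cycles` (computed in log space).
  This captures finite-depth sampling of rare templates but not chimeras,
  index hopping, tag jumps, polymerase error, or read-quality filtering.

Randomness: one root seed per experiment; per-library seeds derive by
SHA-256 hashing of (library id, root seed), truncated below 2³¹; every
run records its seed. With equal efficiencies and r_min = 1 the chain
collapses to the closed form P(detect) = 1 − (1 − p)^depth, which the
tests verify by Monte Carlo.

The detection GLM uses log relative concentration and log depth, with an
interaction by default (the covariate transform is not uniquely dictated
by the modeled experiment, so the formula choice is exposed and recorded
in output). Covariates are centered at their sample means so main effects
are interpretable at a typical observation even with the interaction
present; the centering constants are stored in the fit and applied in
prediction. McFadden's R² = 1 − ℓ/ℓ₀. Complete separation falls back to a
ridge-penalized fit, flagged as such. Units on concentrations are carried
as configured and never interpreted: only relative concentrations enter
the model.

## Fixture generator (`ambiprime.fixture`)

Fixtures plant, per record, an exact random realization of each primer at
its declared offset (reverse primers: of the reverse complement), mutate
the inter-site backbone at rate 0.05 from a shared ancestor, and inject
rule-driven substitutions chosen from bases *outside* the primer's set at
that position, so every (sequence, primer) zoned profile is known by
construction and emitted as a truth table. The alignment is indel-free
and every record covers every site. What passing tests on fixtures shows:
the counting, grouping and design machinery is exact. What it does not
show: behavior on real alignments with gapped or partially covered sites,
biased taxon sampling, or sequencing artifacts — those enter only through
the reason-coded coverage contract and must be judged on real data.
The demo fixture (seed 42, 4 classes × 15 species, planted class-specific
mismatch rules) ships in `examples/data/demo/` and regenerates
byte-identically from `ambiprime.fixture.demo_spec()`.

## Problem sizes in the test and acceptance runs

The suite runs at desk scale by design: oracle equivalence uses 1,000
random site strings per locus primer against full expansion enumeration
(≤ 2,048 variants); the detection closed form uses 10,000 replicates per
(proportion, depth) cell; parameter recovery fits 1,000 simulated
libraries of 30 members. Reproducing published-corpus coverage
percentages would require the full curated COI reference set (~170,000
species representatives), which is out of scope here; the pipeline is
built to accept such an input unchanged (aligned FASTA + taxonomy TSV).

## Known limitations

* No thermodynamics: neither melting temperatures, primer dimers, nor
  annealing-temperature spread within degenerate pools are modeled.
* Site location assumes priming sites align without internal gap columns;
  heavily gapped regions need curation upstream.
* The efficiency and sequencing abstractions are qualitative; absolute
  detection rates from the simulator should not be read as predictions
  for a specific lab protocol, only the direction and rough magnitude of
  concentration/depth effects.
* Taxonomy is taken at face value; no validation against external
  nomenclature databases.
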