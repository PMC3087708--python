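# Methods

## Problem setting

An arrayed RNAi feeding library assigns one bacterial clone per target gene;
each clone's insert was produced by PCR on genomic DNA with a designed primer
pair and is transcribed into dsRNA. The audit asks, clone by clone, whether
that primer pair — evaluated against a current genome and annotation — still
supports the claim on the well's label. Errors fall into four families:
annotation drift (retired gene ids), non-specific amplification, cross-RNAi
through sequence similarity, and physical mishandling (loading shifts, empty
vectors).

## Duplex thermodynamics

Melting temperatures use the nearest-neighbor model with the SantaLucia 1998
unified parameter set (ΔH, ΔS per dinucleotide stack plus initiation and
terminal penalties), the entropic monovalent-salt correction
ΔS' = ΔS + 0.368·N_stacks·ln[Na+], and Tm = 1000·ΔH/(ΔS' + R·ln(C_T/4)) −
273.15 for a non-self-complementary oligo with primer in excess. Defaults:
50 mM Na+, 250 nM primer. Parameter tables come from Biopython's
MeltingTemp collection; the summation is implemented here because the site
scanner needs a *mismatch-aware* duplex Tm: a partially matched site keeps
only the stacks between consecutive matched positions (mismatched positions
pair nothing), and terminal initiation penalties apply only to matched
termini. On perfectly matched input the result agrees with Biopython's
`Tm_NN` to numerical precision (asserted in tests).

The 3'-end stability rule sums the four stack ΔG37 values over each primer's
3'-terminal pentamer. This uses the Breslauer 1986 table by default rather
than the unified 1998 table: under unified-1998 ΔG37 values the most stable
possible 4-stack sum is −8.93 kcal/mol, so a −9 kcal/mol discard threshold
could never fire; under Breslauer 1986 GC-rich pentamers reach −13.1 and the
threshold separates exactly the over-stable 3' ends it is meant to catch.
Both tables are selectable via `ThermoParams`.

## Site discovery and amplicon enumeration

A primer binds productively where (i) its 3'-terminal word (default 4 nt)
matches the template exactly — polymerase extension does not tolerate
3'-terminal mismatches — and (ii) the mismatch-aware duplex Tm reaches the
50 °C floor (the library's PCR anneals at 58 °C). The scanner indexes seed
occurrences with string search and skips the Tm computation for candidate
sites with fewer than 10 matched bases: exhaustive enumeration over all
9-mers shows the maximum achievable Tm with ≤ 9 matched bases is 47.6 °C,
below the floor, so the shortcut cannot change the result (and the
brute-force equivalence test, which uses no shortcut, would catch it if it
did). Amplicons are all (forward-primer + strand site, reverse-primer −
strand site) pairs on one chromosome with positive product length up to
10 kb — the size cap doubles as the permissive-search setting — and with
pair coverage (mean matched fraction across the two primers) ≥ 0.3.

## Virtual gel

Fragment migration on 1 % agarose is modeled as
`mobility(L) = M0 · r(L)/r(L0)` with `r(L) = a + b·log10(L + c)`,
a = 4.61, b = −0.72, c = 474.65, calibrated through a marker band of
L0 = 2000 bp migrating M0 = 50 mm (a typical minigel lane; only distances,
never absolute migrations, enter any decision, so M0 simply scales the
resolution limit). The curve is positive and strictly decreasing over
50–10,000 bp with these constants. Two products co-migrate when their
predicted migrations differ by less than M_min = 2 mm, the smallest band
separation a naked eye resolves; co-migration groups are the connected
components of this relation, so chains of pairwise-close sizes merge into
one apparent band.

## Scoring

Each clone starts at 100 and the ledger records every deduction:

- 3'-end ΔG below −9 kcal/mol (either primer): score set to 0, evaluation
  stops (the pair is discarded).
- No amplicon surviving the filters: score 0.
- Each co-migrating group of ≥ 2 products: penalty `100 − similarity`,
  where similarity is 100× the mean pairwise global-alignment identity
  (match +1, mismatch −1, gap −2; identical inputs score exactly 100) of
  the product sequences, rounded half-up so scores stay integers.

The published rule discusses the similarity penalty for the homolog case
(similarity > 95); the same formula is applied smoothly below 95, which is
what gives unrelated co-migrating products their heavy penalties and
reproduces the yellow/red semantics. Products that are resolvable on the
gel carry no penalty: a verification gel would expose them. Primer-pair
quality flags (Tm ≤ 50 °C, ΔTm ≥ 3 °C) are reported but never scored, and
MULTI_TARGET is likewise unscored because homolog co-silencing can be
deliberate.

Categories are a function of the score — reliable ≥ 95, unreliable ≤ 10,
marginal between — with one override: a clone whose products hit no gene at
all (NO_TARGET) cannot be called reliable however clean its PCR, and a
would-be green call is capped at marginal. This mirrors the convention of
marking no-hit clones with an "R" on a yellow background and is the one
place category depends on anything but the score.

## Target mapping

The genes a product would silence are found by a seed-and-extend local
search against the unspliced gene sequences (both strands): exact 11-mer
seeds (the classic nucleotide-search word size), ungapped X-drop extension
(match +1, mismatch −1, drop 20), keeping per gene the best segment with
identity > 80 % over ≥ 200 nt — the established cross-RNAi threshold.
Ungapped extension is exact for the substitution-only divergence the
synthetic genomes contain and is cross-checked against an independent
alignment oracle (edlib) in the tests. Products shorter than 200 nt cannot
qualify and are flagged SHORT_AMPLICON.

Loading-shift forensics: given a sequencing-confirmed actual gene, the
library position annotated to that gene is looked up; same plate + same
column means a vertical (ROW) shift of `actual_row − expected_row` wells,
same row means a horizontal (COLUMN) shift, ties resolved toward the
smallest |offset|. Rows map A=1…P=16 on the 384-well geometry.

## Synthetic data generator

`generate_genome` packs random genes (default 600–1200 bp) separated by
short intergenic spacers (150–400 bp) onto chromosomes, with optional long
gene deserts for intergenic products, a deterministic fraction of ordinary
genes marked RETIRED, and two kinds of planted gene families built by
duplicating a gene and substituting interior positions while freezing the
first/last 60 bp: *paralog* pairs at high identity (default 0.96, i.e.
similarity ≈ 96 > 95) and *cross-hybridizing* pairs at low identity
(default 0.75). Family members are placed on different chromosomes so the
shared primers cannot form a locus-spanning product. Pair flanks are redrawn
until they admit a valid primer pair, since primers for both family members
must come from the frozen flanks.

`generate_library` lays clones column-major onto 384-well plates and injects
defects by class: SPECIFIC clones get uniquely amplifying pairs designed on
their own gene (validated by the package's own screen; genes whose designed
pair happens to hit a stray near-match site elsewhere are skipped — the
clean class must be clean); NONSPECIFIC clones take the shared flank primers
of a low-identity pair (two same-size co-migrating products of ~75 %
similarity → penalty ≈ 25 → marginal); HOMOLOG clones do the same on a
high-identity pair (penalty ≈ 4 → still reliable, MULTI_TARGET); INTERGENIC
clones amplify a single validated gene-free product inside a desert;
EMPTY_VECTOR clones get random primers verified to amplify nothing;
RETIRED_REMAPPED clones carry a retired annotation with primers for an alive
successor gene; LOADING_SHIFT clones sit a fixed offset (cycling through
ROW+2, ROW+4, COLUMN−2) from the well whose primers they actually carry.
Ground truth is emitted as a sidecar table. Primer design uses the
pipeline's own Tm/ΔG models (Tm 52–65 °C, ΔTm < 3 °C, ΔG ≥ −9) so defects
are never detectable from intrinsic primer quality alone.

What the generator does **not** emulate: repeat-rich genomic background,
GC-content bias, gapped divergence between homologs, partial/chimeric
inserts, or sequencing indels. Passing the recovery tests therefore shows
the pipeline's logic is correct under the stated defect models, not that
its thresholds are optimal for any real genome.

`simulate_sequencing` maps truth classes deterministically onto the
validation taxonomy (SPECIFIC/HOMOLOG → reliable; RETIRED_REMAPPED →
remapped-retired; LOADING_SHIFT → remapped-wrong-insert; NONSPECIFIC/
INTERGENIC/EMPTY_VECTOR → unreliable) and flips each outcome to a random
different one with probability `misread_rate`.

## Replacement primer design

For an alive gene ≥ 300 nt, candidate primers are enumerated on a sliding
grid over the gene (stride ≈ L/40, lengths 18–25 nt), kept when Tm ∈
[55, 65] °C and ΔG(3') ≥ −9, paired when |ΔTm| < 3 °C, ranked by |ΔTm| then
by product size nearest 1 kb (comfortable for both gel reading and dsRNA
synthesis — the ranking criteria are this package's own choice), and
validated in rank order by a genome-wide re-screen requiring exactly one
amplicon whose target list is exactly the input gene. Validation stops
after 200 candidate screens; a fully duplicated gene therefore correctly
yields zero candidates.

## Reporting

Percentages in summary tables and validation cross-tabs are computed on
exact integer counts with `Decimal` and rounded half-up to two decimals;
category percentages are of the library total, sequenced/remapped
percentages of their own category row, and the cross-tab Summary row is the
column-wise sum of the three category rows. Plate maps render the 16×24
grid with G/Y/R glyphs, an `R` suffix for clones needing re-annotation, a
tick/cross for sequencing-confirmed/refuted wells, and a middle dot for
empty wells.

## Problem sizes

The default test and acceptance configurations use 2–4 chromosome genomes
(~0.3 Mb total), 240-gene annotations, 20–200-clone libraries, and 200-draw
search-equivalence experiments on ~2.5 kb genomes; these sizes exercise
every code path and keep a full run in seconds on one CPU while remaining
large enough for the statistical recovery checks (20 clones per defect
class).

## Known limitations

- The mobility curve's algebraic form is an empirical semi-log law
  calibrated through one marker band; it is config-isolated so an
  alternative curve can be swapped in without touching callers.
- Pair-coverage is the mean matched fraction of the two primers — a simple,
  monotone stand-in for more elaborate coverage scores.
- Hairpin/self-dimer screening, degenerate bases and gapped local alignment
  statistics (E-values) are out of scope.
- `enumerate_amplicons` pairs forward-primer sites on + with reverse-primer
  sites on − only; single-primer products and swapped-orientation artifacts
  are not modeled.
- Loading-shift detection explains a sequencing surprise only by same-row or
  same-column geometry on the same plate; multi-plate swaps are not
  considered.
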