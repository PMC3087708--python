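# cloneaudit

Reliability auditing for arrayed RNAi feeding-library clones.

Genome-wide RNAi feeding libraries are collections of bacterial strains, one
per target gene, each carrying a plasmid with a genomic PCR fragment that is
transcribed into dsRNA. Because the libraries were built by high-throughput
PCR from primer pairs designed against an old genome annotation, individual
wells can be wrong in several ways: the annotated gene id has since been
retired, the primers amplify something other than (or in addition to) the
intended fragment, the product lies in an intergenic region, the vector is
empty, or the sample was physically loaded into the wrong well. `cloneaudit`
predicts, for every clone, which of these failure modes applies — before any
bench work — and condenses the evidence into a traffic-light reliability call.

## The method

For each clone (primer pair + annotated gene + plate position):

1. **In-silico PCR.** Every productive binding site of each primer is found on
   the genome: an exact match over the 3'-terminal word (w = 4) plus a
   nearest-neighbor duplex melting temperature ≥ 50 °C (SantaLucia 1998
   unified parameters, monovalent-salt correction, mismatched positions
   contribute no stacks). Forward/reverse site pairs within 10 kb whose
   pair coverage (mean fraction of matched primer bases) reaches 0.3 become
   predicted amplicons.
2. **3'-end stability.** The stack free energy ΔG of the last five bases of
   each primer is summed (Breslauer 1986 table); ΔG < −9 kcal/mol predicts
   promiscuous priming and zeroes the clone's score outright.
3. **Virtual gel.** Each amplicon's migration on a 1 % agarose gel is
   predicted from the semi-log mobility curve
   `r(L) = a + b·log10(L + c)` (a = 4.61, b = −0.72, c = 474.65), anchored to
   a 2000 bp marker band. Amplicons whose bands fall within M_min = 2 mm of
   each other co-migrate — they cannot be told apart by eye on the
   verification gel.
4. **Scoring.** The score starts at 100. Each co-migrating group of ≥ 2
   products costs `100 − similarity` points, where similarity is 100× the
   mean pairwise global-alignment identity of the product sequences, so
   homolog co-amplification (similarity > 95) is nearly free and unrelated
   co-migrating products are heavily punished. No surviving amplicon → 0.
   Categories: **score ≥ 95 reliable (green)**, **10 < score < 95 marginal
   (yellow)**, **score ≤ 10 unreliable (red)**.
5. **Target mapping.** Each product is searched (seed-and-extend, 11-mer
   seeds) against the unspliced gene set; hits with identity > 80 % over
   ≥ 200 nt are the genes the dsRNA would actually silence. A clone whose
   products miss its annotated gene is flagged **REMAPPED**; products hitting
   no gene give **NO_TARGET** (and cap the category at marginal); multiple
   distinct hits give **MULTI_TARGET**.
6. **Plate forensics.** When sequencing reveals a different gene than
   annotated, the position of that gene's own clone is checked: same plate and
   column a few rows away (or same row, columns away) indicates a sample
   loading error, reported with its axis and signed offset.

For marginal/unreliable clones, `primer_rescue` proposes up to five
replacement primer pairs per gene, each re-validated by the same screen to
produce exactly one product mapping only to that gene.

A seeded synthetic-data generator (`synthetic_data`) builds toy genomes with
paralog families, retired ids and gene deserts, and plated libraries with a
controlled mixture of all defect classes plus a ground-truth table, so the
whole pipeline is testable end to end without any downloads.

## Worked example

Simulate a 20-clone library with injected defects, audit it, and read the
plate map:

```
$ clone-audit simulate --spec sim.yaml --seed 4 --out sim/
wrote 20 clones over 2 chromosomes to sim

$ clone-audit run --genome sim/genome.fasta --genes sim/genes.gff3 \
      --clones sim/clones.tsv --out run/
$ head -3 run/evaluations.tsv
clone_name  location  score  category  flags         predicted_targets              n_amplicons
g0007       I-1A01    100    RELIABLE  REMAPPED      g0014:1.000:1107               1
xh01a       I-1A02    75     MARGINAL  MULTI_TARGET  xh01a:1.000:890,xh01b:1.000:890  2
```

`g0007` is a loading-shifted well: its PCR is clean (score 100) but the
product maps to `g0014`, not to its annotation, hence `REMAPPED`. `xh01a`
carries primers that amplify two loci of 75 % mutual identity; the two
same-size products co-migrate, costing `100 − 75 = 25` points and leaving the
clone marginal. The per-plate map shows the same calls as glyphs
(`G`/`Y`/`R` by category, `R`-suffix for clones needing re-annotation,
`·` for empty wells):

```
$ head -4 run/plates/I-1.txt
Plate I-1
      1  2  3  4 ...
  A  GR  Y  ·  · ...
  B  GR  G  ·  · ...
```

and `run/summary.tsv` aggregates the categories:

```
group       count  pct    remapped  remapped_pct
Reliable    18     90.0   4         22.22
Marginal    2      10.0   0         0.0
Unreliable  0      0.0    0         0.0
Total       20     100.0  4         20.0
```

`clone-audit rescue --gene g0001 --genome ... --genes ...` prints replacement
primer candidates with their melting temperatures and product sizes.

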