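"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive results by exhaustive scanning or
direct arithmetic, independent of the package's indexed/seeded search
paths, so that equivalence tests mean something.
"""

from __future__ import annotations

import math
import random

import pytest

from cloneaudit.insilico_pcr import (
    BindingSite,
    ThermoParams,
    _duplex_tm,
    reverse_complement,
)
from cloneaudit.io_formats import CloneRecord, GeneRecord, GenomeSequence, PlateLocation


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def mutate(rng: random.Random, seq: str, n_subs: int) -> str:
    """Apply exactly n distinct substitutions."""
    positions = rng.sample(range(len(seq)), n_subs)
    bases = list(seq)
    for p in positions:
        bases[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(bases)


def make_location(text: str = "I-1A01") -> PlateLocation:
    return PlateLocation.from_text(text)


def make_clone(fwd: str, rev: str, name: str = "c1", gene: str = "g1",
               loc: str = "I-1A01") -> CloneRecord:
    return CloneRecord(name, fwd, rev, gene, PlateLocation.from_text(loc))


# ---------------------------------------------------------------------------
# exhaustive in-silico PCR oracle: O(L * m) scan over every genome offset
# ---------------------------------------------------------------------------

def brute_force_sites(
    primer: str,
    genome: list[GenomeSequence],
    word_size: int = 4,
    min_duplex_tm: float = 50.0,
    thermo: ThermoParams = ThermoParams(),
    strands: str = "+-",
) -> list[BindingSite]:
    """Slide the primer over every offset of every strand; keep offsets
    whose 3'-terminal word matches exactly and whose mismatch-aware
    duplex Tm reaches the floor."""
    plen = len(primer)
    sites = []
    for chrom in genome:
        seq = chrom.sequence
        for start in range(len(seq) - plen + 1):
            window = seq[start : start + plen]
            if "+" in strands:
                if window[-word_size:] == primer[-word_size:]:
                    matched = [a == b for a, b in zip(primer, window)]
                    tm = _duplex_tm(primer, matched, thermo)
                    if tm >= min_duplex_tm:
                        sites.append(
                            BindingSite(chrom.chrom_id, "+", start, start + plen,
                                        sum(matched), tm)
                        )
            if "-" in strands:
                window_rc = reverse_complement(window)
                if window_rc[-word_size:] == primer[-word_size:]:
                    matched = [a == b for a, b in zip(primer, window_rc)]
                    tm = _duplex_tm(primer, matched, thermo)
                    if tm >= min_duplex_tm:
                        sites.append(
                            BindingSite(chrom.chrom_id, "-", start, start + plen,
                                        sum(matched), tm)
                        )
    return sites


def brute_force_amplicons(
    clone: CloneRecord,
    genome: list[GenomeSequence],
    max_amplicon_bp: int = 10_000,
    ppc_cutoff: float = 0.3,
    min_duplex_tm: float = 50.0,
    word_size: int = 4,
    thermo: ThermoParams = ThermoParams(),
) -> list[tuple[str, int, int]]:
    """All (chrom, start, end) products from pairing every brute-force
    forward +strand site with every reverse -strand site."""
    fwd = brute_force_sites(clone.fwd_primer, genome, word_size, min_duplex_tm,
                            thermo, strands="+")
    rev = brute_force_sites(clone.rev_primer, genome, word_size, min_duplex_tm,
                            thermo, strands="-")
    lf, lr = len(clone.fwd_primer), len(clone.rev_primer)
    out = []
    for f in fwd:
        for r in rev:
            if f.chrom_id != r.chrom_id:
                continue
            size = r.end - f.start
            if size <= 0 or size > max_amplicon_bp or size < lf + lr:
                continue
            ppc = ((f.matched_bases / lf) + (r.matched_bases / lr)) / 2.0
            if ppc < ppc_cutoff:
                continue
            out.append((f.chrom_id, f.start, r.end))
    return sorted(out)


# ---------------------------------------------------------------------------
# gel-model closed-form oracle (direct formula evaluation)
# ---------------------------------------------------------------------------

def oracle_mobility(size_bp: float, a: float = 4.61, b: float = -0.72,
                    c: float = 474.65, marker_bp: int = 2000,
                    marker_mm: float = 50.0) -> float:
    r = lambda L: a + b * math.log10(L + c)  # noqa: E731
    return marker_mm * r(size_bp) / r(marker_bp)


# ---------------------------------------------------------------------------
# shared small synthetic dataset (built once per session)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_dataset():
    """A 2-chromosome genome with paralog/cross pairs, deserts, retired
    genes, and a 20-clone library carrying one of each defect class."""
    from cloneaudit.synthetic_data import DefectSpec, generate_genome, generate_library

    genomes, genes = generate_genome(
        n_chrom=2, genes_per_chrom=15, n_paralog_pairs=2, n_crosshyb_pairs=2,
        retired_fraction=0.2, n_deserts_per_chrom=1, seed=5,
    )
    defects = DefectSpec(
        nonspecific_primers=0.1, intergenic_amplicon=0.1, empty_vector=0.1,
        retired_remapped=0.1, loading_shift=0.1, homolog_comigration=0.1,
    )
    clones, truth = generate_library(genomes, genes, defects, ["I-1"], seed=7,
                                     n_clones=20)
    return genomes, genes, clones, truth


@pytest.fixture(scope="session")
def small_evaluations(small_dataset):
    from cloneaudit.pipeline import evaluate_library

    genomes, genes, clones, truth = small_dataset
    return evaluate_library(clones, genomes, genes)
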