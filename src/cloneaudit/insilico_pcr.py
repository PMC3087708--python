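"""Desk-scale in-silico PCR specificity screen.

Finds every place a primer can productively anneal on a genome, computes
nearest-neighbor duplex melting temperatures and 3'-end stack stability,
and enumerates the PCR products a primer pair would make. The screen
follows classic in-silico PCR practice: a short 3'-terminal seed word
must match the template exactly (polymerase extension chemistry tolerates
5' mismatches far better than 3' ones), the annealed duplex must melt
above the PCR annealing regime, products are capped at a maximum length,
and weakly covered primer pairs are dropped by a pair-coverage cutoff.

Thermodynamics use published nearest-neighbor parameter sets (the
SantaLucia 1998 unified table by default for Tm; the Breslauer 1986 table
by default for 3'-end stack free energies, whose larger stack magnitudes
make the -9 kcal/mol instability rule attainable) with a monovalent-salt
entropy correction. Tables are taken from Biopython's MeltingTemp
parameter collection; the duplex model here extends them to partially
mismatched sites by letting only matched positions contribute stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from cloneaudit.io_formats import CloneRecord, GenomeSequence

_R_GAS = 1.987  # cal / (mol K)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NN_TABLES = {
    "unified_1998": _mt.DNA_NN3,
    "breslauer_1986": _mt.DNA_NN1,
}

# Flags for intrinsic primer-pair quality (reported, never scored).
TM_LOW_FWD = "TM_LOW_FWD"
TM_LOW_REV = "TM_LOW_REV"
TM_IMBALANCE = "TM_IMBALANCE"

# Tm over any duplex with <= 9 matched bases cannot reach 50 C under the
# parameter sets above (exhaustive 9-mer maximum is 47.6 C), so the site
# scanner may skip the Tm computation below this match count.
_MIN_MATCHES_FOR_TM = 10


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameterization of the duplex model.

    ``nn_table_id`` selects the nearest-neighbor table used for melting
    temperatures; ``dg_table_id`` the table used for 3'-end stack free
    energies. ``monovalent_mM`` is the Na+ concentration for the salt
    entropy correction and ``primer_conc_nM`` the total primer strand
    concentration (primer assumed in excess over template).
    """

    nn_table_id: str = "unified_1998"
    dg_table_id: str = "breslauer_1986"
    monovalent_mM: float = 50.0
    primer_conc_nM: float = 250.0

    def __post_init__(self) -> None:
        for table_id in (self.nn_table_id, self.dg_table_id):
            if table_id not in NN_TABLES:
                raise ValueError(f"unknown nearest-neighbor table {table_id!r}")
        if self.monovalent_mM <= 0 or self.primer_conc_nM <= 0:
            raise ValueError("concentrations must be positive")


DEFAULT_THERMO = ThermoParams()


@dataclass(frozen=True)
class BindingSite:
    """A primer annealing site on the genome.

    ``start``/``end`` delimit the template footprint (0-based half-open on
    the forward genome strand). ``strand`` is the strand the *primer
    sequence itself* matches: ``+`` sites prime rightward synthesis,
    ``-`` sites leftward.
    """

    chrom_id: str
    strand: str
    start: int
    end: int
    matched_bases: int
    duplex_tm: float


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product with its two generating binding sites."""

    chrom_id: str
    start: int
    end: int
    size: int
    fwd_site: BindingSite
    rev_site: BindingSite
    ppc: float


def _validate_primer(seq: str, min_len: int) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence shorter than {min_len} nt: {seq!r}")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def _stack_params(table: dict, dinuc: str) -> tuple[float, float]:
    comp = dinuc.translate(_COMPLEMENT)
    key = f"{dinuc}/{comp}"
    if key not in table:
        key = f"{comp[::-1]}/{dinuc[::-1]}"
    return table[key]


def _duplex_tm(seq: str, matched: Sequence[bool], thermo: ThermoParams) -> float:
    """NN melting temperature of a (possibly mismatched) primer-template
    duplex. Mismatched positions contribute no stack terms; terminal
    initiation penalties apply only when the terminal base is paired."""
    table = NN_TABLES[thermo.nn_table_id]
    dh, ds = table["init"]
    k = "init_allA/T" if set(seq) <= set("AT") else "init_oneG/C"
    dh2, ds2 = table[k]
    dh, ds = dh + dh2, ds + ds2
    for idx in (0, len(seq) - 1):
        if matched[idx]:
            k = "init_A/T" if seq[idx] in "AT" else "init_G/C"
            dh2, ds2 = table[k]
            dh, ds = dh + dh2, ds + ds2
    n_stacks = 0
    for i in range(len(seq) - 1):
        if matched[i] and matched[i + 1]:
            dh2, ds2 = _stack_params(table, seq[i : i + 2])
            dh, ds = dh + dh2, ds + ds2
            n_stacks += 1
    if n_stacks == 0:
        return -math.inf
    ds += 0.368 * n_stacks * math.log(thermo.monovalent_mM / 1000.0)
    ct = thermo.primer_conc_nM * 1e-9
    denom = ds + _R_GAS * math.log(ct / 4.0)
    if denom >= 0 or dh >= 0:
        return -math.inf
    return 1000.0 * dh / denom - 273.15


def tm_nn(sequence: str, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Nearest-neighbor melting temperature (degrees C) of a perfectly
    matched duplex, with SantaLucia salt correction and the CT/4
    concentration term for a non-self-complementary oligo in excess."""
    _validate_primer(sequence, 8)
    return _duplex_tm(sequence, [True] * len(sequence), thermo)


def dg_3prime_end(primer: str, thermo: ThermoParams = DEFAULT_THERMO) -> float:
    """Free energy (kcal/mol, 37 C) of the four nearest-neighbor stacks
    over the 3'-terminal pentamer of ``primer``.

    Strongly negative values mark an over-stable 3' end that anneals
    promiscuously; values below -9 kcal/mol trigger the discard rule in
    the scoring module.
    """
    _validate_primer(primer, 5)
    table = NN_TABLES[thermo.dg_table_id]
    pent = primer[-5:]
    total = 0.0
    for i in range(4):
        dh, ds = _stack_params(table, pent[i : i + 2])
        total += dh - 310.15 * ds / 1000.0
    return total


def find_binding_sites(
    primer: str,
    genome: Iterable[GenomeSequence] | GenomeSequence,
    word_size: int = 4,
    min_duplex_tm: float = 50.0,
    thermo: ThermoParams = DEFAULT_THERMO,
    strands: str = "+-",
) -> list[BindingSite]:
    """All sites where ``primer`` can productively anneal.

    A site requires an exact match over the 3'-terminal ``word_size``
    bases (the seed) and a mismatch-aware duplex Tm of at least
    ``min_duplex_tm``; mismatches 5' of the seed are permitted.
    """
    _validate_primer(primer, max(word_size, 1))
    if word_size > len(primer):
        raise ValueError("word_size exceeds primer length")
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    plen = len(primer)
    sites: list[BindingSite] = []
    for chrom in genome:
        seq = chrom.sequence
        if "+" in strands:
            seed = primer[-word_size:]
            pos = seq.find(seed, plen - word_size)
            while pos != -1:
                start = pos + word_size - plen
                footprint = seq[start : start + plen]
                matched = sum(a == b for a, b in zip(primer, footprint))
                if matched >= _MIN_MATCHES_FOR_TM:
                    flags = [a == b for a, b in zip(primer, footprint)]
                    tm = _duplex_tm(primer, flags, thermo)
                    if tm >= min_duplex_tm:
                        sites.append(
                            BindingSite(chrom.chrom_id, "+", start, start + plen, matched, tm)
                        )
                pos = seq.find(seed, pos + 1)
        if "-" in strands:
            seed_rc = reverse_complement(primer[-word_size:])
            pos = seq.find(seed_rc)
            while pos != -1:
                start, end = pos, pos + plen
                if end <= len(seq):
                    footprint_rc = reverse_complement(seq[start:end])
                    matched = sum(a == b for a, b in zip(primer, footprint_rc))
                    if matched >= _MIN_MATCHES_FOR_TM:
                        flags = [a == b for a, b in zip(primer, footprint_rc)]
                        tm = _duplex_tm(primer, flags, thermo)
                        if tm >= min_duplex_tm:
                            sites.append(
                                BindingSite(chrom.chrom_id, "-", start, end, matched, tm)
                            )
                pos = seq.find(seed_rc, pos + 1)
    sites.sort(key=lambda s: (s.chrom_id, s.start, s.strand))
    return sites


def enumerate_amplicons(
    clone: CloneRecord,
    genome: Iterable[GenomeSequence] | GenomeSequence,
    max_amplicon_bp: int = 10_000,
    ppc_cutoff: float = 0.3,
    min_duplex_tm: float = 50.0,
    word_size: int = 4,
    thermo: ThermoParams = DEFAULT_THERMO,
) -> list[Amplicon]:
    """Every PCR product the clone's primer pair would make on ``genome``.

    Pairs each forward-primer site on the + strand with each
    reverse-primer site on the - strand of the same chromosome, keeping
    products of positive length up to ``max_amplicon_bp`` whose
    pair-coverage (mean fraction of matched primer bases) reaches
    ``ppc_cutoff``. Results are sorted by (chrom, start, end).
    """
    if isinstance(genome, GenomeSequence):
        genome = [genome]
    genome = list(genome)
    fwd_sites = find_binding_sites(
        clone.fwd_primer, genome, word_size, min_duplex_tm, thermo, strands="+"
    )
    rev_sites = find_binding_sites(
        clone.rev_primer, genome, word_size, min_duplex_tm, thermo, strands="-"
    )
    lf, lr = len(clone.fwd_primer), len(clone.rev_primer)
    amplicons: list[Amplicon] = []
    by_chrom: dict[str, list[BindingSite]] = {}
    for site in rev_sites:
        by_chrom.setdefault(site.chrom_id, []).append(site)
    for f in fwd_sites:
        for r in by_chrom.get(f.chrom_id, ()):
            size = r.end - f.start
            if size <= 0 or size > max_amplicon_bp or size < lf + lr:
                continue
            ppc = ((f.matched_bases / lf) + (r.matched_bases / lr)) / 2.0
            if ppc < ppc_cutoff:
                continue
            amplicons.append(Amplicon(f.chrom_id, f.start, r.end, size, f, r, ppc))
    amplicons.sort(key=lambda a: (a.chrom_id, a.start, a.end))
    return amplicons


def amplicon_sequence(amplicon: Amplicon, genome: Iterable[GenomeSequence]) -> str:
    """Forward-strand sequence of a predicted product."""
    for chrom in genome:
        if chrom.chrom_id == amplicon.chrom_id:
            return chrom.sequence[amplicon.start : amplicon.end]
    raise ValueError(f"chromosome {amplicon.chrom_id!r} not in genome")


def primer_pair_flags(
    clone: CloneRecord, thermo: ThermoParams = DEFAULT_THERMO
) -> set[str]:
    """Intrinsic primer-pair quality flags.

    An efficient pair has both Tm above 50 C and a Tm difference below
    3 C. Violations are flagged for reporting but carry no score penalty.
    """
    tm_f = tm_nn(clone.fwd_primer, thermo)
    tm_r = tm_nn(clone.rev_primer, thermo)
    flags: set[str] = set()
    if tm_f <= 50.0:
        flags.add(TM_LOW_FWD)
    if tm_r <= 50.0:
        flags.add(TM_LOW_REV)
    if abs(tm_f - tm_r) >= 3.0:
        flags.add(TM_IMBALANCE)
    return flags
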