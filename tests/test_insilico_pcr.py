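"""Nearest-neighbor thermodynamics and the in-silico PCR screen."""

import random

import pytest
from Bio.SeqUtils import MeltingTemp as mt
from hypothesis import given, settings, strategies as st

from conftest import brute_force_amplicons, brute_force_sites, make_clone, mutate, random_dna
from cloneaudit.insilico_pcr import (
    TM_IMBALANCE,
    TM_LOW_FWD,
    TM_LOW_REV,
    ThermoParams,
    amplicon_sequence,
    dg_3prime_end,
    enumerate_amplicons,
    find_binding_sites,
    primer_pair_flags,
    reverse_complement,
    tm_nn,
)
from cloneaudit.io_formats import GenomeSequence

dna = st.text(alphabet="ACGT", min_size=12, max_size=30)


class TestTmNN:
    def test_frozen_reference_value(self):
        # independent hand summation of the unified-1998 table (via the
        # published parameter collection) for a 20-mer at 50 mM Na+/250 nM
        assert tm_nn("ACGTACGTACGTACGTACGT") == pytest.approx(55.2220, abs=1e-3)

    @given(seq=dna)
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_biopython_on_perfect_duplexes(self, seq):
        # Biopython's Tm_NN with k = CT/4 is an independent summation of
        # the same published table
        expected = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=62.5,
                            dnac2=0, saltcorr=5)
        assert tm_nn(seq) == pytest.approx(expected, abs=1e-6)

    @given(seq=dna)
    @settings(max_examples=30, deadline=None)
    def test_symmetric_under_reverse_complement(self, seq):
        assert tm_nn(seq) == pytest.approx(tm_nn(reverse_complement(seq)), abs=1e-9)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tm_nn("ACGTXCGTACGT")
        with pytest.raises(ValueError):
            tm_nn("ACGTACG")  # < 8 nt


class TestDg3PrimeEnd:
    # oracle values: hand sums of 4 stack dG37 = dH - 310.15*dS/1000 terms
    @pytest.mark.parametrize("primer,table,expected", [
        ("ACGTACGTACGTACGGCGCC", "breslauer_1986", -11.6658),
        ("ACGTACGTACGTACGAATAA", "breslauer_1986", -5.2587),
        ("ACGTACGTACGTACGAATAA", "unified_1998", -3.4961),
        ("ACGTACGTACGTACGGCGCG", "breslauer_1986", -12.1937),
        ("ACGTACGTACGTACGGCGCG", "unified_1998", -8.7925),
    ])
    def test_frozen_pentamer_sums(self, primer, table, expected):
        thermo = ThermoParams(dg_table_id=table)
        assert dg_3prime_end(primer, thermo) == pytest.approx(expected, abs=1e-3)

    def test_gc_rich_end_breaches_discard_threshold_under_breslauer(self):
        # the maximally stable stacks give < -9 kcal/mol, arming the rule
        assert dg_3prime_end("ACGTACGTACGTACGGCGCG") < -9.0
        # AT-rich ends stay clear of it under both tables
        for table in ("breslauer_1986", "unified_1998"):
            assert dg_3prime_end("ACGTACGTACGTACGAATAA",
                                 ThermoParams(dg_table_id=table)) > -9.0

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            dg_3prime_end("ACGT")


class TestFindBindingSites:
    def test_perfect_unique_match(self):
        rng = random.Random(0)
        primer = "GCCTAGGCTTAAGGCCTAGG"
        genome = [GenomeSequence("c", random_dna(rng, 500) + primer + random_dna(rng, 500))]
        sites = find_binding_sites(primer, genome)
        plus = [s for s in sites if s.strand == "+"]
        assert len(plus) == 1
        assert plus[0].matched_bases == len(primer)
        assert (plus[0].start, plus[0].end) == (500, 520)

    def test_absent_seed_word_means_no_sites(self):
        genome = [GenomeSequence("c", "AT" * 300)]
        assert find_binding_sites("GCGCGCGCGCGCGCGCCGGC", genome) == []

    def test_single_5prime_mismatch_still_binds(self):
        rng = random.Random(1)
        primer = "GCCTAGGCTTAAGGCCTAGG"
        template = "T" + primer[1:]  # mismatch only at the primer's 5' base
        genome = [GenomeSequence("c", random_dna(rng, 300) + template + random_dna(rng, 300))]
        sites = [s for s in find_binding_sites(primer, genome) if s.strand == "+"]
        assert len(sites) == 1
        assert sites[0].matched_bases == len(primer) - 1

    def test_3prime_terminal_mismatch_abolishes_site(self):
        rng = random.Random(2)
        primer = "GCCTAGGCTTAAGGCCTAGG"
        template = primer[:-1] + "A"  # breaks the seed's terminal base
        genome = [GenomeSequence("c", random_dna(rng, 300) + template + random_dna(rng, 300))]
        assert all(
            s.start != 300 for s in find_binding_sites(primer, genome)
            if s.strand == "+"
        )


def _planted_genome(rng: random.Random, primers: list[str], length: int = 3000):
    """Random genome with exact, 1-mismatch and reverse-complement copies
    of each primer planted at random offsets."""
    seq = list(random_dna(rng, length))
    for primer in primers:
        for variant in (primer, mutate(rng, primer, 1),
                        reverse_complement(primer),
                        reverse_complement(mutate(rng, primer, 2))):
            pos = rng.randrange(0, length - len(variant))
            seq[pos : pos + len(variant)] = variant
    return [GenomeSequence("c", "".join(seq))]


class TestOracleEquivalence:
    def test_sites_match_exhaustive_scan(self):
        rng = random.Random(42)
        for _ in range(25):
            primer = random_dna(rng, rng.randint(15, 24))
            genome = _planted_genome(rng, [primer])
            fast = find_binding_sites(primer, genome)
            slow = brute_force_sites(primer, genome)
            assert sorted((s.strand, s.start, s.matched_bases) for s in fast) == \
                   sorted((s.strand, s.start, s.matched_bases) for s in slow)

    def test_amplicons_match_exhaustive_pairing(self):
        rng = random.Random(43)
        for _ in range(15):
            fwd = random_dna(rng, rng.randint(16, 22))
            rev = random_dna(rng, rng.randint(16, 22))
            genome = _planted_genome(rng, [fwd, rev])
            clone = make_clone(fwd, rev)
            fast = [(a.chrom_id, a.start, a.end) for a in enumerate_amplicons(clone, genome)]
            assert fast == brute_force_amplicons(clone, genome)

    def test_raising_thresholds_never_adds_amplicons(self):
        rng = random.Random(44)
        fwd, rev = random_dna(rng, 20), random_dna(rng, 20)
        genome = _planted_genome(rng, [fwd, rev], length=5000)
        clone = make_clone(fwd, rev)
        base = {(a.start, a.end) for a in enumerate_amplicons(clone, genome)}
        for min_tm, ppc in ((55.0, 0.3), (50.0, 0.6), (60.0, 0.9)):
            tighter = {
                (a.start, a.end)
                for a in enumerate_amplicons(clone, genome, min_duplex_tm=min_tm,
                                             ppc_cutoff=ppc)
            }
            assert tighter <= base


class TestEnumerateAmplicons:
    def _flanking_genome(self, rng, fwd, rev, insert_len):
        insert = random_dna(rng, insert_len)
        core = fwd + insert + reverse_complement(rev)
        return GenomeSequence("c", random_dna(rng, 400) + core + random_dna(rng, 400))

    def test_unique_flanked_locus_gives_one_amplicon(self):
        rng = random.Random(7)
        fwd, rev = "GCCTAGGCTTAAGGCCTAGG", "CAGGTTCACCAGGATGCCAA"
        genome = [self._flanking_genome(rng, fwd, rev, 460)]
        amps = enumerate_amplicons(make_clone(fwd, rev), genome)
        assert len(amps) == 1
        assert amps[0].size == 500
        seq = amplicon_sequence(amps[0], genome)
        assert seq.startswith(fwd)
        assert seq.endswith(reverse_complement(rev))

    def test_two_loci_give_two_amplicons(self):
        rng = random.Random(8)
        fwd, rev = "GCCTAGGCTTAAGGCCTAGG", "CAGGTTCACCAGGATGCCAA"
        locus = fwd + random_dna(rng, 300) + reverse_complement(rev)
        genome = [GenomeSequence(
            "c", random_dna(rng, 200) + locus + random_dna(rng, 500) + locus
                 + random_dna(rng, 200))]
        amps = enumerate_amplicons(make_clone(fwd, rev), genome)
        # 2 cis products plus the long trans product spanning both loci
        sizes = sorted(a.size for a in amps)
        assert sizes[:2] == [340, 340]
        assert len(amps) == 3

    def test_oversized_product_excluded(self):
        rng = random.Random(9)
        fwd, rev = "GCCTAGGCTTAAGGCCTAGG", "CAGGTTCACCAGGATGCCAA"
        genome = [self._flanking_genome(rng, fwd, rev, 12_000)]
        assert enumerate_amplicons(make_clone(fwd, rev), genome) == []
        assert len(enumerate_amplicons(make_clone(fwd, rev), genome,
                                       max_amplicon_bp=15_000)) == 1


class TestPrimerPairFlags:
    def test_balanced_strong_pair_clean(self):
        fwd, rev = "GCCTAGGCTTAAGGCCTAGG", "CCTAGGCCTTAAGCCTAGGC"
        assert abs(tm_nn(fwd) - tm_nn(rev)) < 3.0 and min(tm_nn(fwd), tm_nn(rev)) > 50
        assert primer_pair_flags(make_clone(fwd, rev)) == set()

    def test_cold_and_imbalanced_pair_flagged(self):
        cold = "ATATATTATAATATTAT"   # AT-rich 17-mer, far below 50 C
        hot = "GCCTAGGCTTAAGGCCTAGGGC"
        assert tm_nn(cold) <= 50.0 and tm_nn(hot) - tm_nn(cold) >= 3.0
        assert primer_pair_flags(make_clone(cold, hot)) == {TM_LOW_FWD, TM_IMBALANCE}
        assert primer_pair_flags(make_clone(hot, cold)) == {TM_LOW_REV, TM_IMBALANCE}
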