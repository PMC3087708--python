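"""Target identification: overlap, similarity, cross-RNAi search, plate forensics."""

import random

import edlib
import pytest

from conftest import make_clone, mutate, random_dna
from cloneaudit.insilico_pcr import Amplicon, BindingSite, reverse_complement
from cloneaudit.io_formats import GeneRecord, GeneStatus, GenomeSequence
from cloneaudit.target_mapping import (
    COLUMN,
    INTERGENIC,
    ROW,
    GeneIndex,
    check_gene_alive,
    detect_loading_shift,
    find_target_genes,
    genes_overlapping,
    similarity_score,
)


def _amp(chrom="chr1", start=0, end=100):
    site = BindingSite(chrom, "+", start, start + 20, 20, 60.0)
    rsite = BindingSite(chrom, "-", end - 20, end, 20, 60.0)
    return Amplicon(chrom, start, end, end - start, site, rsite, 1.0)


GENES = [
    GeneRecord("Y110A2A_4093.a", "chr1", 100, 600, "+", GeneStatus.RETIRED),
    GeneRecord("F18H3.3", "chr1", 700, 1400, "-", GeneStatus.ALIVE),
    GeneRecord("K02F6.9", "chr1", 1500, 2100, "+", GeneStatus.ALIVE),
]


class TestGeneAlive:
    def test_status_lookup(self):
        assert check_gene_alive("Y110A2A_4093.a", GENES) == "RETIRED"
        assert check_gene_alive("F18H3.3", GENES) == "ALIVE"
        assert check_gene_alive("nope", GENES) == "UNKNOWN"


class TestGenesOverlapping:
    def test_single_containing_gene(self):
        assert genes_overlapping(_amp(start=800, end=1200), GENES) == ["F18H3.3"]

    def test_boundary_spanning_amplicon_reports_both(self):
        assert genes_overlapping(_amp(start=1300, end=1600), GENES) == [
            "F18H3.3", "K02F6.9"
        ]

    def test_gene_desert_is_intergenic(self):
        assert genes_overlapping(_amp(start=2500, end=2700), GENES) == [INTERGENIC]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            genes_overlapping(_amp(chrom="chrX"), GENES)


class TestSimilarityScore:
    def test_identical_sequences_score_100(self):
        s = random_dna(random.Random(0), 500)
        assert similarity_score([s, s]) == 100.0
        assert similarity_score([s, s, s]) == 100.0

    def test_fifteen_substitutions_in_300_score_95(self):
        rng = random.Random(1)
        s = random_dna(rng, 300)
        t = mutate(rng, s, 15)
        # substitutions are cheaper than gaps, so the optimal alignment is
        # gapless: identity = 285/300 exactly
        assert similarity_score([s, t]) == pytest.approx(95.0, abs=0.2)

    def test_unrelated_sequences_score_far_below_homolog_threshold(self):
        rng = random.Random(2)
        assert similarity_score([random_dna(rng, 300), random_dna(rng, 300)]) < 80

    def test_agrees_with_edlib_on_substitution_pairs(self):
        rng = random.Random(3)
        s = random_dna(rng, 400)
        for n_subs in (4, 20, 60):
            t = mutate(rng, s, n_subs)
            d = edlib.align(s, t, task="distance")["editDistance"]
            assert similarity_score([s, t]) == pytest.approx(
                100.0 * (400 - d) / 400, abs=0.5
            )

    def test_permutation_invariant(self):
        rng = random.Random(4)
        seqs = [random_dna(rng, 200) for _ in range(3)]
        assert similarity_score(seqs) == pytest.approx(
            similarity_score(list(reversed(seqs))), abs=1e-9
        )

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            similarity_score([random_dna(random.Random(5), 100)])


def _index_with_genes(rng, gene_seqs):
    """Build a genome of concatenated genes with spacers and its index."""
    parts, genes, pos = [], [], 0
    for i, seq in enumerate(gene_seqs):
        spacer = random_dna(rng, 200)
        parts.append(spacer)
        pos += len(spacer)
        genes.append(GeneRecord(f"G{i}", "chr1", pos, pos + len(seq), "+"))
        parts.append(seq)
        pos += len(seq)
    genome = [GenomeSequence("chr1", "".join(parts) + random_dna(rng, 200))]
    return GeneIndex(genes, genome)


class TestFindTargetGenes:
    def test_verbatim_amplicon_hits_its_gene_perfectly(self):
        rng = random.Random(10)
        gene = random_dna(rng, 800)
        index = _index_with_genes(rng, [gene, random_dna(rng, 700)])
        (hit,) = find_target_genes(gene[100:500], index)
        assert hit.gene_id == "G0"
        assert hit.identity == 1.0
        assert hit.aligned_length == 400

    def test_085_identity_paralog_reported(self):
        rng = random.Random(11)
        gene = random_dna(rng, 600)
        amplicon = mutate(rng, gene[100:350], 37)  # 250 nt at ~85% identity
        index = _index_with_genes(rng, [gene])
        hits = find_target_genes(amplicon, index)
        assert [h.gene_id for h in hits] == ["G0"]
        assert hits[0].identity > 0.80
        assert hits[0].aligned_length >= 200

    def test_short_homology_region_rejected(self):
        rng = random.Random(12)
        gene = random_dna(rng, 600)
        # only 150 nt of homology inside a 250 nt amplicon
        amplicon = mutate(rng, gene[100:250], 22) + random_dna(rng, 100)
        index = _index_with_genes(rng, [gene])
        assert find_target_genes(amplicon, index) == []

    def test_reverse_strand_homology_found(self):
        rng = random.Random(13)
        gene = random_dna(rng, 600)
        index = _index_with_genes(rng, [gene])
        (hit,) = find_target_genes(reverse_complement(gene[50:450]), index)
        assert hit.gene_id == "G0"
        assert hit.identity == 1.0

    def test_short_amplicon_returns_empty(self):
        rng = random.Random(14)
        index = _index_with_genes(rng, [random_dna(rng, 600)])
        assert find_target_genes(random_dna(rng, 150), index) == []

    def test_matches_exhaustive_alignment_oracle(self):
        """Hit decisions agree with edlib local alignment on a small table."""
        rng = random.Random(15)
        base = random_dna(rng, 700)
        gene_seqs = [
            base,
            mutate(rng, base, 70),          # ~90% identity homolog
            mutate(rng, base, 300),         # far below threshold
            random_dna(rng, 700),           # unrelated
        ]
        index = _index_with_genes(rng, gene_seqs)
        amplicon = base[50:650]
        got = {h.gene_id for h in find_target_genes(amplicon, index)}
        expected = set()
        for i, seq in enumerate(gene_seqs):
            # oracle: infix alignment identity over the aligned span
            res = edlib.align(amplicon, seq, task="path", mode="HW")
            span = res["locations"][0]
            aligned = span[1] - span[0] + 1
            identity = 1 - res["editDistance"] / max(aligned, len(amplicon))
            if identity > 0.80 and aligned >= 200:
                expected.add(f"G{i}")
        assert got == expected


class TestDetectLoadingShift:
    def _library(self):
        return [
            make_clone("ACGTACGTAC", "TGCATGCATG", name="F36H12.3",
                       gene="F36H12.3", loc="IV-2B04"),
            make_clone("ACGTACGTAC", "TGCATGCATG", name="F36H12.17",
                       gene="F36H12.17", loc="IV-2D04"),
            make_clone("ACGTACGTAC", "TGCATGCATG", name="B0554.1",
                       gene="B0554.1", loc="V-1K09"),
            make_clone("ACGTACGTAC", "TGCATGCATG", name="Y39D8A.1",
                       gene="Y39D8A.1", loc="V-1K07"),
            make_clone("ACGTACGTAC", "TGCATGCATG", name="F32B5.4",
                       gene="F32B5.4", loc="I-1I14"),
            make_clone("ACGTACGTAC", "TGCATGCATG", name="C45E1.1",
                       gene="C45E1.1", loc="I-1M14"),
        ]

    @pytest.mark.parametrize("clone_name,actual,axis,offset", [
        ("F36H12.3", "F36H12.17", ROW, 2),    # vertical, two rows down
        ("B0554.1", "Y39D8A.1", COLUMN, -2),  # horizontal, two columns back
        ("F32B5.4", "C45E1.1", ROW, 4),       # vertical, four rows down
    ])
    def test_plate_shift_patterns_recovered(self, clone_name, actual, axis, offset):
        library = self._library()
        clone = next(c for c in library if c.clone_name == clone_name)
        shift = detect_loading_shift(clone, actual, library)
        assert shift is not None
        assert (shift.axis, shift.offset, shift.same_plate) == (axis, offset, True)

    def test_no_shift_when_annotation_confirmed(self):
        library = self._library()
        assert detect_loading_shift(library[0], "F36H12.3", library) is None

    def test_no_shift_for_gene_absent_or_off_plate(self):
        library = self._library()
        assert detect_loading_shift(library[0], "unknown.1", library) is None
        # actual gene's clone on a different plate: no geometric explanation
        assert detect_loading_shift(library[0], "B0554.1", library) is None
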