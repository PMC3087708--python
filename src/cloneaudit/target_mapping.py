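"""What does each predicted amplicon actually silence?

Couples four decisions: (1) is the annotated gene id still alive in the
current annotation; (2) which gene loci does the amplicon physically
overlap; (3) which genes does the amplicon's dsRNA plausibly silence by
sequence similarity (a seed-and-extend local search over the unspliced
gene set, reporting hits above 80% identity over at least 200 nt, the
classic cross-RNAi threshold); and (4) when sequencing reveals a
different gene than annotated, does the geometry of the arrayed plate
point at a loading error (the true clone sitting a fixed number of rows
or columns away in the same plate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Align import PairwiseAligner
from intervaltree import IntervalTree

from cloneaudit.insilico_pcr import Amplicon, reverse_complement
from cloneaudit.io_formats import CloneRecord, GeneRecord, GenomeSequence

INTERGENIC = "Intergenic"

UNKNOWN = "UNKNOWN"

ROW = "ROW"
COLUMN = "COLUMN"


@dataclass(frozen=True)
class TargetHit:
    """A gene the amplicon's dsRNA would silence."""

    gene_id: str
    identity: float
    aligned_length: int


@dataclass(frozen=True)
class LoadingShift:
    """A plate-handling error: the clone sits ``offset`` wells away from
    the well annotated for its true product, along ``axis``."""

    axis: str  # ROW (vertical) or COLUMN (horizontal)
    offset: int
    same_plate: bool = True

    def __post_init__(self) -> None:
        if self.axis not in (ROW, COLUMN):
            raise ValueError(f"unknown shift axis {self.axis!r}")
        if self.offset == 0:
            raise ValueError("shift offset must be non-zero")


class GeneIndex:
    """Prebuilt lookup structures over a gene table.

    Holds per-chromosome interval trees for positional overlap, the
    id -> record map for status checks, extracted unspliced gene
    sequences, and a k-mer -> genes inverted index used to shortlist
    candidates for the similarity search.
    """

    def __init__(
        self,
        genes: Sequence[GeneRecord],
        genome: Iterable[GenomeSequence] | None = None,
        seed_size: int = 11,
    ) -> None:
        self.genes = list(genes)
        self.by_id: dict[str, GeneRecord] = {}
        self.trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            self.by_id[g.gene_id] = g
            self.trees.setdefault(g.chrom_id, IntervalTree()).addi(g.start, g.end, g.gene_id)
        self.seed_size = seed_size
        self.sequences: dict[str, str] = {}
        self._kmer_genes: dict[str, set[str]] | None = None
        if genome is not None:
            chrom_seq = {c.chrom_id: c.sequence for c in genome}
            for g in self.genes:
                if g.chrom_id in chrom_seq:
                    self.sequences[g.gene_id] = chrom_seq[g.chrom_id][g.start : g.end]

    def _kmer_index(self) -> dict[str, set[str]]:
        if self._kmer_genes is None:
            idx: dict[str, set[str]] = {}
            k = self.seed_size
            for gid, seq in self.sequences.items():
                for strand_seq in (seq, reverse_complement(seq)):
                    for i in range(len(strand_seq) - k + 1):
                        idx.setdefault(strand_seq[i : i + k], set()).add(gid)
            self._kmer_genes = idx
        return self._kmer_genes


def _as_index(gene_table: GeneIndex | Sequence[GeneRecord],
              genome: Iterable[GenomeSequence] | None = None) -> GeneIndex:
    if isinstance(gene_table, GeneIndex):
        return gene_table
    return GeneIndex(gene_table, genome)


def check_gene_alive(gene_id: str, gene_table: GeneIndex | Sequence[GeneRecord]) -> str:
    """``ALIVE``/``RETIRED`` from the annotation table, ``UNKNOWN`` if the
    id is absent altogether."""
    index = _as_index(gene_table)
    gene = index.by_id.get(gene_id)
    if gene is None:
        return UNKNOWN
    return gene.status.value


def genes_overlapping(
    amplicon: Amplicon, gene_table: GeneIndex | Sequence[GeneRecord]
) -> list[str]:
    """Gene ids whose loci intersect the amplicon's interval, or the
    ``Intergenic`` sentinel when the amplicon lies in a gene desert."""
    index = _as_index(gene_table)
    if amplicon.chrom_id not in index.trees:
        known = any(g.chrom_id == amplicon.chrom_id for g in index.genes)
        if not known:
            raise ValueError(f"unknown chromosome {amplicon.chrom_id!r}")
    tree = index.trees.get(amplicon.chrom_id, IntervalTree())
    hits = sorted(
        (iv.begin, iv.data) for iv in tree.overlap(amplicon.start, amplicon.end)
    )
    if not hits:
        return [INTERGENIC]
    return [gid for _, gid in hits]


_ALIGNER: PairwiseAligner | None = None


def _aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.match_score = match
        a.mismatch_score = mismatch
        a.open_gap_score = gap
        a.extend_gap_score = gap
        _ALIGNER = a
    return _ALIGNER


def _pairwise_identity(s1: str, s2: str) -> float:
    """Fraction of identical columns in an optimal global alignment."""
    aln = _aligner().align(s1, s2)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def similarity_score(sequences: Sequence[str]) -> float:
    """0-100 similarity of a set of co-migrating amplicon sequences.

    Defined as 100 times the mean pairwise global-alignment identity
    (match +1, mismatch -1, gap -2), so identical inputs score exactly
    100 and the score calibrates directly against the >95 homolog
    threshold used in penalty scoring.
    """
    if len(sequences) < 2:
        raise ValueError("similarity_score needs at least 2 sequences")
    for s in sequences:
        if len(s) < 50:
            raise ValueError("sequences must be at least 50 nt")
    total, n_pairs = 0.0, 0
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            if sequences[i] == sequences[j]:
                total += 1.0
            else:
                total += _pairwise_identity(sequences[i], sequences[j])
            n_pairs += 1
    return 100.0 * total / n_pairs


def _extend_ungapped(
    amp: str, gene: str, amp_pos: int, gene_pos: int, k: int, xdrop: int = 20
) -> tuple[int, int, int]:
    """X-drop ungapped extension of a k-mer seed on one diagonal.

    Returns (amp_start, length, n_matches) of the best-scoring segment
    (match +1, mismatch -1) containing the seed.
    """
    # rightward from the seed end
    score = best = k
    best_right = amp_pos + k  # exclusive, in amplicon coordinates
    i, j = amp_pos + k, gene_pos + k
    while i < len(amp) and j < len(gene) and score > best - xdrop:
        score += 1 if amp[i] == gene[j] else -1
        i += 1
        j += 1
        if score > best:
            best, best_right = score, i
    # leftward from the seed start
    score = best_l = 0
    best_left = amp_pos
    i, j = amp_pos - 1, gene_pos - 1
    while i >= 0 and j >= 0 and score > best_l - xdrop:
        score += 1 if amp[i] == gene[j] else -1
        if score > best_l:
            best_l, best_left = score, i
        i -= 1
        j -= 1
    length = best_right - best_left
    offset = gene_pos - amp_pos
    matches = sum(
        1 for p in range(best_left, best_right) if amp[p] == gene[p + offset]
    )
    return best_left, length, matches


def find_target_genes(
    amplicon_sequence: str,
    gene_table: GeneIndex | Sequence[GeneRecord],
    genome: Iterable[GenomeSequence] | None = None,
    min_identity: float = 0.80,
    min_len: int = 200,
) -> list[TargetHit]:
    """Genes the amplicon can silence, by local sequence similarity.

    A seed-and-extend search (exact seeds of the index's ``seed_size``,
    default 11 nt; ungapped X-drop extension) against each unspliced gene
    sequence on both strands. Hits require identity above ``min_identity``
    over at least ``min_len`` nucleotides; the best hit per gene (longest,
    then most identical) is kept. Amplicons shorter than ``min_len``
    cannot qualify and return an empty list.
    """
    index = _as_index(gene_table, genome)
    if not index.sequences:
        raise ValueError("gene sequences unavailable: build GeneIndex with a genome")
    if len(amplicon_sequence) < min_len:
        return []
    k = index.seed_size
    kmer_idx = index._kmer_index()
    candidates: set[str] = set()
    amp_kmers: dict[str, list[int]] = {}
    for i in range(len(amplicon_sequence) - k + 1):
        kmer = amplicon_sequence[i : i + k]
        amp_kmers.setdefault(kmer, []).append(i)
        hit_genes = kmer_idx.get(kmer)
        if hit_genes:
            candidates.update(hit_genes)
    hits: list[TargetHit] = []
    for gid in sorted(candidates):
        gene_seq = index.sequences[gid]
        best: tuple[int, float] | None = None  # (length, identity)
        for strand_seq in (gene_seq, reverse_complement(gene_seq)):
            seen_diagonals: set[int] = set()
            for j in range(len(strand_seq) - k + 1):
                positions = amp_kmers.get(strand_seq[j : j + k])
                if not positions:
                    continue
                for i in positions:
                    diag = j - i
                    if diag in seen_diagonals:
                        continue
                    seen_diagonals.add(diag)
                    _, length, matches = _extend_ungapped(
                        amplicon_sequence, strand_seq, i, j, k
                    )
                    identity = matches / length
                    if length >= min_len and identity > min_identity:
                        if best is None or (length, identity) > best:
                            best = (length, identity)
        if best is not None:
            hits.append(TargetHit(gid, best[1], best[0]))
    hits.sort(key=lambda h: (-h.aligned_length * h.identity, h.gene_id))
    return hits


def detect_loading_shift(
    clone: CloneRecord,
    actual_gene: str,
    library: Sequence[CloneRecord],
) -> LoadingShift | None:
    """Explain a sequencing surprise as a plate loading error.

    If sequencing shows the clone actually carries ``actual_gene``, look
    up the library clone annotated to that gene: sitting on the same
    plate in the same column means the sample was shifted vertically by
    some rows (ROW axis); same row means a horizontal column shift.
    Offset sign is (actual clone position - this clone's position); ties
    are broken by the smallest absolute offset.
    """
    if actual_gene == clone.annotated_gene:
        return None
    loc = clone.location
    best: LoadingShift | None = None
    for other in library:
        if other.annotated_gene != actual_gene or other is clone:
            continue
        oloc = other.location
        if oloc.plate_key != loc.plate_key:
            continue
        shift: LoadingShift | None = None
        if oloc.col == loc.col and oloc.row != loc.row:
            shift = LoadingShift(ROW, oloc.row_index - loc.row_index)
        elif oloc.row == loc.row and oloc.col != loc.col:
            shift = LoadingShift(COLUMN, oloc.col - loc.col)
        if shift is not None and (best is None or abs(shift.offset) < abs(best.offset)):
            best = shift
    return best
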