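"""Replacement primer design for marginal and unreliable clones.

For a clone judged untrustworthy, propose up to five alternative primer
pairs inside its (alive) target gene, each guaranteed — by the package's
own screen — to make exactly one genomic product that maps back to that
gene alone. Candidates are ranked by Tm balance and then by how close
the product is to 1 kb, a comfortable size for both gel verification
and dsRNA synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from cloneaudit.insilico_pcr import (
    dg_3prime_end,
    enumerate_amplicons,
    reverse_complement,
    tm_nn,
)
from cloneaudit.io_formats import (
    CloneRecord,
    GeneRecord,
    GeneStatus,
    GenomeSequence,
    PlateLocation,
)
from cloneaudit.pipeline import PipelineConfig, DEFAULT_CONFIG
from cloneaudit.target_mapping import GeneIndex, find_target_genes


@dataclass(frozen=True)
class PrimerCandidate:
    """A validated alternative primer pair for one gene."""

    fwd_primer: str
    rev_primer: str
    tm_fwd: float
    tm_rev: float
    product_size: int


_PROBE_LOCATION = PlateLocation("NA", 1, "A", 1)

_MAX_VALIDATIONS = 200  # genome-wide re-screens are the expensive step


def _window_candidates(
    region: str,
    offsets: range,
    len_range: tuple[int, int],
    tm_range: tuple[float, float],
    as_reverse: bool,
    config: PipelineConfig,
) -> list[tuple[str, float, int, int]]:
    """(primer, tm, region_start, region_end) for every passing window."""
    out = []
    for off in offsets:
        for length in range(len_range[0], len_range[1] + 1):
            if off + length > len(region):
                continue
            primer = region[off : off + length]
            if as_reverse:
                primer = reverse_complement(primer)
            tm = tm_nn(primer, config.thermo)
            if not (tm_range[0] <= tm <= tm_range[1]):
                continue
            if dg_3prime_end(primer, config.thermo) < config.dg3_threshold:
                continue
            out.append((primer, tm, off, off + length))
    return out


def design_alternatives(
    gene: GeneRecord,
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneRecord] | GeneIndex,
    n: int = 5,
    len_range: tuple[int, int] = (18, 25),
    tm_range: tuple[float, float] = (55.0, 65.0),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[PrimerCandidate]:
    """Up to ``n`` specific alternative primer pairs for ``gene``.

    Candidate primers are enumerated over sliding windows inside the
    gene and kept only when each primer's Tm lies in ``tm_range``, the
    pair is balanced (|dTm| < 3 C), neither 3' end breaches the
    instability rule, and a genome-wide re-screen yields exactly one
    amplicon that maps back (by the similarity search) to this gene and
    no other. Ranked by |dTm|, then by product size closest to 1 kb.
    """
    if gene.status is not GeneStatus.ALIVE:
        raise ValueError(f"gene {gene.gene_id!r} is retired; remap the clone instead")
    length = gene.end - gene.start
    if length < 300:
        raise ValueError(f"gene {gene.gene_id!r} too short ({length} nt) for rescue")
    genome = list(genome)
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, genome)
    region = next(
        c.sequence[gene.start : gene.end] for c in genome if c.chrom_id == gene.chrom_id
    )

    stride = max(10, length // 40)
    fwd_half = range(0, max(1, length // 2 - len_range[1]), stride)
    rev_half = range(length // 2, length - len_range[1], stride)
    fwd_cands = _window_candidates(region, fwd_half, len_range, tm_range, False, config)
    rev_cands = _window_candidates(region, rev_half, len_range, tm_range, True, config)

    pairs = []
    for fwd, tm_f, fwd_start, _ in fwd_cands:
        for rev, tm_r, _, rev_end in rev_cands:
            dtm = abs(tm_f - tm_r)
            if dtm >= 3.0:
                continue
            size = rev_end - fwd_start
            if size < max(200, config.min_hit_len):
                continue
            pairs.append((dtm, abs(size - 1000), fwd, rev, tm_f, tm_r))
    pairs.sort(key=lambda p: (p[0], p[1], p[2], p[3]))

    candidates: list[PrimerCandidate] = []
    seen: set[tuple[str, str]] = set()
    for attempt, (dtm, _, fwd, rev, tm_f, tm_r) in enumerate(pairs):
        if len(candidates) >= n or attempt >= _MAX_VALIDATIONS:
            break
        if (fwd, rev) in seen:
            continue
        seen.add((fwd, rev))
        probe = CloneRecord(f"rescue:{gene.gene_id}", fwd, rev, gene.gene_id, _PROBE_LOCATION)
        amplicons = enumerate_amplicons(
            probe,
            genome,
            max_amplicon_bp=config.max_amplicon_bp,
            ppc_cutoff=config.ppc_cutoff,
            min_duplex_tm=config.min_duplex_tm,
            word_size=config.word_size,
            thermo=config.thermo,
        )
        if len(amplicons) != 1:
            continue
        amp = amplicons[0]
        chrom = next(c for c in genome if c.chrom_id == amp.chrom_id)
        hits = find_target_genes(
            chrom.sequence[amp.start : amp.end],
            index,
            min_identity=config.min_identity,
            min_len=config.min_hit_len,
        )
        if [h.gene_id for h in hits] != [gene.gene_id]:
            continue
        candidates.append(PrimerCandidate(fwd, rev, tm_f, tm_r, amp.size))
    return candidates
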