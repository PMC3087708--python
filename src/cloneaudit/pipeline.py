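"""End-to-end clone evaluation: glue over the screening modules.

``evaluate_clone`` runs one clone through the whole audit — 3'-end
stability, in-silico PCR, virtual gel co-migration, similarity scoring,
target mapping — and condenses the evidence into a
:class:`~cloneaudit.scoring.CloneEvaluation`. ``evaluate_library`` does
the same for a whole plate set, sharing the prebuilt gene index.

One category rule sits above the numeric score: a clone whose products
hit no gene at all cannot be called reliable no matter how specific its
PCR is, so a would-be green clone with the ``NO_TARGET`` flag is
downgraded to marginal (yellow), mirroring the convention of flagging
no-hit clones with an "R" on a yellow background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from cloneaudit.gel_model import GelConfig, comigrating_groups
from cloneaudit.insilico_pcr import (
    ThermoParams,
    amplicon_sequence,
    dg_3prime_end,
    enumerate_amplicons,
    primer_pair_flags,
)
from cloneaudit.io_formats import CloneRecord, GeneRecord, GenomeSequence
from cloneaudit.scoring import (
    Category,
    CloneEvaluation,
    NO_TARGET,
    SHORT_AMPLICON,
    classify,
    remap_flags,
    score_clone,
)
from cloneaudit.target_mapping import (
    GeneIndex,
    TargetHit,
    find_target_genes,
    similarity_score,
)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the audit in one place.

    Defaults are the library-screening conditions: 4-nt 3' seed word,
    products up to 10 kb, pair-coverage cutoff 0.3, 50 C duplex-Tm floor,
    -9 kcal/mol 3'-end rule, cross-RNAi hit thresholds of 80% identity
    over 200 nt, and the 95/10 category boundaries.
    """

    thermo: ThermoParams = field(default_factory=ThermoParams)
    gel: GelConfig = field(default_factory=GelConfig)
    word_size: int = 4
    max_amplicon_bp: int = 10_000
    ppc_cutoff: float = 0.3
    min_duplex_tm: float = 50.0
    dg3_threshold: float = -9.0
    min_identity: float = 0.80
    min_hit_len: int = 200


DEFAULT_CONFIG = PipelineConfig()


def evaluate_clone(
    clone: CloneRecord,
    genome: Sequence[GenomeSequence],
    gene_index: GeneIndex,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> CloneEvaluation:
    """Run the full audit for a single clone."""
    flags = primer_pair_flags(clone, config.thermo)
    dg_f = dg_3prime_end(clone.fwd_primer, config.thermo)
    dg_r = dg_3prime_end(clone.rev_primer, config.thermo)

    dg_failed = dg_f < config.dg3_threshold or dg_r < config.dg3_threshold
    amplicons = []
    if not dg_failed:
        amplicons = enumerate_amplicons(
            clone,
            genome,
            max_amplicon_bp=config.max_amplicon_bp,
            ppc_cutoff=config.ppc_cutoff,
            min_duplex_tm=config.min_duplex_tm,
            word_size=config.word_size,
            thermo=config.thermo,
        )

    groups = comigrating_groups(amplicons, config.gel)
    similarities: list[float | None] = []
    for group in groups:
        if len(group) >= 2:
            seqs = [amplicon_sequence(a, genome) for a in group]
            similarities.append(similarity_score(seqs))
        else:
            similarities.append(None)

    ledger = score_clone(
        clone, amplicons, groups, similarities, dg_f, dg_r, config.dg3_threshold
    )
    score = ledger.final_score

    # target mapping: union of similarity hits over all products, best per gene
    best_hits: dict[str, TargetHit] = {}
    for amp in amplicons:
        seq = amplicon_sequence(amp, genome)
        if len(seq) < config.min_hit_len:
            flags.add(SHORT_AMPLICON)
            continue
        for hit in find_target_genes(
            seq, gene_index, min_identity=config.min_identity, min_len=config.min_hit_len
        ):
            prev = best_hits.get(hit.gene_id)
            if prev is None or (hit.aligned_length, hit.identity) > (
                prev.aligned_length, prev.identity
            ):
                best_hits[hit.gene_id] = hit
    targets = sorted(
        best_hits.values(), key=lambda h: (-h.aligned_length * h.identity, h.gene_id)
    )

    flags |= remap_flags(clone, targets)

    category = classify(score)
    if NO_TARGET in flags and category is Category.RELIABLE:
        category = Category.MARGINAL

    return CloneEvaluation(
        clone_name=clone.clone_name,
        location=clone.location,
        score=score,
        category=category,
        flags=frozenset(flags),
        predicted_targets=targets,
        amplicons=list(amplicons),
        ledger=ledger,
    )


def evaluate_library(
    clones: Iterable[CloneRecord],
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneRecord] | GeneIndex,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CloneEvaluation]:
    """Audit every clone of a library against one shared gene index."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, genome)
    return [evaluate_clone(c, genome, index, config) for c in clones]
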