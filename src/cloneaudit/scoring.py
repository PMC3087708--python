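"""Penalty ledger: evidence in, 0-100 reliability score out.

Every clone starts at 100 and loses points for each piece of evidence
against it: an over-stable primer 3' end (below -9 kcal/mol over the
terminal pentamer) or a total absence of surviving products zeroes the
score outright, and each group of co-migrating products costs
``100 - similarity`` points, so near-identical homolog products cost
almost nothing while unrelated co-migrating products are heavily
punished. Scores map onto the road-traffic categories: green/reliable at
>= 95, red/unreliable at <= 10, yellow/marginal between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Sequence

from cloneaudit.insilico_pcr import Amplicon
from cloneaudit.io_formats import CloneRecord, PlateLocation
from cloneaudit.target_mapping import TargetHit

# score-bearing rule ids
DG3_END = "DG3_END"
NO_AMPLICON = "NO_AMPLICON"
COMIGRATION = "COMIGRATION"

# report-only flags (beyond the Tm flags from insilico_pcr)
REMAPPED = "REMAPPED"
NO_TARGET = "NO_TARGET"
MULTI_TARGET = "MULTI_TARGET"
SHORT_AMPLICON = "SHORT_AMPLICON"

DG3_THRESHOLD = -9.0  # kcal/mol


class Category(Enum):
    """Reliability category, ordered UNRELIABLE < MARGINAL < RELIABLE."""

    UNRELIABLE = 0
    MARGINAL = 1
    RELIABLE = 2

    def __lt__(self, other: "Category") -> bool:
        return self.value < other.value

    def __le__(self, other: "Category") -> bool:
        return self.value <= other.value


@dataclass(frozen=True)
class LedgerEntry:
    rule_id: str
    penalty: int
    note: str


@dataclass
class PenaltyLedger:
    """Auditable arithmetic trail from the initial 100 to the final score."""

    initial: int = 100
    entries: list[LedgerEntry] = field(default_factory=list)

    def add(self, rule_id: str, penalty: int, note: str = "") -> None:
        self.entries.append(LedgerEntry(rule_id, penalty, note))

    @property
    def final_score(self) -> int:
        score = self.initial - sum(e.penalty for e in self.entries)
        return max(0, min(100, score))

    def replay(self) -> int:
        """Recompute the score from the entries alone (audit check)."""
        score = self.initial
        for e in self.entries:
            score -= e.penalty
        return max(0, min(100, score))


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def score_clone(
    clone: CloneRecord,
    amplicons: Sequence[Amplicon],
    comigration_groups: Sequence[Sequence[Amplicon]],
    group_similarities: Sequence[float | None],
    dg3_fwd: float,
    dg3_rev: float,
    dg_threshold: float = DG3_THRESHOLD,
) -> PenaltyLedger:
    """Build the penalty ledger for one clone.

    ``comigration_groups`` is the gel-model partition of ``amplicons``;
    ``group_similarities`` is parallel to it and holds the 0-100
    similarity of each multi-member group (None for singletons).
    Similarities are rounded half-up to integers before subtraction so
    the final score is an integer.
    """
    ledger = PenaltyLedger()
    if dg3_fwd < dg_threshold or dg3_rev < dg_threshold:
        which = "forward" if dg3_fwd < dg_threshold else "reverse"
        ledger.add(
            DG3_END, 100,
            f"{which} primer 3'-end dG below {dg_threshold} kcal/mol "
            f"(fwd {dg3_fwd:.2f}, rev {dg3_rev:.2f})",
        )
        return ledger
    if not amplicons:
        ledger.add(NO_AMPLICON, 100, "no amplicon survives the specificity filters")
        return ledger
    for group, sim in zip(comigration_groups, group_similarities):
        if len(group) < 2:
            continue
        if sim is None:
            raise ValueError("multi-member co-migration group without a similarity score")
        penalty = 100 - _round_half_up(sim)
        sizes = ",".join(str(a.size) for a in group)
        ledger.add(
            COMIGRATION, penalty,
            f"{len(group)} co-migrating products (sizes {sizes} bp), similarity {sim:.1f}",
        )
    return ledger


def classify(score: int | float) -> Category:
    """Road-traffic category for a 0-100 score.

    >= 95 is reliable (green), <= 10 unreliable (red), in between
    marginal (yellow).
    """
    if not (0 <= score <= 100):
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= 95:
        return Category.RELIABLE
    if score <= 10:
        return Category.UNRELIABLE
    return Category.MARGINAL


def remap_flags(
    clone: CloneRecord,
    predicted_targets: Sequence[TargetHit],
    gene_status: str | None = None,
) -> set[str]:
    """Annotation flags derived from the predicted target list.

    ``REMAPPED``: the amplicon silences genes, but not the one the clone
    is annotated to (retired ids and wrong inserts end up here).
    ``NO_TARGET``: the amplicon silences no gene at all (intergenic
    products, dead primer sets). ``MULTI_TARGET``: two or more distinct
    genes would be silenced (cross-RNAi / homolog co-amplification).
    """
    gene_ids = {t.gene_id for t in predicted_targets}
    flags: set[str] = set()
    if not gene_ids:
        flags.add(NO_TARGET)
    elif clone.annotated_gene not in gene_ids:
        flags.add(REMAPPED)
    if len(gene_ids) >= 2:
        flags.add(MULTI_TARGET)
    return flags


@dataclass
class CloneEvaluation:
    """Final verdict for one clone, with the full evidence trail."""

    clone_name: str
    location: PlateLocation
    score: int
    category: Category
    flags: frozenset[str]
    predicted_targets: list[TargetHit]
    amplicons: list[Amplicon]
    ledger: PenaltyLedger
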