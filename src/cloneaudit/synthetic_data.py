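"""Seeded generators for toy genomes and defect-laden clone libraries.

The generator emulates the situations an arrayed RNAi feeding library
can get into: clean specific clones, clones annotated to retired gene
ids whose primers amplify a successor gene, primer pairs shared between
two loci (high-identity paralog pairs that co-amplify, and
lower-identity "cross-hybridizing" pairs that yield unrelated
co-migrating products), products that land in gene deserts, empty-vector
wells whose primers match nothing, and plate loading errors where a
sample sits a fixed number of rows or columns away from its intended
well. Every clone's intended defect class is emitted in a ground-truth
table so recovery can be measured without reverse-engineering sequences.

Shared-primer gene pairs are built by duplicating a gene and mutating
only its interior, leaving the first and last ``FLANK_LEN`` bases exact
so primers designed on the flanks bind both copies and the two products
have identical gel mobility. Primer design uses the pipeline's own
melting-temperature and 3'-end models, so generated primers pass the
intrinsic quality filters and defects are detectable only by the
genomic evidence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from cloneaudit.insilico_pcr import (
    ThermoParams,
    dg_3prime_end,
    enumerate_amplicons,
    reverse_complement,
    tm_nn,
)
from cloneaudit.io_formats import (
    PLATE_COLS,
    PLATE_ROWS,
    CloneRecord,
    GeneRecord,
    GeneStatus,
    GenomeSequence,
    PlateLocation,
)
from cloneaudit.reporting import (
    OUTCOME_RELIABLE,
    OUTCOME_REMAPPED_RETIRED,
    OUTCOME_REMAPPED_WRONG_INSERT,
    OUTCOME_UNRELIABLE,
    OUTCOMES,
    ValidationRecord,
)
from cloneaudit.target_mapping import COLUMN, ROW

# defect class names (the ground-truth vocabulary)
SPECIFIC = "SPECIFIC"
RETIRED_REMAPPED = "RETIRED_REMAPPED"
NONSPECIFIC_PRIMERS = "NONSPECIFIC_PRIMERS"
INTERGENIC_AMPLICON = "INTERGENIC_AMPLICON"
LOADING_SHIFT = "LOADING_SHIFT"
EMPTY_VECTOR = "EMPTY_VECTOR"
HOMOLOG_COMIGRATION = "HOMOLOG_COMIGRATION"

FLANK_LEN = 60  # exact-copy flank length of shared-primer gene pairs

_WELLS_PER_PLATE = len(PLATE_ROWS) * PLATE_COLS  # 384

_TRUTH_TO_OUTCOME = {
    SPECIFIC: OUTCOME_RELIABLE,
    HOMOLOG_COMIGRATION: OUTCOME_RELIABLE,
    RETIRED_REMAPPED: OUTCOME_REMAPPED_RETIRED,
    LOADING_SHIFT: OUTCOME_REMAPPED_WRONG_INSERT,
    NONSPECIFIC_PRIMERS: OUTCOME_UNRELIABLE,
    INTERGENIC_AMPLICON: OUTCOME_UNRELIABLE,
    EMPTY_VECTOR: OUTCOME_UNRELIABLE,
}


@dataclass(frozen=True)
class DefectSpec:
    """Fractions of each injected defect class; the remainder of the
    library is clean SPECIFIC clones."""

    nonspecific_primers: float = 0.0
    intergenic_amplicon: float = 0.0
    empty_vector: float = 0.0
    retired_remapped: float = 0.0
    loading_shift: float = 0.0
    homolog_comigration: float = 0.0
    shift_patterns: tuple[tuple[str, int], ...] = ((ROW, 2), (ROW, 4), (COLUMN, -2))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fractions = self._fractions()
        if any(f < 0 for f in fractions.values()):
            raise ValueError("defect fractions must be non-negative")
        if sum(fractions.values()) > 1.0 + 1e-9:
            raise ValueError("defect fractions sum above 1")
        for axis, offset in self.shift_patterns:
            if axis not in (ROW, COLUMN) or offset == 0:
                raise ValueError(f"invalid shift pattern ({axis}, {offset})")

    def _fractions(self) -> dict[str, float]:
        return {
            NONSPECIFIC_PRIMERS: self.nonspecific_primers,
            INTERGENIC_AMPLICON: self.intergenic_amplicon,
            EMPTY_VECTOR: self.empty_vector,
            RETIRED_REMAPPED: self.retired_remapped,
            LOADING_SHIFT: self.loading_shift,
            HOMOLOG_COMIGRATION: self.homolog_comigration,
        }


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choices("ACGT", k=n))


def _mutated_copy(rng: random.Random, seq: str, identity: float, flank: int) -> str:
    """Substitution-mutated copy of ``seq`` with exact flanks.

    The number of substitutions is chosen so the overall (full-length)
    identity equals ``identity``; all of them land in the interior
    ``[flank, len-flank)`` so flank-designed primers match both copies.
    """
    n_mut = round((1.0 - identity) * len(seq))
    interior = range(flank, len(seq) - flank)
    if n_mut > len(interior):
        raise ValueError(
            f"cannot place {n_mut} substitutions in a {len(interior)} nt interior"
        )
    positions = rng.sample(list(interior), n_mut)
    bases = list(seq)
    for p in positions:
        bases[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(bases)


def generate_genome(
    n_chrom: int = 4,
    genes_per_chrom: int = 60,
    gene_len_range: tuple[int, int] = (600, 1200),
    intergenic_len_range: tuple[int, int] = (150, 400),
    n_paralog_pairs: int = 0,
    paralog_identity: float = 0.96,
    n_crosshyb_pairs: int = 0,
    crosshyb_identity: float = 0.75,
    retired_fraction: float = 0.0,
    n_deserts_per_chrom: int = 0,
    desert_len: int = 2500,
    seed: int = 0,
) -> tuple[list[GenomeSequence], list[GeneRecord]]:
    """Generate a toy genome with gene models and planted gene families.

    Paralog pairs (ids ``parNNa``/``parNNb``) share exact ``FLANK_LEN``
    flanks and differ only by interior substitutions at
    ``paralog_identity``; cross-hybridizing pairs (``xhNNa``/``xhNNb``)
    are built the same way at the lower ``crosshyb_identity``. A
    ``retired_fraction`` of the ordinary genes is marked RETIRED (their
    loci stay in place; successor assignment happens at library
    generation). ``n_deserts_per_chrom`` long intergenic spans per
    chromosome provide room for intergenic amplicons. Deterministic for
    a fixed seed.
    """
    if not (0.80 <= paralog_identity < 1.0):
        raise ValueError("paralog_identity must be in [0.80, 1.0)")
    rng = random.Random(seed)
    total_slots = n_chrom * genes_per_chrom
    n_pair_slots = 2 * (n_paralog_pairs + n_crosshyb_pairs)
    if n_pair_slots > total_slots:
        raise ValueError(
            f"cannot pack {n_pair_slots} gene-family slots into {total_slots} gene slots"
        )
    if genes_per_chrom and gene_len_range[0] < 2 * FLANK_LEN + 50:
        raise ValueError(f"gene_len_range minimum must be >= {2 * FLANK_LEN + 50}")

    # assign gene-family members to slots
    kinds: list[tuple[str, int, str]] = []  # (family, pair index, member)
    for k in range(n_paralog_pairs):
        kinds += [("par", k, "a"), ("par", k, "b")]
    for k in range(n_crosshyb_pairs):
        kinds += [("xh", k, "a"), ("xh", k, "b")]
    kinds += [("g", i, "") for i in range(total_slots - n_pair_slots)]
    rng.shuffle(kinds)

    # keep the two members of a shared-primer pair on different chromosomes
    # so the pair cannot also make a locus-spanning product
    if n_chrom > 1 and genes_per_chrom:
        slot_of = {kind: s for s, kind in enumerate(kinds)}
        chrom_of = lambda s: s // genes_per_chrom  # noqa: E731
        for fam, n_pairs in (("par", n_paralog_pairs), ("xh", n_crosshyb_pairs)):
            for k in range(n_pairs):
                sa, sb = slot_of[(fam, k, "a")], slot_of[(fam, k, "b")]
                if chrom_of(sa) != chrom_of(sb):
                    continue
                swaps = [
                    s for s, kind in enumerate(kinds)
                    if kind[0] == "g" and chrom_of(s) != chrom_of(sa)
                ]
                if swaps:
                    s = swaps[rng.randrange(len(swaps))]
                    kinds[sb], kinds[s] = kinds[s], kinds[sb]
                    slot_of[kinds[sb]], slot_of[kinds[s]] = sb, s

    # sequences per family so both members share length and flanks
    pair_seq: dict[tuple[str, int, str], str] = {}
    design_thermo = ThermoParams()
    for fam, ident in (("par", paralog_identity), ("xh", crosshyb_identity)):
        n_pairs = n_paralog_pairs if fam == "par" else n_crosshyb_pairs
        for k in range(n_pairs):
            # flanks are frozen between the two copies, so they must admit
            # a primer pair; redraw the rare AT-rich draw that does not
            for _ in range(50):
                first = _random_dna(rng, rng.randint(*gene_len_range))
                if _design_pair_on_region(first, design_thermo, FLANK_LEN, FLANK_LEN):
                    break
            else:
                raise ValueError("could not draw designable flanks for a gene pair")
            pair_seq[(fam, k, "a")] = first
            pair_seq[(fam, k, "b")] = _mutated_copy(rng, first, ident, FLANK_LEN)

    # exactly round(retired_fraction * n_normal) ordinary genes are retired
    n_normal = total_slots - n_pair_slots
    retired_ids = set(rng.sample(range(n_normal), round(retired_fraction * n_normal)))

    genomes: list[GenomeSequence] = []
    genes: list[GeneRecord] = []
    slot = 0
    for ci in range(n_chrom):
        chrom_id = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0
        desert_after = set()
        if n_deserts_per_chrom and genes_per_chrom:
            step = max(1, genes_per_chrom // (n_deserts_per_chrom + 1))
            desert_after = {step * (d + 1) - 1 for d in range(n_deserts_per_chrom)}
        for gi in range(genes_per_chrom):
            spacer = _random_dna(rng, rng.randint(*intergenic_len_range))
            parts.append(spacer)
            pos += len(spacer)
            fam, k, member = kinds[slot]
            if member:
                seq = pair_seq[(fam, k, member)]
                gene_id = f"{fam}{k:02d}{member}"
                status = GeneStatus.ALIVE
            else:
                seq = _random_dna(rng, rng.randint(*gene_len_range))
                gene_id = f"g{k:04d}"
                status = GeneStatus.RETIRED if k in retired_ids else GeneStatus.ALIVE
            strand = rng.choice("+-")
            genes.append(GeneRecord(gene_id, chrom_id, pos, pos + len(seq), strand, status))
            parts.append(seq)
            pos += len(seq)
            slot += 1
            if gi in desert_after:
                parts.append(_random_dna(rng, desert_len))
                pos += desert_len
        tail = _random_dna(rng, rng.randint(*intergenic_len_range))
        parts.append(tail)
        if n_deserts_per_chrom and not genes_per_chrom:
            parts.append(_random_dna(rng, desert_len))
        genomes.append(GenomeSequence(chrom_id, "".join(parts)))
    return genomes, genes


def _design_pair_on_region(
    region: str,
    thermo: ThermoParams,
    fwd_window: int,
    rev_window: int,
    len_range: tuple[int, int] = (18, 24),
    tm_range: tuple[float, float] = (52.0, 65.0),
    max_dtm: float = 3.0,
    dg_floor: float = -9.0,
) -> tuple[str, str] | None:
    """Best primer pair flanking ``region``: forward primer inside the
    first ``fwd_window`` bases, reverse inside the last ``rev_window``,
    both within the Tm range and above the 3'-end dG floor, minimizing
    the pair's Tm difference. None when the windows admit no such pair."""

    def candidates(window_seq: str, as_reverse: bool) -> list[tuple[float, str]]:
        out = []
        for length in range(len_range[0], len_range[1] + 1):
            for off in range(0, len(window_seq) - length + 1):
                primer = window_seq[off : off + length]
                if as_reverse:
                    primer = reverse_complement(primer)
                tm = tm_nn(primer, thermo)
                if tm_range[0] <= tm <= tm_range[1] and dg_3prime_end(primer, thermo) >= dg_floor:
                    out.append((tm, primer))
        return out

    fwd_cands = candidates(region[:fwd_window], as_reverse=False)
    rev_cands = candidates(region[-rev_window:], as_reverse=True)
    best: tuple[float, str, str] | None = None
    for tm_f, fwd in fwd_cands:
        for tm_r, rev in rev_cands:
            dtm = abs(tm_f - tm_r)
            if dtm >= max_dtm:
                continue
            if best is None or dtm < best[0]:
                best = (dtm, fwd, rev)
    if best is None:
        return None
    return best[1], best[2]


def _desert_spans(
    genomes: Sequence[GenomeSequence], genes: Sequence[GeneRecord], min_len: int = 1200
) -> list[tuple[str, int, int]]:
    """Intergenic spans long enough to host a full amplicon."""
    spans = []
    for chrom in genomes:
        intervals = sorted(
            (g.start, g.end) for g in genes if g.chrom_id == chrom.chrom_id
        )
        pos = 0
        for start, end in intervals + [(len(chrom.sequence), len(chrom.sequence))]:
            if start - pos >= min_len:
                spans.append((chrom.chrom_id, pos, start))
            pos = max(pos, end)
    return spans


_N_ROWS = len(PLATE_ROWS)  # 16


def _well_location(index: int, plate_labels: Sequence[str]) -> PlateLocation:
    """Column-major well layout: A01, B01, ... P01, A02, ..."""
    plate = plate_labels[index // _WELLS_PER_PLATE]
    chrom_label, plate_no = plate.rsplit("-", 1)
    within = index % _WELLS_PER_PLATE
    return PlateLocation(
        chrom_label=chrom_label,
        plate_no=int(plate_no),
        row=PLATE_ROWS[within % _N_ROWS],
        col=within // _N_ROWS + 1,
    )


def generate_library(
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneRecord],
    defects: DefectSpec,
    plate_labels: Sequence[str],
    seed: int = 0,
    n_clones: int | None = None,
    thermo: ThermoParams | None = None,
) -> tuple[list[CloneRecord], pd.DataFrame]:
    """Build a plated clone library with injected defects.

    Returns the clone records and a ground-truth table (one row per
    clone: intended class, the gene(s) the primers actually amplify, and
    for loading shifts the axis/offset and displaced gene). Clones are
    named after their annotated gene. Deterministic for a fixed seed.
    """
    rng = random.Random(seed)
    thermo = thermo or ThermoParams()
    genome = list(genome)
    chrom_seq = {c.chrom_id: c.sequence for c in genome}
    capacity = _WELLS_PER_PLATE * len(plate_labels)

    normal_alive = [g for g in genes if g.gene_id.startswith("g") and g.status is GeneStatus.ALIVE]
    retired = [g for g in genes if g.status is GeneStatus.RETIRED]
    par_a = sorted((g for g in genes if g.gene_id.startswith("par") and g.gene_id.endswith("a")), key=lambda g: g.gene_id)
    xh_a = sorted((g for g in genes if g.gene_id.startswith("xh") and g.gene_id.endswith("a")), key=lambda g: g.gene_id)

    if n_clones is None:
        n_clones = min(capacity, len(normal_alive))
    if n_clones > capacity:
        raise ValueError(f"{n_clones} clones exceed plate capacity {capacity}")

    fractions = defects._fractions()
    counts = {klass: int(round(frac * n_clones)) for klass, frac in fractions.items()}
    n_specific = n_clones - sum(counts.values())
    if n_specific < 0:
        raise ValueError("defect fractions leave no room for specific clones")

    # annotation pool: every clone needs a unique annotated gene
    need_annotations = n_specific + counts[NONSPECIFIC_PRIMERS] * 0 + (
        counts[INTERGENIC_AMPLICON] + counts[EMPTY_VECTOR] + counts[LOADING_SHIFT]
    )
    pool = list(normal_alive)
    rng.shuffle(pool)
    for klass, available, what in (
        (RETIRED_REMAPPED, len(retired), "retired genes"),
        (HOMOLOG_COMIGRATION, len(par_a), "paralog pairs"),
        (NONSPECIFIC_PRIMERS, len(xh_a), "cross-hybridizing pairs"),
    ):
        if counts[klass] > available:
            raise ValueError(
                f"{counts[klass]} {klass} clones requested but only {available} {what}"
            )
    if need_annotations > len(pool):
        raise ValueError(
            f"not enough alive genes: need {need_annotations}, have {len(pool)}"
        )
    deserts = _desert_spans(genome, genes)
    if counts[INTERGENIC_AMPLICON] > 0 and not deserts:
        raise ValueError("no gene desert long enough for intergenic amplicons")

    # --- well/class layout ------------------------------------------------
    classes: dict[int, str] = {}
    shift_plan: dict[int, tuple[str, int, int]] = {}  # well -> (axis, offset, target well)
    reserved: set[int] = set()
    pattern_cycle = list(defects.shift_patterns)
    pi = 0
    w = 0
    while len(shift_plan) < counts[LOADING_SHIFT]:
        if w >= n_clones:
            raise ValueError("plate too small to place all loading shifts")
        axis, offset = pattern_cycle[pi % len(pattern_cycle)]
        # column-major layout: +1 well is +1 row, +16 wells is +1 column
        target = w + offset if axis == ROW else w + offset * _N_ROWS
        ok = (
            0 <= target < n_clones
            and target != w
            and w // _WELLS_PER_PLATE == target // _WELLS_PER_PLATE
            and w not in reserved
            and target not in reserved
        )
        if ok and axis == ROW:  # same column after the shift
            ok = (w % _WELLS_PER_PLATE) // _N_ROWS == (target % _WELLS_PER_PLATE) // _N_ROWS
        if ok:
            shift_plan[w] = (axis, offset, target)
            classes[w] = LOADING_SHIFT
            classes[target] = SPECIFIC  # shift target must be a clean clone
            reserved.update((w, target))
            pi += 1
        w += 1
    free = [i for i in range(n_clones) if i not in reserved]
    rng.shuffle(free)
    cursor = 0
    for klass in (NONSPECIFIC_PRIMERS, INTERGENIC_AMPLICON, EMPTY_VECTOR,
                  RETIRED_REMAPPED, HOMOLOG_COMIGRATION):
        for _ in range(counts[klass]):
            classes[free[cursor]] = klass
            cursor += 1
    for i in free[cursor:]:
        classes[i] = SPECIFIC

    # --- clone construction ----------------------------------------------
    def gene_region(g: GeneRecord) -> str:
        return chrom_seq[g.chrom_id][g.start : g.end]

    def design_for_gene(g: GeneRecord, window: int, widen: bool = True) -> tuple[str, str]:
        region = gene_region(g)
        windows = [window]
        if widen:  # unconstrained genes may search deeper into the gene body
            windows += [w for w in (2 * window, len(region) // 2) if w > window]
        for w in windows:
            pair = _design_pair_on_region(region, thermo, min(w, len(region) // 2),
                                          min(w, len(region) // 2))
            if pair is not None:
                return pair
        raise ValueError(f"no valid primer pair for gene {g.gene_id}")

    def unique_amplifier(name: str, fwd: str, rev: str, well: int) -> bool:
        probe = CloneRecord(name, fwd, rev, name, _well_location(well, plate_labels))
        return len(enumerate_amplicons(probe, genome, thermo=thermo)) == 1

    def next_specific_design(well: int) -> tuple[GeneRecord, str, str]:
        """Pop genes until one's designed pair amplifies uniquely.

        A gene whose primers happen to have a stray near-match site
        elsewhere is skipped: the clean class must be clean.
        """
        for _ in range(10):
            g = pool.pop()
            fwd, rev = design_for_gene(g, 60)
            if unique_amplifier(g.gene_id, fwd, rev, well):
                return g, fwd, rev
        raise ValueError("could not design a uniquely amplifying primer pair")

    retired_pool = list(retired)
    rng.shuffle(retired_pool)
    par_pool = list(par_a)
    xh_pool = list(xh_a)

    clones: dict[int, CloneRecord] = {}
    truth_rows: list[dict] = []

    def add_clone(i: int, name: str, fwd: str, rev: str, annotated: str,
                  klass: str, targets: Sequence[str],
                  shift: tuple[str, int, str] | None = None) -> None:
        loc = _well_location(i, plate_labels)
        clones[i] = CloneRecord(name, fwd, rev, annotated, loc)
        truth_rows.append({
            "clone_name": name,
            "class": klass,
            "expected_targets": ";".join(targets),
            "shift_axis": shift[0] if shift else "",
            "shift_offset": shift[1] if shift else 0,
            "actual_gene": shift[2] if shift else "",
        })

    gene_by_id = {g.gene_id: g for g in genes}
    for i in sorted(classes):
        klass = classes[i]
        if klass == LOADING_SHIFT:
            continue  # second pass, needs the target clone's primers
        if klass == SPECIFIC:
            g, fwd, rev = next_specific_design(i)
            add_clone(i, g.gene_id, fwd, rev, g.gene_id, SPECIFIC, [g.gene_id])
        elif klass == HOMOLOG_COMIGRATION:
            g = par_pool.pop(0)
            partner = gene_by_id[g.gene_id[:-1] + "b"]
            fwd, rev = design_for_gene(g, FLANK_LEN, widen=False)
            add_clone(i, g.gene_id, fwd, rev, g.gene_id, klass,
                      [g.gene_id, partner.gene_id])
        elif klass == NONSPECIFIC_PRIMERS:
            g = xh_pool.pop(0)
            partner = gene_by_id[g.gene_id[:-1] + "b"]
            fwd, rev = design_for_gene(g, FLANK_LEN, widen=False)
            add_clone(i, g.gene_id, fwd, rev, g.gene_id, klass,
                      [g.gene_id, partner.gene_id])
        elif klass == INTERGENIC_AMPLICON:
            g = pool.pop()
            # the intended defect is a single gene-free product, so a
            # draw whose primers also hit a stray near-match site (and
            # could drag genes into a secondary product) is redrawn
            for _ in range(20):
                chrom_id, start, end = deserts[rng.randrange(len(deserts))]
                length = min(end - start - 100, rng.randint(500, 900))
                offset = rng.randint(0, end - start - length - 50)
                region = chrom_seq[chrom_id][start + offset : start + offset + length]
                pair = _design_pair_on_region(region, thermo, 60, 60)
                if pair is None:
                    continue
                probe = CloneRecord(g.gene_id, pair[0], pair[1], g.gene_id,
                                    _well_location(i, plate_labels))
                if len(enumerate_amplicons(probe, genome, thermo=thermo)) == 1:
                    break
            else:
                raise ValueError("no valid primer pair inside gene desert")
            add_clone(i, g.gene_id, pair[0], pair[1], g.gene_id, klass, [])
        elif klass == EMPTY_VECTOR:
            g = pool.pop()
            while True:
                fwd = _random_dna(rng, 21)
                rev = _random_dna(rng, 21)
                if any(fwd in s or rev in s for s in chrom_seq.values()):
                    continue
                probe = CloneRecord(g.gene_id, fwd, rev, g.gene_id,
                                    _well_location(i, plate_labels))
                if not enumerate_amplicons(probe, genome, thermo=thermo):
                    break
            add_clone(i, g.gene_id, fwd, rev, g.gene_id, klass, [])
        elif klass == RETIRED_REMAPPED:
            old = retired_pool.pop()
            for _ in range(10):
                successor = normal_alive[rng.randrange(len(normal_alive))]
                fwd, rev = design_for_gene(successor, 60)
                if unique_amplifier(successor.gene_id, fwd, rev, i):
                    break
            else:
                raise ValueError("no uniquely amplifying successor for retired clone")
            add_clone(i, old.gene_id, fwd, rev, old.gene_id, klass,
                      [successor.gene_id])
    for i, (axis, offset, target) in sorted(shift_plan.items()):
        donor = clones[target]
        g = pool.pop()
        add_clone(i, g.gene_id, donor.fwd_primer, donor.rev_primer, g.gene_id,
                  LOADING_SHIFT, [donor.annotated_gene],
                  shift=(axis, offset, donor.annotated_gene))

    ordered = [clones[i] for i in sorted(clones)]
    truth = pd.DataFrame(truth_rows)
    truth = truth.set_index("clone_name").loc[[c.clone_name for c in ordered]].reset_index()
    return ordered, truth


def simulate_sequencing(
    clones: Sequence[CloneRecord],
    ground_truth: pd.DataFrame,
    misread_rate: float = 0.0,
    seed: int = 0,
) -> list[ValidationRecord]:
    """Simulate direct-sequencing validation of the library.

    Each clone's true defect class maps deterministically onto the
    validation taxonomy (reliable / remapped-retired / remapped-wrong-
    insert / unreliable); with probability ``misread_rate`` the outcome
    is replaced by a different one, emulating sequencing or bookkeeping
    error. Deterministic per seed.
    """
    if not (0.0 <= misread_rate < 1.0):
        raise ValueError("misread_rate must be in [0, 1)")
    rng = random.Random(seed)
    by_name = dict(zip(ground_truth["clone_name"], ground_truth["class"]))
    records = []
    for clone in clones:
        outcome = _TRUTH_TO_OUTCOME[by_name[clone.clone_name]]
        if misread_rate and rng.random() < misread_rate:
            outcome = rng.choice([o for o in OUTCOMES if o != outcome])
        records.append(ValidationRecord(clone.clone_name, outcome))
    return records
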