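"""CDR3 extraction and two-stage clonotype classification.

The CDR3 of a rearranged TCR/IG sequence begins at the last cysteine codon
of the V segment and ends at the conserved [FW]-G-X-G motif of the J
segment.  Both anchors are located once on the reference genes
(:mod:`lymprofiler.reference`) and mapped onto each read through its
ungapped V/J alignments.  The extracted region runs from the first base of
the Cys codon through the last base of the [FW] codon, inclusive.

Reads sharing the same V(D)J assignment and an identical CDR3 nucleotide
sequence form a clonotype.  Classification is two-stage: exact grouping
first, then rare clonotypes (count below an adjustable fraction of the
CDR3-bearing reads, default 0.001%) are labelled *minimum sequences* and
merged into a *core* clonotype of the same V(D)J genes and CDR3 length when
their Hamming distance is strictly less than M (default 2) — an error
correction step for PCR/sequencing artefacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .align import AlignmentHit, ReadAnnotation
from .reference import ReferenceDatabase, translate_codon


def extract_cdr3(
    read: str,
    v_hit: AlignmentHit,
    j_hit: AlignmentHit,
    db: ReferenceDatabase,
) -> tuple[Optional[str], str]:
    """Extract the CDR3 from a mapped read.

    Returns ``(cdr3_nt, status)``; the sequence is None with an explanatory
    status when the V gene lacks a Cys annotation, the Cys codon falls
    outside the aligned region, the J motif is absent from the read, or the
    two anchors are inverted.
    """
    v_gene = db[v_hit.gene_id]
    j_gene = db[j_hit.gene_id]
    cys = v_gene.cys_codon_start
    if cys is None:
        return None, "cys_missing"
    if not (v_hit.gene_start <= cys and cys + 3 <= v_hit.gene_end):
        return None, "cys_missing"
    read_cys = v_hit.read_start + (cys - v_hit.gene_start)
    motif_start = j_gene.fwgxg_start
    if motif_start is None:
        return None, "motif_missing"
    motif = j_gene.sequence[motif_start : motif_start + 12]
    idx = read.find(motif, j_hit.read_start, j_hit.read_end)
    if idx == -1:
        return None, "motif_not_found"
    end = idx + 3  # through the last base of the [FW] codon
    if end <= read_cys:
        return None, "inverted_boundaries"
    return read[read_cys:end], "ok"


def translate_cdr3(cdr3_nt: str) -> Optional[str]:
    """Standard-code translation from base 0; None when out of frame.

    Codons containing N (or any non-ACGT character) translate to X.
    """
    if len(cdr3_nt) % 3 != 0 or not cdr3_nt:
        return None
    return "".join(
        translate_codon(cdr3_nt[i : i + 3]) for i in range(0, len(cdr3_nt), 3)
    )


def annotate_cdr3(ann: ReadAnnotation, db: ReferenceDatabase) -> ReadAnnotation:
    """Fill cdr3_nt / cdr3_aa on a mapped annotation in place."""
    if not ann.mapped:
        return ann
    cdr3, status = extract_cdr3(ann.sequence, ann.v_hit, ann.j_hit, db)
    ann.cdr3_nt = cdr3
    if status != "ok":
        ann.status = status
    elif cdr3:
        ann.cdr3_aa = translate_cdr3(cdr3)
    return ann


@dataclass
class Clonotype:
    """A V(D)J + CDR3 equivalence class with its read support."""

    v_gene: str
    j_gene: str
    cdr3_nt: str
    d_gene: Optional[str] = None
    count: int = 0
    member_reads: list[str] = field(default_factory=list)
    is_core: bool = True

    @property
    def key(self) -> tuple[str, Optional[str], str, str]:
        return (self.v_gene, self.d_gene, self.j_gene, self.cdr3_nt)

    @property
    def cdr3_aa(self) -> Optional[str]:
        return translate_cdr3(self.cdr3_nt)


@dataclass
class RepertoireProfile:
    """Clonotype table plus the read-accounting totals of one run."""

    clonotypes: list[Clonotype] = field(default_factory=list)
    total_reads: int = 0
    mapped_reads: int = 0
    cdr3_reads: int = 0
    merge_log: list[tuple[str, str]] = field(default_factory=list)

    def sorted_clonotypes(self) -> list[Clonotype]:
        return sorted(self.clonotypes, key=lambda c: (-c.count, c.cdr3_nt))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def classify_clonotypes(
    annotations: Iterable[ReadAnnotation],
    min_core_frac: float = 0.00001,
    M: int = 2,
) -> RepertoireProfile:
    """Group reads into clonotypes and merge minimum sequences into cores.

    Stage 1 groups CDR3-bearing reads exactly by (V, D, J, CDR3).  Stage 2
    labels clonotypes with count < min_core_frac x (CDR3-bearing reads) as
    minimum sequences; each is merged into the closest core of identical
    V(D)J genes and CDR3 length at Hamming distance strictly below M
    (closest distance, then largest pre-merge core count, then
    lexicographic CDR3).  The core set is fixed after labelling; merged
    minima are never re-promoted.  Counts are conserved.
    """
    total = mapped = 0
    groups: dict[tuple, Clonotype] = {}
    for ann in annotations:
        total += 1
        if ann.mapped:
            mapped += 1
        if not ann.cdr3_nt:
            continue
        key = (
            ann.v_hit.gene_id,
            ann.d_hit.gene_id if ann.d_hit else None,
            ann.j_hit.gene_id,
            ann.cdr3_nt,
        )
        clone = groups.get(key)
        if clone is None:
            clone = Clonotype(
                v_gene=key[0], d_gene=key[1], j_gene=key[2], cdr3_nt=key[3]
            )
            groups[key] = clone
        clone.count += 1
        clone.member_reads.append(ann.read_id)

    cdr3_reads = sum(c.count for c in groups.values())
    threshold = min_core_frac * cdr3_reads
    cores: list[Clonotype] = []
    minima: list[Clonotype] = []
    for clone in groups.values():
        if clone.count < threshold:
            clone.is_core = False
            minima.append(clone)
        else:
            cores.append(clone)

    # index cores by (V, D, J, CDR3 length); snapshot counts for tie-breaks
    core_index: dict[tuple, list[Clonotype]] = {}
    core_count_at_labelling = {id(c): c.count for c in cores}
    for c in cores:
        core_index.setdefault(
            (c.v_gene, c.d_gene, c.j_gene, len(c.cdr3_nt)), []
        ).append(c)

    merge_log: list[tuple[str, str]] = []
    kept: list[Clonotype] = list(cores)
    for clone in sorted(minima, key=lambda c: (-c.count, c.cdr3_nt)):
        candidates = core_index.get(
            (clone.v_gene, clone.d_gene, clone.j_gene, len(clone.cdr3_nt)), []
        )
        best: Optional[tuple[int, int, str, Clonotype]] = None
        for core in candidates:
            d = hamming(clone.cdr3_nt, core.cdr3_nt)
            if d >= M:
                continue
            rank = (d, -core_count_at_labelling[id(core)], core.cdr3_nt, core)
            if best is None or rank[:3] < best[:3]:
                best = rank
        if best is None:
            kept.append(clone)
        else:
            core = best[3]
            core.count += clone.count
            core.member_reads.extend(clone.member_reads)
            merge_log.append((clone.cdr3_nt, core.cdr3_nt))

    return RepertoireProfile(
        clonotypes=kept,
        total_reads=total,
        mapped_reads=mapped,
        cdr3_reads=cdr3_reads,
        merge_log=merge_log,
    )


CLONOTYPE_COLUMNS = [
    "rank",
    "count",
    "fraction",
    "v_gene",
    "d_gene",
    "j_gene",
    "cdr3_nt",
    "cdr3_aa",
    "frame_flag",
]


def write_clonotype_table(profile: RepertoireProfile, path) -> None:
    """TSV of clonotypes sorted by descending count, then CDR3."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CLONOTYPE_COLUMNS)
        for rank, clone in enumerate(profile.sorted_clonotypes(), start=1):
            aa = clone.cdr3_aa
            writer.writerow(
                [
                    rank,
                    clone.count,
                    f"{clone.count / profile.cdr3_reads:.6g}"
                    if profile.cdr3_reads
                    else "0",
                    clone.v_gene,
                    clone.d_gene or "",
                    clone.j_gene,
                    clone.cdr3_nt,
                    aa or "",
                    "in-frame" if aa is not None else "out-of-frame",
                ]
            )
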