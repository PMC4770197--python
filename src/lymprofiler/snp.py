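"""Novel-allele (SNP) detection from accumulated alignment mismatches.

A germline polymorphism absent from the reference database shows up as the
same mismatch recurring across many reads of one gene.  To separate such
variants from PCR/sequencing errors and somatic mutation, a candidate must
satisfy two criteria:

1. the variant recurs across multiple rearrangement partners — more than
   three distinct J genes for a V-gene variant, at least five distinct V
   genes for a J-gene variant (partners counted at gene-name level,
   allele-collapsed);
2. the non-reference base is seen in at least 10% of the reads covering
   that position of the gene.

Somatic point mutations are expected below ~5% (up to ~10% in G/C
hotspots), so true novel alleles — carried by every cell of the clone pool —
stand out.  Variants on D segments are not called: D is short and sits
inside the hypervariable CDR3.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .align import ReadAnnotation
from .reference import ReferenceDatabase


@dataclass
class SnpParams:
    """Calling thresholds (defaults follow the two criteria above)."""

    min_freq: float = 0.10
    min_j_partners_for_v: int = 4
    min_v_partners_for_j: int = 5

    def __post_init__(self) -> None:
        if self.min_freq <= 0 or self.min_j_partners_for_v <= 0 or (
            self.min_v_partners_for_j <= 0
        ):
            raise ValueError("all SNP parameters must be positive")


@dataclass
class _VariantRecord:
    alt_count: int = 0
    partner_genes: set[str] = field(default_factory=set)


class _GeneRecord:
    __slots__ = ("coverage", "aligned_reads", "variants")

    def __init__(self, length: int):
        self.coverage = np.zeros(length, dtype=np.int64)
        self.aligned_reads = 0
        self.variants: dict[tuple[int, str], _VariantRecord] = {}


class MutationMap:
    """Nested per-gene store of observed mismatches and coverage."""

    def __init__(self, db: ReferenceDatabase):
        self.db = db
        self.genes: dict[str, _GeneRecord] = {}

    def _gene_record(self, gene_id: str) -> _GeneRecord:
        rec = self.genes.get(gene_id)
        if rec is None:
            rec = _GeneRecord(len(self.db[gene_id]))
            self.genes[gene_id] = rec
        return rec

    def add_hit(self, hit, partner_gene_name: str) -> None:
        rec = self._gene_record(hit.gene_id)
        rec.aligned_reads += 1
        rec.coverage[hit.gene_start : hit.gene_end] += 1
        for pos, read_base in hit.mismatch_positions:
            var = rec.variants.get((pos, read_base))
            if var is None:
                var = _VariantRecord()
                rec.variants[(pos, read_base)] = var
            var.alt_count += 1
            var.partner_genes.add(partner_gene_name)


@dataclass
class SnpCandidate:
    """One putative novel-allele site passing both criteria."""

    gene_id: str
    position: int  # 0-based on the reference gene
    ref_base: str
    alt_base: str
    frequency: float
    alt_count: int
    coverage: int
    partner_gene_count: int


def collect_mismatches(
    annotations: Iterable[ReadAnnotation], db: ReferenceDatabase
) -> MutationMap:
    """Accumulate V- and J-hit mismatches of mapped reads into a MutationMap.

    Each mismatch inside a V (resp. J) alignment records the read's J (resp.
    V) gene name as the rearrangement partner; coverage counts every aligned
    position regardless of match.
    """
    mmap = MutationMap(db)
    for ann in annotations:
        if not ann.mapped:
            continue
        v_name = db[ann.v_hit.gene_id].gene_name
        j_name = db[ann.j_hit.gene_id].gene_name
        mmap.add_hit(ann.v_hit, j_name)
        mmap.add_hit(ann.j_hit, v_name)
    return mmap


def call_snps(mmap: MutationMap, params: SnpParams | None = None) -> list[SnpCandidate]:
    """Emit candidates passing the partner-count and frequency criteria."""
    params = params or SnpParams()
    out: list[SnpCandidate] = []
    for gene_id in sorted(mmap.genes):
        gene = mmap.db[gene_id]
        if gene.segment_class == "V":
            min_partners = params.min_j_partners_for_v
        elif gene.segment_class == "J":
            min_partners = params.min_v_partners_for_j
        else:
            continue  # D segments are not called
        rec = mmap.genes[gene_id]
        for (pos, alt), var in sorted(rec.variants.items()):
            cov = int(rec.coverage[pos])
            if cov == 0:
                continue
            freq = var.alt_count / cov
            if freq < params.min_freq:
                continue
            if len(var.partner_genes) < min_partners:
                continue
            out.append(
                SnpCandidate(
                    gene_id=gene_id,
                    position=pos,
                    ref_base=gene.sequence[pos],
                    alt_base=alt,
                    frequency=freq,
                    alt_count=var.alt_count,
                    coverage=cov,
                    partner_gene_count=len(var.partner_genes),
                )
            )
    return out


SNP_COLUMNS = [
    "gene_id",
    "position",
    "ref",
    "alt",
    "frequency_pct",
    "alt_count",
    "coverage",
    "partner_count",
]


def write_snp_report(candidates: Iterable[SnpCandidate], path) -> None:
    """TSV report; positions are 1-based, frequencies printed as percent."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SNP_COLUMNS)
        for cand in candidates:
            writer.writerow(
                [
                    cand.gene_id,
                    cand.position + 1,
                    cand.ref_base,
                    cand.alt_base,
                    f"{cand.frequency * 100:.2f}",
                    cand.alt_count,
                    cand.coverage,
                    cand.partner_gene_count,
                ]
            )
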