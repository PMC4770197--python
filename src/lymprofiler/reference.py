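"""Reference V/D/J gene databases and exact-match detection tags.

A reference database holds the germline V, D and J gene segments of one
receptor chain (e.g. TRB, IGH), typically taken from an IMGT-style FASTA
export.  Each segment is annotated on load with the features the rest of the
pipeline needs:

* V segments — the start of the last in-frame cysteine codon (TGT/TGC),
  which anchors the 5' end of the CDR3;
* J segments — the position of the 12-nt stretch encoding the conserved
  [FW]-G-X-G motif, which anchors the 3' end of the CDR3.

The aligner does not scan whole genes.  Instead each gene contributes a small
ordered set of fixed-length *detection tags* used for exact-match seeding:

* V genes: five 5-nt tags read from the 3' end inward (the 3' end of V is the
  part an amplicon read is guaranteed to cover);
* J genes: three 5-nt tags read from the 5' end inward;
* D genes: the terminal 3 nt of each end (D segments are only 12-16 bp).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Optional

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

SegmentClass = Literal["V", "D", "J"]

VALID_BASES = frozenset("ACGTN")
CYS_CODONS = ("TGT", "TGC")

#: D segments are short (12-16 bp); anything much longer is probably a
#: mis-classified record.
D_LENGTH_WARN = 40

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard code; ambiguous codons give X."""
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    if not set(codon) <= {"A", "C", "G", "T"}:
        return "X"
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


class DatabaseError(ValueError):
    """Raised for malformed or inconsistent reference databases."""


class TagError(ValueError):
    """Raised when a gene is too short for its tag scheme."""


@dataclass
class GeneSegment:
    """One reference V, D or J allele.

    ``gene_id`` is the full IMGT-style name ``gene*allele`` (e.g.
    ``TRBV2*02``); ``gene_name`` strips the allele suffix.
    """

    gene_id: str
    segment_class: SegmentClass
    chain: str
    sequence: str
    cys_codon_start: Optional[int] = None
    fwgxg_start: Optional[int] = None

    @property
    def gene_name(self) -> str:
        return self.gene_id.split("*", 1)[0]

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"{self.gene_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise DatabaseError(
                f"{self.gene_id}: invalid bases {sorted(bad)} in sequence"
            )
        if self.segment_class == "V" and self.cys_codon_start is not None:
            codon = self.sequence[self.cys_codon_start : self.cys_codon_start + 3]
            if codon not in CYS_CODONS:
                raise DatabaseError(
                    f"{self.gene_id}: cys_codon_start does not point at TGT/TGC"
                )
        if self.segment_class == "D" and len(self.sequence) > D_LENGTH_WARN:
            logger.warning(
                "D segment %s is %d nt (expected 12-16)", self.gene_id, len(self)
            )


@dataclass
class TagSet:
    """Ordered exact-match detection tags of one reference gene."""

    gene_id: str
    tags: list[str]
    tag_len: int
    anchors: list[int]
    orientation: Literal["from_3prime", "from_5prime", "dual_end"]

    def __iter__(self) -> Iterator[tuple[int, str, int]]:
        """Yield (1-based tag number, tag, anchor) in search order."""
        for i, (tag, anchor) in enumerate(zip(self.tags, self.anchors), start=1):
            yield i, tag, anchor


class ReferenceDatabase:
    """Validated collection of GeneSegments keyed by gene_id."""

    def __init__(self, chain: str = "") -> None:
        self.chain = chain
        self.segments: dict[str, GeneSegment] = {}
        # caches built lazily by the aligner; invalidated on mutation
        self._align_cache: dict = {}

    def add(self, segment: GeneSegment) -> None:
        if segment.gene_id in self.segments:
            raise DatabaseError(f"duplicate gene_id {segment.gene_id}")
        segment.validate()
        self.segments[segment.gene_id] = segment
        self._align_cache.clear()
        if not self.chain:
            self.chain = segment.chain

    def __getitem__(self, gene_id: str) -> GeneSegment:
        return self.segments[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.segments

    def __len__(self) -> int:
        return len(self.segments)

    def by_class(self, segment_class: SegmentClass) -> list[GeneSegment]:
        """Segments of one class, sorted by gene_id (deterministic order)."""
        return sorted(
            (s for s in self.segments.values() if s.segment_class == segment_class),
            key=lambda s: s.gene_id,
        )

    @property
    def v_genes(self) -> list[GeneSegment]:
        return self.by_class("V")

    @property
    def d_genes(self) -> list[GeneSegment]:
        return self.by_class("D")

    @property
    def j_genes(self) -> list[GeneSegment]:
        return self.by_class("J")

    def validate(self) -> "ReferenceDatabase":
        if not self.segments:
            raise DatabaseError("empty reference database")
        if not self.v_genes or not self.j_genes:
            raise DatabaseError("database must contain at least one V and one J gene")
        return self

    def annotate(self) -> "ReferenceDatabase":
        """Locate CDR3 anchors: last Cys codon on V, [FW]GXG motif on J."""
        for gene in self.v_genes:
            gene.cys_codon_start = locate_last_cysteine(gene)
            if gene.cys_codon_start is None:
                logger.warning(
                    "V gene %s has no in-frame cysteine codon; "
                    "CDR3 extraction disabled for it",
                    gene.gene_id,
                )
        for gene in self.j_genes:
            gene.fwgxg_start = locate_fwgxg_motif(gene.sequence)
            if gene.fwgxg_start is None:
                logger.warning(
                    "J gene %s has no [FW]GXG motif; "
                    "CDR3 extraction disabled for it",
                    gene.gene_id,
                )
        return self

    def write_fasta(self, path) -> None:
        """Dump the validated database as plain-header FASTA."""
        with open(path, "w") as handle:
            for gene_id in sorted(self.segments):
                handle.write(f">{gene_id}\n{self.segments[gene_id].sequence}\n")


_ALPHA_PREFIX = re.compile(r"^[A-Za-z]+")


def infer_segment_class(gene_name: str) -> Optional[SegmentClass]:
    """Infer V/D/J from an IMGT-style gene name.

    The segment letter is the last V/D/J in the leading alphabetic prefix,
    so delta-chain names like TRDV1 resolve to V, not D.
    """
    m = _ALPHA_PREFIX.match(gene_name)
    if not m:
        return None
    for ch in reversed(m.group(0).upper()):
        if ch in "VDJ":
            return ch  # type: ignore[return-value]
    return None


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_reference_fasta(
    path, dialect: Literal["imgt", "plain"] = "imgt"
) -> ReferenceDatabase:
    """Load a reference gene database from FASTA.

    dialect="imgt" expects pipe-delimited headers with ``gene*allele`` in the
    second field (and optionally a ``V-REGION``-style field naming the
    segment class); dialect="plain" takes the first whitespace token of the
    header as the gene_id.  IMGT alignment dots are stripped and sequences
    uppercased.
    """
    db = ReferenceDatabase()
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            header = record.description
            region_class: Optional[SegmentClass] = None
            if dialect == "imgt":
                fields = header.split("|")
                if len(fields) < 2 or "*" not in fields[1]:
                    raise DatabaseError(
                        f"malformed IMGT header (no gene*allele field): {header!r}"
                    )
                gene_id = fields[1].strip()
                for f in fields[2:]:
                    m = re.match(r"\s*([VDJ])-REGION", f.strip(), re.IGNORECASE)
                    if m:
                        region_class = m.group(1).upper()  # type: ignore[assignment]
                        break
            else:
                gene_id = header.split()[0] if header.split() else ""
            if not gene_id:
                raise DatabaseError(f"record with empty identifier: {header!r}")
            sequence = str(record.seq).replace(".", "").upper()
            if not sequence:
                raise DatabaseError(f"record {gene_id}: empty sequence")
            bad = set(sequence) - VALID_BASES
            if bad:
                raise DatabaseError(
                    f"record {gene_id}: invalid characters {sorted(bad)}"
                )
            segment_class = region_class or infer_segment_class(gene_id)
            if segment_class is None:
                raise DatabaseError(
                    f"record {gene_id}: cannot infer segment class (V/D/J)"
                )
            m = _ALPHA_PREFIX.match(gene_id)
            prefix = m.group(0).upper() if m else ""
            idx = prefix.rfind(segment_class)
            chain = prefix[:idx] if idx > 0 else prefix
            db.add(
                GeneSegment(
                    gene_id=gene_id,
                    segment_class=segment_class,
                    chain=chain,
                    sequence=sequence,
                )
            )
    db.validate()
    db.annotate()
    return db


def locate_last_cysteine(gene: GeneSegment, frame_offset: int = 0) -> Optional[int]:
    """0-based start of the last in-frame TGT/TGC codon, or None.

    The supplied V sequence is assumed to begin in frame 1 (offset 0), as
    IMGT V-REGION records do; ``frame_offset`` shifts the frame.
    """
    if gene.segment_class != "V":
        raise ValueError("locate_last_cysteine applies to V segments")
    seq = gene.sequence
    last = None
    for i in range(frame_offset, len(seq) - 2, 3):
        if seq[i : i + 3] in CYS_CODONS:
            last = i
    return last


def locate_fwgxg_motif(sequence: str) -> Optional[int]:
    """0-based start of the first 12-nt window encoding [FW]-G-X-G, or None.

    The reading frame of a J record is not assumed; every offset is tried.
    Twelve nucleotides suffice to make the motif effectively unique within a
    receptor sequence, so the window doubles as the read-side search string.
    """
    for i in range(len(sequence) - 11):
        aa0 = translate_codon(sequence[i : i + 3])
        if aa0 not in ("F", "W"):
            continue
        if (
            translate_codon(sequence[i + 3 : i + 6]) == "G"
            and translate_codon(sequence[i + 9 : i + 12]) == "G"
        ):
            return i
    return None


def build_v_tagset(gene: GeneSegment, n_tags: int = 5, tag_len: int = 5) -> TagSet:
    """Detection tags of a V gene: adjacent tag_len-mers from the 3' end inward."""
    if gene.segment_class != "V":
        raise ValueError("build_v_tagset applies to V segments")
    if len(gene) < n_tags * tag_len:
        raise TagError(
            f"{gene.gene_id}: {len(gene)} nt is too short for "
            f"{n_tags} tags of {tag_len} nt"
        )
    anchors = [len(gene) - i * tag_len for i in range(1, n_tags + 1)]
    tags = [gene.sequence[a : a + tag_len] for a in anchors]
    return TagSet(gene.gene_id, tags, tag_len, anchors, "from_3prime")


def build_j_tagset(gene: GeneSegment, n_tags: int = 3, tag_len: int = 5) -> TagSet:
    """Detection tags of a J gene: adjacent tag_len-mers from the 5' end inward."""
    if gene.segment_class != "J":
        raise ValueError("build_j_tagset applies to J segments")
    if len(gene) < n_tags * tag_len:
        raise TagError(
            f"{gene.gene_id}: {len(gene)} nt is too short for "
            f"{n_tags} tags of {tag_len} nt"
        )
    anchors = [i * tag_len for i in range(n_tags)]
    tags = [gene.sequence[a : a + tag_len] for a in anchors]
    return TagSet(gene.gene_id, tags, tag_len, anchors, "from_5prime")


def build_d_tags(gene: GeneSegment, tag_len: int = 3) -> TagSet:
    """Dual-end detection tags of a D gene (3'-terminal first, then 5').

    Degenerate D segments shorter than two tags fall back to a single tag
    spanning the whole sequence.
    """
    if gene.segment_class != "D":
        raise ValueError("build_d_tags applies to D segments")
    if len(gene) < 2 * tag_len:
        logger.warning(
            "D gene %s (%d nt) shorter than two %d-nt tags; "
            "using the whole sequence as a single tag",
            gene.gene_id,
            len(gene),
            tag_len,
        )
        return TagSet(gene.gene_id, [gene.sequence], len(gene), [0], "dual_end")
    anchors = [len(gene) - tag_len, 0]
    tags = [gene.sequence[a : a + tag_len] for a in anchors]
    return TagSet(gene.gene_id, tags, tag_len, anchors, "dual_end")
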