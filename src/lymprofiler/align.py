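"""Seed-and-extend exact-tag alignment of reads to reference V/D/J segments.

Each reference gene is reduced to a handful of short detection tags
(:mod:`lymprofiler.reference`).  Tags are tried in order; the first tag with
an exact occurrence in the read seeds an ungapped extension anchored at that
occurrence.  The extension covers the whole overlap between gene and read
(no X-drop, no indels) and is scored by Hamming-style match counting — the
number of matches and the percentage of matches over the overlap.  A gene
joins the candidate set when both the identity fraction and the absolute
match count pass class-specific thresholds (defaults: 90% identity with
30/20/10 bp matched for V/J/D); the winner is the candidate with the highest
identity.

D segments are handled after V and J: only the read interval between the V
and J alignments is searched, with 3-nt tags at both D ends, because D genes
are short, mutually similar and sit inside the hypervariable CDR3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .reference import (
    GeneSegment,
    ReferenceDatabase,
    SegmentClass,
    TagError,
    TagSet,
    build_d_tags,
    build_j_tagset,
    build_v_tagset,
)

logger = logging.getLogger(__name__)

_N_BYTE = ord("N")

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """View a nucleotide string as a uint8 array for fast comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class AlignerParams:
    """Thresholds and tag-scheme parameters of the aligner.

    ``min_identity`` is the minimum fraction of matching bases over the
    gene/read overlap; ``min_match_*`` are the minimum absolute numbers of
    matching bases per segment class.
    """

    min_identity: float = 0.90
    min_match_v: int = 30
    min_match_j: int = 20
    min_match_d: int = 10
    n_tags_v: int = 5
    n_tags_j: int = 3
    tag_len: int = 5
    d_tag_len: int = 3
    try_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        for name in ("min_match_v", "min_match_j", "min_match_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_match(self, segment_class: SegmentClass) -> int:
        return {
            "V": self.min_match_v,
            "J": self.min_match_j,
            "D": self.min_match_d,
        }[segment_class]


@dataclass
class AlignmentHit:
    """Ungapped alignment of a read interval to a reference gene interval."""

    gene_id: str
    read_start: int
    read_end: int
    gene_start: int
    gene_end: int
    matched_bases: int
    aligned_length: int
    mismatch_positions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.matched_bases / self.aligned_length

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.aligned_length:
            raise ValueError("read interval inconsistent with aligned_length")
        if self.gene_end - self.gene_start != self.aligned_length:
            raise ValueError("gene interval inconsistent with aligned_length")


@dataclass
class ReadAnnotation:
    """Per-read outcome: segment assignments, strand and (later) CDR3."""

    read_id: str
    sequence: str  # read in the aligned orientation
    strand: str = "+"
    v_hit: Optional[AlignmentHit] = None
    d_hit: Optional[AlignmentHit] = None
    j_hit: Optional[AlignmentHit] = None
    mapped: bool = False
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    status: str = "mapped"


class _GeneEntry:
    """Precomputed per-gene state used by the aligner."""

    __slots__ = ("gene", "arr", "tagset")

    def __init__(self, gene: GeneSegment, tagset: TagSet):
        self.gene = gene
        self.arr = encode(gene.sequence)
        self.tagset = tagset


def _build_index(
    db: ReferenceDatabase, segment_class: SegmentClass, params: AlignerParams
) -> list[_GeneEntry]:
    """Tag sets + byte arrays for one segment class, cached on the database."""
    key = (
        segment_class,
        params.n_tags_v,
        params.n_tags_j,
        params.tag_len,
        params.d_tag_len,
    )
    cached = db._align_cache.get(key)
    if cached is not None:
        return cached
    entries: list[_GeneEntry] = []
    for gene in db.by_class(segment_class):
        try:
            if segment_class == "V":
                tagset = build_v_tagset(gene, params.n_tags_v, params.tag_len)
            elif segment_class == "J":
                tagset = build_j_tagset(gene, params.n_tags_j, params.tag_len)
            else:
                tagset = build_d_tags(gene, params.d_tag_len)
        except TagError as exc:
            logger.warning("excluding %s from alignment: %s", gene.gene_id, exc)
            continue
        entries.append(_GeneEntry(gene, tagset))
    db._align_cache[key] = entries
    return entries


def find_tag_seeds(read: str, tagset: TagSet) -> list[tuple[int, int]]:
    """All exact occurrences of each tag, in tag order.

    Returns (1-based tag number, read position) pairs; callers consume the
    seeds tag-by-tag — every T1 occurrence first, then T2, and so on.
    """
    seeds: list[tuple[int, int]] = []
    for tag_no, tag, _anchor in tagset:
        start = read.find(tag)
        while start != -1:
            seeds.append((tag_no, start))
            start = read.find(tag, start + 1)
    return seeds


def _score_offset(
    read_arr: np.ndarray,
    gene_arr: np.ndarray,
    offset: int,
    lo: int = 0,
    hi: Optional[int] = None,
) -> Optional[tuple[int, int, int]]:
    """Match count of the full gene/read overlap at a fixed offset.

    ``offset`` is the read coordinate of gene position 0; the overlap is
    optionally clipped to read window [lo, hi).  Returns
    (gene_start, gene_end, matched) or None when the overlap is empty.
    N never matches anything.
    """
    if hi is None:
        hi = len(read_arr)
    gene_start = max(0, lo - offset)
    gene_end = min(len(gene_arr), hi - offset)
    if gene_end <= gene_start:
        return None
    g = gene_arr[gene_start:gene_end]
    r = read_arr[gene_start + offset : gene_end + offset]
    eq = g == r
    # an N in the gene can only "equal" an N in the read; neither counts
    eq &= g != _N_BYTE
    return gene_start, gene_end, int(np.count_nonzero(eq))


def _mismatches(
    read: str, gene: GeneSegment, gene_start: int, gene_end: int, offset: int
) -> list[tuple[int, str]]:
    out = []
    seq = gene.sequence
    for gp in range(gene_start, gene_end):
        rb = read[gp + offset]
        gb = seq[gp]
        if rb != gb or gb == "N":
            out.append((gp, rb))
    return out


def extend_seed(
    read: str,
    gene: GeneSegment,
    seed: tuple[int, int],
    tagset: TagSet,
) -> AlignmentHit:
    """Extend an exact tag occurrence to the full-overlap ungapped hit."""
    tag_no, read_pos = seed
    tag = tagset.tags[tag_no - 1]
    if read[read_pos : read_pos + len(tag)] != tag:
        raise ValueError(
            f"inconsistent seed: tag {tag_no} of {gene.gene_id} "
            f"not at read position {read_pos}"
        )
    offset = read_pos - tagset.anchors[tag_no - 1]
    scored = _score_offset(encode(read), encode(gene.sequence), offset)
    assert scored is not None  # the tag itself overlaps
    gene_start, gene_end, matched = scored
    return AlignmentHit(
        gene_id=gene.gene_id,
        read_start=gene_start + offset,
        read_end=gene_end + offset,
        gene_start=gene_start,
        gene_end=gene_end,
        matched_bases=matched,
        aligned_length=gene_end - gene_start,
        mismatch_positions=_mismatches(read, gene, gene_start, gene_end, offset),
    )


def _better(matched_a: int, len_a: int, matched_b: int, len_b: int) -> bool:
    """identity then matched_bases ordering, compared exactly (cross-mult)."""
    ia = matched_a * len_b
    ib = matched_b * len_a
    if ia != ib:
        return ia > ib
    return matched_a > matched_b


def _best_for_gene(
    read: str,
    read_arr: np.ndarray,
    entry: _GeneEntry,
    min_identity: float,
    min_match: int,
    lo: int = 0,
    hi: Optional[int] = None,
) -> Optional[tuple[int, int, int, int]]:
    """Best passing (gene_start, gene_end, matched, offset) for one gene.

    Tags are tried in order; each occurrence of the current tag is extended
    and the best *threshold-passing* extension is the gene's candidate.  If
    no extension from that tag passes, later tags are still tried (a
    spurious seed counts as tag failure, not gene failure).  An offset that
    failed under an earlier tag is never rescored: the extension depends
    only on the offset, not on which tag seeded it.
    """
    window = read if hi is None and lo == 0 else read[lo : hi if hi is not None else len(read)]
    seen: set[int] = set()
    for tag_no, tag, anchor in entry.tagset:
        pos = window.find(tag)
        best: Optional[tuple[int, int, int, int]] = None
        while pos != -1:
            offset = pos + lo - anchor
            if offset not in seen:
                seen.add(offset)
                scored = _score_offset(read_arr, entry.arr, offset, lo, hi)
                if scored is not None:
                    gs, ge, matched = scored
                    alen = ge - gs
                    if matched >= min_match and matched >= min_identity * alen:
                        if best is None or _better(
                            matched, alen, best[2], best[1] - best[0]
                        ):
                            best = (gs, ge, matched, offset)
            pos = window.find(tag, pos + 1)
        if best is not None:
            return best
    return None


def _hit_from(
    read: str, entry: _GeneEntry, best: tuple[int, int, int, int]
) -> AlignmentHit:
    gs, ge, matched, offset = best
    return AlignmentHit(
        gene_id=entry.gene.gene_id,
        read_start=gs + offset,
        read_end=ge + offset,
        gene_start=gs,
        gene_end=ge,
        matched_bases=matched,
        aligned_length=ge - gs,
        mismatch_positions=_mismatches(read, entry.gene, gs, ge, offset),
    )


def align_segment(
    read: str,
    db: ReferenceDatabase,
    segment_class: SegmentClass,
    params: Optional[AlignerParams] = None,
    *,
    read_arr: Optional[np.ndarray] = None,
) -> Optional[AlignmentHit]:
    """Best V or J assignment for a read, or None.

    The winner is the candidate with the highest identity; ties go to more
    matched bases, then to the lexicographically smallest gene_id (genes are
    scanned in sorted order, so the first full tie wins).
    """
    params = params or AlignerParams()
    if not read:
        return None
    if read_arr is None:
        read_arr = encode(read)
    min_match = params.min_match(segment_class)
    best_entry: Optional[_GeneEntry] = None
    best: Optional[tuple[int, int, int, int]] = None
    for entry in _build_index(db, segment_class, params):
        cand = _best_for_gene(read, read_arr, entry, params.min_identity, min_match)
        if cand is None:
            continue
        if best is None or _better(
            cand[2], cand[1] - cand[0], best[2], best[1] - best[0]
        ):
            best, best_entry = cand, entry
    if best is None or best_entry is None:
        return None
    return _hit_from(read, best_entry, best)


def align_d(
    read: str,
    v_hit: AlignmentHit,
    j_hit: AlignmentHit,
    db: ReferenceDatabase,
    params: Optional[AlignerParams] = None,
    *,
    read_arr: Optional[np.ndarray] = None,
) -> Optional[AlignmentHit]:
    """Best D assignment inside the read interval between the V and J hits."""
    params = params or AlignerParams()
    lo, hi = v_hit.read_end, j_hit.read_start
    if hi - lo < params.min_match_d:
        return None
    if read_arr is None:
        read_arr = encode(read)
    best_entry: Optional[_GeneEntry] = None
    best: Optional[tuple[int, int, int, int]] = None
    for entry in _build_index(db, "D", params):
        cand = _best_for_gene(
            read, read_arr, entry, params.min_identity, params.min_match_d, lo, hi
        )
        if cand is None:
            continue
        if best is None or _better(
            cand[2], cand[1] - cand[0], best[2], best[1] - best[0]
        ):
            best, best_entry = cand, entry
    if best is None or best_entry is None:
        return None
    return _hit_from(read, best_entry, best)


def _matched_total(*hits: Optional[AlignmentHit]) -> int:
    return sum(h.matched_bases for h in hits if h is not None)


def align_read(
    read_id: str,
    read: str,
    db: ReferenceDatabase,
    params: Optional[AlignerParams] = None,
) -> ReadAnnotation:
    """Assign V, J (and D) segments to one read, trying both strands.

    A read is *mapped* when both a V and a J segment are assigned.  If the
    forward strand fails, the reverse complement is tried and the orientation
    with more total matched bases is kept.  D is attempted only on mapped
    reads of databases that have a D pool.
    """
    params = params or AlignerParams()
    read = read.upper()
    fwd_arr = encode(read)
    v = align_segment(read, db, "V", params, read_arr=fwd_arr)
    j = align_segment(read, db, "J", params, read_arr=fwd_arr)
    seq, strand, arr = read, "+", fwd_arr
    if (v is None or j is None) and params.try_reverse_complement:
        rc = reverse_complement(read)
        rc_arr = encode(rc)
        rv = align_segment(rc, db, "V", params, read_arr=rc_arr)
        rj = align_segment(rc, db, "J", params, read_arr=rc_arr)
        take_rc = (rv is not None and rj is not None) or _matched_total(
            rv, rj
        ) > _matched_total(v, j)
        if take_rc:
            v, j, seq, strand, arr = rv, rj, rc, "-", rc_arr
    mapped = v is not None and j is not None
    if mapped:
        status = "mapped"
    elif v is None and j is None:
        status = "no_vj"
    elif v is None:
        status = "no_v"
    else:
        status = "no_j"
    ann = ReadAnnotation(
        read_id=read_id,
        sequence=seq,
        strand=strand,
        v_hit=v,
        j_hit=j,
        mapped=mapped,
        status=status,
    )
    if mapped and db.d_genes and v.read_end <= j.read_start:
        ann.d_hit = align_d(seq, v, j, db, params, read_arr=arr)
    return ann
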