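"""End-to-end repertoire profiling: align -> CDR3 -> clonotypes -> SNPs/trees.

The pipeline mirrors the four functional components of the analysis:
V(D)J alignment, CDR3 extraction and classification, polymorphism analysis,
and (for IG chains) lineage mutation tree construction.  It is a thin
composition of the library modules — running the stages by hand through the
API yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

from .align import AlignerParams, ReadAnnotation, align_read
from .cdr3 import RepertoireProfile, annotate_cdr3, classify_clonotypes, write_clonotype_table
from .lineage import TreeParams, build_lineage_tree, identify_roots, to_newick
from .reference import ReferenceDatabase, load_reference_fasta
from .snp import SnpParams, call_snps, collect_mismatches, write_snp_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    reads_path: Path
    out_dir: Path
    reference_path: Optional[Path] = None
    reference_dialect: str = "imgt"
    synthetic_reference: Optional[dict] = None  # kwargs for the simulator
    aligner: AlignerParams = field(default_factory=AlignerParams)
    min_core_frac: float = 0.00001
    merge_m: int = 2
    snp_params: SnpParams = field(default_factory=SnpParams)
    tree_params: TreeParams = field(default_factory=TreeParams)
    enable_snp: bool = True
    enable_trees: Optional[bool] = None  # None: on for IG chains
    dump_unmapped: bool = False
    seed: int = 0


@dataclass
class RunResult:
    profile: RepertoireProfile
    annotations: list[ReadAnnotation]
    summary: dict
    db: ReferenceDatabase


def iter_reads(path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA/FASTQ, plain or gzipped."""
    path = Path(path)
    suffixes = path.suffixes
    gzipped = suffixes and suffixes[-1] == ".gz"
    stem = suffixes[-2] if gzipped and len(suffixes) >= 2 else (
        suffixes[-1] if suffixes else ""
    )
    fmt = "fastq" if stem.lower() in (".fastq", ".fq") else "fasta"
    opener = gzip.open if gzipped else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, fmt):
            yield record.id, str(record.seq).upper()


def load_database(config: RunConfig) -> ReferenceDatabase:
    if config.reference_path is not None:
        return load_reference_fasta(config.reference_path, config.reference_dialect)
    if config.synthetic_reference is not None:
        from .simulate import generate_synthetic_reference

        kwargs = dict(config.synthetic_reference)
        kwargs.setdefault("seed", config.seed)
        return generate_synthetic_reference(**kwargs)
    raise ValueError("config needs reference_path or synthetic_reference")


def _safe_name(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "-", text)


def write_lineage_trees(
    annotations: list[ReadAnnotation], tree_params: TreeParams, out_dir: Path
) -> int:
    """One Newick file per rooted V/J group plus an index TSV; returns count."""
    tree_dir = out_dir / "trees"
    tree_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for rank, group in enumerate(identify_roots(annotations), start=1):
        tree = build_lineage_tree(
            group.root_sequence,
            group.members,
            tree_params,
            root_count=group.root_count,
        )
        max_layer = max(node.layer for node in tree.walk())
        n_members = sum(
            1 for node in tree.walk() if not node.is_hypothetical
        ) - 1
        fname = f"{_safe_name(group.v_gene)}_{_safe_name(group.j_gene)}_root{rank}.nwk"
        (tree_dir / fname).write_text(to_newick(tree) + "\n")
        index_rows.append((fname, group.root_sequence, n_members, max_layer))
    with open(tree_dir / "index.tsv", "w") as handle:
        handle.write("tree_file\troot_sequence\tmember_count\tmax_layer\n")
        for row in index_rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
    return len(index_rows)


def run_profile(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write the run artifacts.

    Writes clonotypes.tsv, summary.json and, when enabled, snps.tsv and
    trees/*.nwk under ``config.out_dir``.  A read failing any stage is
    recorded (with a reason code) and never aborts the run.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    db = load_database(config)
    timings["load_reference"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    annotations: list[ReadAnnotation] = []
    for read_id, seq in iter_reads(config.reads_path):
        ann = align_read(read_id, seq, db, config.aligner)
        annotate_cdr3(ann, db)
        annotations.append(ann)
    timings["align_and_cdr3"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    profile = classify_clonotypes(annotations, config.min_core_frac, config.merge_m)
    write_clonotype_table(profile, out_dir / "clonotypes.tsv")
    timings["classify"] = time.perf_counter() - t0

    n_snps = None
    if config.enable_snp:
        t0 = time.perf_counter()
        candidates = call_snps(collect_mismatches(annotations, db), config.snp_params)
        write_snp_report(candidates, out_dir / "snps.tsv")
        n_snps = len(candidates)
        timings["snp_calling"] = time.perf_counter() - t0

    enable_trees = config.enable_trees
    if enable_trees is None:
        enable_trees = db.chain.upper().startswith("IG")
    n_trees = None
    if enable_trees:
        t0 = time.perf_counter()
        n_trees = write_lineage_trees(annotations, config.tree_params, out_dir)
        timings["lineage_trees"] = time.perf_counter() - t0

    if config.dump_unmapped:
        with open(out_dir / "unmapped.tsv", "w") as handle:
            handle.write("read_id\tstatus\n")
            for ann in annotations:
                if not ann.mapped:
                    handle.write(f"{ann.read_id}\t{ann.status}\n")

    summary = {
        "total_reads": profile.total_reads,
        "mapped_reads": profile.mapped_reads,
        "cdr3_reads": profile.cdr3_reads,
        "clonotype_count": len(profile.clonotypes),
        "merged_minimum_sequences": len(profile.merge_log),
        "snp_candidates": n_snps,
        "lineage_trees": n_trees,
        "chain": db.chain,
        "parameters": {
            "aligner": dataclasses.asdict(config.aligner),
            "min_core_frac": config.min_core_frac,
            "merge_m": config.merge_m,
            "snp": dataclasses.asdict(config.snp_params),
            "tree": dataclasses.asdict(config.tree_params),
            "seed": config.seed,
        },
        "timings_sec": {k: round(v, 4) for k, v in timings.items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return RunResult(profile=profile, annotations=annotations, summary=summary, db=db)
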