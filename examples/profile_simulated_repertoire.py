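"""Profile a simulated TCR repertoire end to end.

Builds a synthetic reference (20 V genes x 2 alleles, 2 D, 13 J), simulates
3,000 reads at the low mismatch level, runs the full pipeline (alignment,
CDR3 extraction, clonotype classification, SNP screen) and prints the run
summary plus the top clonotypes.
"""

import tempfile
from pathlib import Path

from lymprofiler import RunConfig, run_profile
from lymprofiler.simulate import (
    SimulationConfig,
    generate_synthetic_reference,
    simulate_reads,
    write_reads_fasta,
)

workdir = Path(tempfile.mkdtemp(prefix="lymprofiler_example_"))

db = generate_synthetic_reference(n_v=20, n_d=2, n_j=13, seed=11)
db.write_fasta(workdir / "reference.fasta")
reads = simulate_reads(db, SimulationConfig("low", n_reads=3000, seed=12))
write_reads_fasta(reads, workdir / "reads.fasta")

result = run_profile(
    RunConfig(
        reads_path=workdir / "reads.fasta",
        out_dir=workdir / "out",
        reference_path=workdir / "reference.fasta",
        reference_dialect="plain",
    )
)

s = result.summary
print(f"total reads      {s['total_reads']}")
print(f"mapped reads     {s['mapped_reads']}  (V and J assigned)")
print(f"CDR3 extracted   {s['cdr3_reads']}  (others: a mismatch broke an anchor motif)")
print(f"clonotypes       {s['clonotype_count']}  (distinct V(D)J + CDR3 classes)")
print(f"SNP candidates   {s['snp_candidates']}  (expected 0: errors are scattered)")
# productive = in frame with no stop codon, as a real repertoire report would show
productive = sorted(
    (c for c in result.profile.clonotypes if c.cdr3_aa and "*" not in c.cdr3_aa),
    key=lambda c: (-c.count, c.cdr3_aa),
)
print(f"\nproductive clonotypes: {len(productive)}; first 5 (count, V, J, CDR3):")
for clone in productive[:5]:
    print(f"  {clone.count:4d}  {clone.v_gene:10s} {clone.j_gene:10s} {clone.cdr3_aa}")
print("\neach CDR3 runs from the V segment's last cysteine (C...) to the")
print("J segment's conserved [FW] residue. random junction inserts give")
print("nearly every simulated read a unique CDR3 (often out of frame) -")
print(f"the simulator has no clonal expansion. artifacts: {workdir}/out")
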