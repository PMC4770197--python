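# Methods

This note documents the models, parameters and numerical choices behind
lymprofiler, the behaviour of the built-in read simulator, and the limits
of what the simulation-backed tests demonstrate.

## Fast-tag-search alignment

The aligner assigns each read to the reference V, (D) and J segments it
most plausibly derives from, using exact-match seeding and ungapped
extension rather than dynamic programming — amplicon reads of rearranged
receptors align to their germline segments essentially without indels, so
a Hamming-scored full-overlap extension is both sufficient and fast.

**Tag schemes.** V genes are seeded from the 3′ end (the part of V an
amplicon read is guaranteed to cover) with `n_tags_v = 5` adjacent,
non-overlapping tags of `tag_len = 5` nt; J genes from the 5′ end with
`n_tags_j = 3` tags; D genes with the terminal 3 nt of each end
(`d_tag_len = 3`), because D segments are only 12–16 bp, mutually similar,
and sit inside the hypervariable junction. Multiple tags provide
redundancy: a read maps as long as at least one tag region is
mismatch-free. Genes too short for their scheme are excluded with a
warning rather than aborting the run; a D gene shorter than two tags falls
back to a single whole-sequence tag.

**Seeding policy.** For each gene, tags are tried in order. Every exact
occurrence of the current tag is extended; the gene's candidate is the
best *threshold-passing* extension from that tag. If none of the current
tag's extensions passes, later tags are still tried — a spurious
occurrence (the tag matching at the wrong place) counts as tag failure,
not gene failure. This matters in practice: a 5-mer tag can legitimately
recur inside the same gene or read (some J genes end with the same 5-mer
they start with), and a tiny perfect-identity overlap seeded at the wrong
offset must not shadow a full-length passing alignment at the right one.
Offsets already scored under an earlier tag are not rescored; the
extension depends only on the offset, not on which tag seeded it.

**Scoring and selection.** An extension covers the whole gene/read
overlap (no X-drop, no early stopping); its score is the matched-base
count and the identity, matched / overlap length. `N` never matches
anything. A gene enters the candidate set when identity ≥ `min_identity`
(default 0.90) and matched bases ≥ the class floor (`min_match_v` 30,
`min_match_j` 20, `min_match_d` 10). The assignment is the candidate with
the highest identity; ties break by matched bases, then lexicographically
smallest gene id, making results fully deterministic. Identity
comparisons use exact integer cross-multiplication, never floats.

**Strand handling.** If V or J fails on the forward strand, both are
retried on the reverse complement and the orientation with more total
matched bases is kept (`try_reverse_complement`, default on). A read is
*mapped* when both V and J are assigned; D is attempted only on mapped
reads of databases with a D pool, and only inside the read interval
between the V and J alignments. Unmapped reads carry a reason code
(`no_v`, `no_j`, `no_vj`).

## CDR3 extraction and clonotype classification

The CDR3 is delimited by the V segment's last in-frame cysteine codon and
the J segment's conserved [FW]-G-X-G motif. Both anchors are located once
per reference gene at load time: the Cys by scanning codons in frame 0
(IMGT V-REGION records start in frame; `frame_offset` shifts the scan if a
custom database does not), the J motif by testing every 12-nt window for
the [FW]-G-X-G translation pattern (no frame assumption, since J records
commonly begin mid-codon). Twelve nucleotides suffice to make the motif
effectively unique within a receptor read.

On each mapped read, the Cys anchor is *mapped through* the ungapped V
alignment (so mismatches inside the codon do not break extraction), while
the J motif is located by exact search for the reference 12-mer within the
J-aligned interval. The extracted region runs from the first base of the
Cys codon through the last base of the [FW] codon, inclusive — stated
exactly so tests can assert byte equality. Reads whose V alignment does
not cover the Cys codon, whose J motif is absent (e.g. destroyed by a
sequencing error), or whose anchors invert, are recorded with a status
code and excluded from clonotyping; a sequencing error inside the 12-mer
therefore costs that read its CDR3, which is the main gap between mapped
and CDR3-bearing counts on noisy data.

Clonotypes group reads by (V, D, J, CDR3 nucleotide sequence). The
error-correction stage labels clonotypes with count < `min_core_frac`
(default 0.001%) of the CDR3-bearing reads as *minimum sequences* and
merges each into a core clonotype of identical V(D)J genes and CDR3 length
at Hamming distance strictly below `M` (default 2, i.e. only distance-1
neighbours merge). Choices the definition leaves open, fixed here:

* the 0.001% denominator is the number of CDR3-bearing reads, not raw
  input reads — invariant under unmappable junk in the input;
* when several cores qualify, the merge target is the closest, then the
  one with the largest pre-merge count, then the lexicographically
  smallest CDR3; minima are processed in descending count order;
* the core set is frozen after labelling — merged minima never promote a
  clonotype into the core set mid-pass.

Counts are conserved by construction, and merging never alters a core's
CDR3. Translation (standard code, frame 0 of the extracted CDR3) flags
out-of-frame junctions; codons containing `N` translate to `X`.

## Novel-allele (SNP) calling

A germline polymorphism missing from the reference appears as the same
mismatch recurring in a large fraction of one gene's reads, independent of
rearrangement partner. Candidates must pass two filters: partner
multiplicity (a V variant must co-occur with > 3 distinct J genes, i.e.
≥ `min_j_partners_for_v` = 4; a J variant with ≥ `min_v_partners_for_j`
= 5 distinct V genes) and frequency ≥ `min_freq` = 10% among reads
covering that position. Somatic point mutations are expected below ~5%
(≤ ~10% in G/C hotspots), so clone-independent germline variants stand
out; truly imbalanced alleles below 10% are missed, which is why the
threshold is exposed as a parameter.

Implementation choices: partners are counted at gene-name level (two
alleles of one J gene are one partner — the criterion concerns
rearrangement combinations, not allele calls); the frequency denominator
is per-position coverage among reads aligned to that gene allele, robust
to partial overlaps; D segments are never called (too short, inside the
hypervariable junction); variants are nucleotide-level records, reported
with 1-based positions and percent frequencies.

## Lineage mutation trees

For IG chains, each V/J rearrangement group with at least one sequence in
the original germline configuration — defined here operationally as zero
mismatches over both the V- and J-aligned intervals — yields a tree. The
most abundant such sequence (ties: lexicographic) is the root; all other
unique read sequences of the group within `max_radius` = 10 Levenshtein
steps are placed on the layer equal to their edit distance from the root.
The full read sequence is used, not just the CDR3: hypermutation also hits
the V framework. The tree shows the *minimal* steps that could explain the
observed sequences, not the actual mutation history.

A layer-k node attaches to an observed layer-(k−1) node at distance 1
(ties: higher count, then lexicographic). A node with no such parent hangs
from its nearest observed ancestor on a minimal path — an observed
layer-j node at distance exactly k−j, with the largest such j; the root
always qualifies — through a chain of hypothetical nodes, one per skipped
layer, shared between orphans that take the same path. Hypothetical nodes
represent unobserved intermediates and carry no sequence or count.
Newick output labels observed nodes `label_count` and hypothetical ones
`HYP<layer>`; a validator asserts the layer, distance and radius
invariants on every constructed tree. Levenshtein distances come from
edlib; an independent dynamic-programming oracle checks them in the test
suite.

## The read simulator

The simulator is the package's evaluation harness and emulates the
standard benchmarking protocol for this class of tools: uniform gene usage
over the database; per-segment substitution counts drawn uniformly from a
level-specific range (none: 0/0/0; low: V 0–7, D 0–1, J 0–3; high: V 0–15,
D 0–2, J 0–5) at distinct uniform positions, each substitution replacing
the base with a uniformly chosen different base; and 0–6 uniformly random
nucleotides inserted at the V–D and D–J junctions (one junction when the
chain has no D pool). Mismatches are applied to the segments first, then
junctions are inserted; segment ends are not trimmed. Reads are emitted
full-length (whole V through whole J). Every read carries a truth record
(segment ids, mismatch positions and bases, junction inserts, CDR3
boundaries) sufficient to regenerate it byte-for-byte; the test suite
asserts that reconstruction and checks the mismatch-count histograms
against their uniform ranges by chi-square goodness of fit.

The synthetic reference generator produces databases with IMGT-like
anatomy: V genes of ~285 nt carrying an in-frame TGT near the 3′ end (and
no in-frame Cys codon after it, so the "last cysteine" is unambiguous);
J genes of exactly 50 nt with unique 15-nt 5′ prefixes — so the three
5-nt J tags discriminate genes — and a [FW]GXG-encoding 12-mer at a fixed
offset; D genes of 12–16 nt. Each gene gets `allele_copies` (default 2)
alleles differing by 1–3 substitutions, to stress allele-level assignment.
Allele substitutions are drawn 5′ of the V Cys codon and outside the J
motif so every allele keeps valid CDR3 anchors; this mirrors real allelic
variation, which is concentrated in framework regions rather than in the
conserved anchors. The fixed J length of 50 nt makes the 90% identity
threshold interact with the J mismatch range as it does for IMGT-scale J
genes.

**What the simulator does not model:** clonal expansion (every read is an
independent rearrangement, so clonotype counts are ~1 and merging has
little to do), quality-score-correlated errors, indel errors, PCR
chimeras, exonucleolytic trimming of segment ends, and read truncation.
Passing the simulation benchmarks therefore demonstrates the correctness
and mismatch tolerance of the assignment/extraction machinery, not
robustness to indels or to library-preparation artefacts.

## Statistical comparisons

Two-method comparisons of mapped (or correctly mapped) proportions use the
2×2 chi-square test without continuity correction, computed by the closed
form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with the p-value from the χ²(1)
survival function; tables with ad−bc = 0 — including degenerate
all-success/all-failure margins — return statistic 0. Paired per-sample
proportions use the two-sided Wilcoxon signed-rank test (zero differences
dropped, statistic min(T⁺, T⁻), exact null for small tie-free samples via
scipy). Evaluation against simulation truth reports completeness (mapped /
total × 100) and accuracy (correct / mapped × 100) at allele or gene-name
level; the D assignment is scored only when the truth D segment retains at
least `min_match_d` unmutated bases, since below that the thresholds make
the true D undetectable by design.

## Problem sizes and determinism

The acceptance benchmarks run at 5,000 reads (no-mismatch completeness),
20,000 reads (high-mismatch completeness and IG accuracy) and 10,000 reads
(planted-SNP recovery and simulator goodness of fit) on synthetic
references of 50×2 / 40×2 V alleles — sizes at which the binomial standard
error on a ~98–99% proportion is under 0.1 percentage points, so the
bounds are not sampling noise. All randomness flows from explicit integer
seeds; identical configuration yields byte-identical reads, truth tables
and output files.

## Known limitations

* Ungapped extension cannot recover reads with indel sequencing errors in
  the V or J region; such reads lose matched bases en bloc and may drop
  below the identity floor.
* CDR3 extraction requires the exact reference 12-mer motif in the read;
  an error inside the motif costs the read its CDR3 (the mapped-but-no-
  CDR3 gap visible on noisy data).
* A V gene whose database record lacks an in-frame Cys codon is alignable
  but excluded from CDR3 extraction (flagged at load time); how the
  original tooling of this field handles that case is not standardised.
* D-segment assignment at high mismatch levels is intrinsically limited:
  with 2 substitutions on a 12–16 bp segment the 90%/10 bp thresholds are
  frequently unreachable, so D-inclusive allele-level accuracy degrades
  even though V/J assignment stays near-perfect.
* Novel alleles below the 10% frequency threshold (strong allelic
  imbalance) are not reported; the threshold is a parameter, not a model.
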