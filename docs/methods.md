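# Methods

`crisprmge` implements a reference-free protocol for discovering
CRISPR-targeted, terminally redundant (circular) mobile genetic elements
(MGEs) from metagenomic contigs and reads, and for predicting their
CRISPR-targeting hosts. This note documents the model behind each stage,
the tunable parameters and their defaults, what the synthetic community
does and does not emulate, and the numerical choices that shape results.

## Rationale

CRISPR arrays record a host's infection history as spacers sampled from
invading MGEs. Direct repeats (DRs) are easy to find; spacers between
them are not recognizable on their own but become so once the flanking
DRs are identified. The protocol therefore: (1) detects arrays on
contigs to obtain consensus DRs; (2) extracts spacers directly from raw
reads by masking DR occurrences (capturing diversity lost in assembly);
(3) maps spacers back to CRISPR-masked contigs to find protospacers;
(4) groups spacers targeting the same element via protospacer
co-occurrence; (5) extracts densely targeted contig regions and keeps
those with exact terminal redundancy — the assembler's signature of a
completely assembled circular genome; (6) links records to hosts through
the taxonomy of the DRs whose spacers target them.

## Stage-by-stage model and parameters

### Global alignment (seqcore)

End-to-end Needleman–Wunsch/Gotoh with affine gaps; defaults match=1,
mismatch=−1, gap open=−1, gap extend=−1 (open = extend makes the model
effectively linear, but both knobs are honored when configured apart).
End gaps are penalized. Identity is matches / alignment columns,
counting gap columns. Traceback is deterministic: diagonal preferred
over a gap in the second sequence, preferred over a gap in the first.
N never counts as a match. Under these conventions the two 34-nt direct
repeats highlighted in the README's worked example align at exactly 4
mismatches and 29/35 = 82.9% identity; the end-gap and identity
conventions were chosen because they are the ones consistent with that
alignment, and they are applied uniformly in the flank filter.

### Array detection (crispr)

A minimal CRT-style detector, not a full array annotator: exact repeated
13-mers with period 43–115 (repeat 23–55 plus spacer 20–60) seed
candidate chains, which are extended while every copy agrees
column-wise. Arrays need ≥3 copies; spacer lengths are validated after
extension; overlapping candidates resolve to the maximal array (most
copies, then longest repeat). The consensus DR is the column-wise
majority. Limitations accepted by design: a substitution inside a
repeat copy truncates extension at that column (the conserved core is
still reported); array orientation is as-seeded on the forward strand —
no orientation scoring is attempted, so "5′" in downstream PAM profiles
is relative to the detected DR frame, not the transcribed crRNA.

### Spacer extraction from reads (crispr)

Every DR occurrence on a read (either strand, ≤1 mismatch) is masked,
including partial DR copies of ≥18 nt at read ends — without the
end-partial rule, truncated repeat copies would leak into spacers as
chimeras. Only segments bounded by masks on *both* sides are spacers
(a read-terminal fragment may be an incomplete spacer). Uniqueness is
defined on the canonical orientation (lexicographic minimum of sequence
and reverse complement); alongside it each spacer retains its majority
DR-frame orientation, i.e. the orientation it shows when its bounding
DR matches the stored consensus forward. This keeps all spacers of one
array in a consistent frame, which is what makes protospacer-adjacent
motifs (PAMs) line up position-by-position later; canonical-only
orientation would randomize the motif's side and wash it out.

### Protospacer detection (protospacer)

DRs are mapped to contigs at ≥93% full-length identity
(substitution-only) and every hit ±60 bases is masked; spacers are then
mapped full-length at ≥93% to the masked contigs, suppressing any hit
overlapping a mask by ≥1 base. Mapping is Hamming (no indels) by
design: it makes "minimum sequence identity" arithmetic exact and the
mapper's behavior reproducible; spacer-protospacer divergence is
dominated by substitutions. The false-positive filter aligns flank5 vs
flank3, flank5 vs DR, and flank3 vs DR (flank window = associated DR
length; the filter exists to catch unmasked DR remnants, so a DR-sized
window is the natural unit) and discards the locus when any score
divided by the shorter sequence length exceeds 0.5 — with the +1/−1
scores this ratio is a similarity on [−1, 1], and 0.5 corresponds to
roughly 75% identity between flanks. On random 34-nt trios the false
discard rate is below 1% (Monte-Carlo, tested).

### Spacer clustering (clustering)

Validated loci within 50 kb on one contig chain into locus clusters
(single linkage). The co-occurrence graph has spacers as nodes and edge
weight = number of locus clusters containing both spacers. Communities
come from a deterministic dense Markov clustering: pre-inflation 0.4
(entrywise power on weights), self-loops at each node's maximum incident
weight (standard MCL regularization; keeps the walk lazy enough to
converge), column normalization, then alternating expansion (matrix
square) and inflation (entrywise 4th power, renormalize), pruning
entries <1e-5 after normalization, to a tolerance of 1e-6 or 100
iterations. Clusters are read from attractor rows; nodes reachable from
several attractors go to the largest flow value, ties to the lowest
cluster index; node order never affects memberships. Clusters with <10
spacers or global clustering coefficient (3·triangles / connected
triples, unweighted induced subgraph) <0.5 are discarded. "Size" counts
spacers. At package scale the matrix is dense; the implementation is
not intended for millions of spacers.

### Target extraction and terminal redundancy (targets)

Per cluster, member loci chain into blocks with gap ≤ max(mean
adjacent-locus distance of the cluster, 1 kb) — the mean adjacent-locus
distance is measured start-to-start within locus clusters and acts as a
density-adaptive chaining radius with a 1-kb floor. Blocks targeted by
strictly more than 30% of the cluster's members (distinct spacers) are
kept; blocks within 1 kb are joined; sequences containing N are
discarded. A sequence is terminally redundant (TR) when its longest
exact prefix=suffix repeat L satisfies 20 ≤ L ≤ 0.5·length (borders via
the KMP failure function; the 0.5 cap stops periodic sequences from
degenerating). min_tr = 20 makes a chance terminal 20-mer repeat in a
300-kb sequence ~1e-6. TR detection is exact-match because
assembler-produced terminal redundancy is exact by construction. The
circular sequence is the linear sequence minus its terminal repeat.
Deduplication is greedy longest-first: a record joins a representative
when it aligns (edlib, either strand) at ≥95% identity over ≥95% of
both lengths against the representative's *doubled* circular sequence —
doubling makes the test rotation-invariant. This is a single-stage
stand-in with the same 95/95 rotation-aware contract as multi-round
clustering tools, adequate at desk scale.

### Metrics and classification (annotation metrics)

Singleton coverage = k-mers occurring exactly once (forward strand,
wrap-around included so a doubled sequence scores exactly 0 and the
metric is rotation-invariant) divided by length. Auto-k is the smallest
k with 4^k ≥ 100·L², keeping expected chance doubletons below ~0.01 so
large genomes are scored with larger k. Coding ratio = fraction of the
circular genome covered by the union of predicted ORFs (6 frames on the
doubled sequence so origin-spanning genes are recovered; starts
ATG/GTG/TTG; longest ORF per stop; ≥33 codons). The ORF caller is a
deliberate naive scanner — on random DNA it is permissive (coding
ratios ~0.8), so coding ratio is informative as a *relative* metric and
for detecting notably gene-poor records, not as a gene count.
Classification applies marker precedence to an externally produced
annotation table: HK97 capsid → Caudovirales; else Microviridae MCP →
Microviridae; else Inoviridae MCP → Inoviridae; else any of
ParA/ParB/ParM/MobM → Plasmid-like; else Unclassified. Capsids outrank
plasmid markers because the plasmid rule applies to capsid-less records
only. Size classes split at 20 kb, GC classes at 55%.

### Host prediction and PAM (host_pam)

DRs map to reference genomes at ≥90% identity; a genome supports a DR
only via a validated CRISPR locus: ≥3 hits whose consecutive
start-to-start gaps are each ≤100 bases (a repeat+spacer period is
60–110 bases, so three consecutive array copies satisfy this, while
isolated hits never do). A DR is assigned at a rank only when all
supporting genomes agree there. Per record and rank, protospacer loci
whose DR resolves to a single taxon are counted; a taxon is called when
≥10 loci are assigned and the top taxon holds >90% of them
(exclusiveness over assigned loci only); ≥10 but ≤90% → AMBIGUOUS;
<10 → NA. PAM profiles accumulate base counts over the 10 flanking
positions each side, all protospacers oriented spacer-strand 5′→3′;
consensus letters require ≥75% of the column, else N; profiles from <3
protospacers are flagged low-support. Scrambled controls are
length-matched i.i.d. draws from the input's aggregate base
composition. The remnant-spacer sweep computes, once per spacer, its
best full-length identity anywhere in the TR (and scrambled) set; hit
counts at each threshold in 0.80–1.00 follow by comparison, which makes
monotonicity in the threshold structural rather than incidental.

## The synthetic community

The generator produces the conditions every end-to-end test runs under:
10 circular phages (3–40 kb), 5 host genomes (30 kb) across 3 phyla,
one CRISPR array per phage on its assigned host (DRs 28–36 nt, spacers
30–40 nt), a TTT motif planted immediately 5′ of every sampled
protospacer, escape mutations (4 substitutions per protospacer, i.e.
87–90% residual identity, below the 93% mapping threshold) applied to
the phage copy at rate 0.05, error-free 200-nt reads at 15× coverage,
and phage contigs linearized with a 55-nt exact terminal repeat.

Two density choices matter and are deliberate:

* **Targeting density.** Protospacer positions are stratified along each
  phage circle at ~1 per 300 bases (clamped to 12–150 per phage). Real
  CRISPR-targeted elements in gut data are targeted far more densely
  (hundreds of protospacers on a ~50-kb element, about one per 80
  bases); the stratified ~300-base spacing is a conservative stand-in
  that still lets density-adaptive chaining behave as it does on real
  data. With Poisson-random placement at low density, chaining with a
  gap bound near the mean spacing would fragment every genome — an
  artifact of sparse toy data, not of the method.
* **Rotation anchoring.** Each phage contig is linearized so one
  sampled, never-mutated protospacer lies inside the terminal repeat.
  On densely targeted real data some protospacer always falls in the
  redundant region (so the extracted region can span a full circle plus
  ≥20 bases of redundancy); anchoring reproduces that property
  deterministically at toy density.

What the generator does **not** emulate: sequencing errors (reads are
error-free by default; the upstream error-correction stage is outside
this package's scope), chimeras, strain mixtures, abundance skew,
assembly fragmentation of host genomes, arrays shared across hosts, and
DR orientation ambiguity. Passing end-to-end tests therefore
demonstrates the pipeline's logic — masking, mapping arithmetic,
clustering, terminal-redundancy handling, host logic — under clean
conditions; they do not certify recall on real, noisy metagenomes.

All randomness flows from a single mandatory seed; repeated runs are
byte-identical.

## Numerical choices and degenerate inputs

* Identity thresholds convert to mismatch budgets as
  floor((1−identity)·L + 1e-9); the epsilon prevents float
  representation from tightening a boundary case (e.g. 7 mismatches in
  100 at 93%).
* Merged read masks keep the orientation of their first interval;
  bounding masks of a spacer contribute the union of their DR ids.
* Palindromic spacers map on one strand only (avoids double-reporting).
* Zero-length flanks at contig edges skip their alignment comparisons.
* An all-N sequence has undefined GC; requesting k ≥ length for
  singleton coverage is an error; detect_tr returns none for sequences
  of length ≤ 2·min_tr.
* MCL on an empty graph returns no clusters; unattracted nodes become
  singletons; non-convergence at 100 iterations warns and returns the
  current partition.
* Host genomes too small to hold their arrays plus margins are a
  configuration error, reported at generation time.

## Problem sizes

Default test and acceptance conditions: ~30,000 reads (6 Mb), ~365 kb
of contigs, ~800 unique spacers, ~800 protospacer loci, graphs of ~800
nodes, 10 TR records of 3–40 kb, and ≥1 Mb of scrambled control
sequence. The full pipeline runs in well under a minute on one core at
these sizes; the mapping stages scale linearly in spacers × contig
length and are not engineered beyond vectorized scanning.

## Known limitations

* The array detector reports the conserved repeat core, not
  CRISPRDetect-grade boundaries or orientation; degenerate repeats and
  Cas-locus context are out of scope.
* Spacer mapping is substitution-only; indel-divergent protospacers are
  missed (an edit-distance mode could reuse the edlib dependency but is
  not wired into the pipeline).
* The dedup stage is single-round greedy; corpus-scale redundancy
  (hundreds of thousands of records) would need the staged clustering
  it stands in for.
* Coding ratio from the naive ORF caller overestimates coding content
  on random sequence; comparisons are meaningful within this package's
  outputs, not against Prodigal-based annotations.
* Host calls inherit every caveat of DR-taxonomy transfer: horizontal
  transfer of CRISPR loci between taxa can mislabel the targeting host,
  which is precisely why conflicting DR assignments demote to
  UNASSIGNED and mixed-taxon records to AMBIGUOUS rather than forcing a
  call.
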