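# Methods

This note documents the models and procedures estforge implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## The analysis in one paragraph

Long single-end cDNA reads from several normalized tissue libraries are
trimmed (adapters, terminal poly-A/T), filtered (< 100 bp after trimming,
contaminant hits), pre-clustered by overlap with multi-membership, and
assembled into consensus contigs over four refinement cycles plus one
stricter merge cycle. Contigs and leftover singleton reads are then
(a) assigned to a surrogate reference genome by best alignment score and
summarized in 0.5-Mb strand-separated coverage bins, (b) mined for perfect
microsatellites, (c) quantified per library by shredding reads into
40-mers, mapping them to contigs and converting counts to RPKM, and
(d) screened against retroelement, conserved-ortholog and reference
transcript databases.

## Synthetic-data generator (`simulate`)

The generator defines the study conditions for every test in the package.

**Transcriptome.** `n_genes` genes; each becomes a paralog family with
probability `paralog_family_prob` (default 0.15), of size drawn from
`family_size_range` (2–4). Family members derive from a common ancestor by
independent per-base substitution at `paralog_divergence / 2` each, so
`paralog_divergence` (default 0.05) is the *expected pairwise* divergence
between members. A `conserved_block_len` region (default 0) can be held
identical across a family; this models the conserved domains that make
homeolog separation hard and is used by the multi-membership tests.
Transcripts optionally carry one embedded perfect SSR (flanks guarded so
the planted locus is maximal exactly at its recorded coordinates) and/or a
retroelement fragment cut from a small generated family library; all
coordinates are recorded as ground truth.

**Reference.** Transcripts are shuffled onto `n_chroms` chromosomes with
random strand and fixed-length random spacers, spacer-flanked, so a
chromosome with *n* transcripts has length Σlenᵢ + (n+1)·spacer. The toy
reference is intron-free by construction; spliced alignment is explicitly
out of scope.

**Normalized abundances.** Per library, raw abundances are log-normal
(σ = 1.5) flattened as w^γ and renormalized. γ = 0.3 by default — the
flattening exponent is a free parameter chosen to give visibly compressed
but still distinct abundance ranks, which reproduces the left-skewed
contig read-count distribution normalization produces in real data;
duplex-specific-nuclease kinetics are deliberately not modeled.

**Read sampling.** The probability a read comes from transcript *t* is
proportional to wₜ · lenₜ: weights are molar abundances, and cDNA
nebulization yields fragments (hence sequenced reads) in proportion to
molecule length. This makes RPKM a consistent estimator of w, which is the
property the abundance-recovery test checks.

**Read lengths.** length = max − G with G a Gamma(shape 3.8, scale
calibrated) variate rejected above max − min. The scale is solved
numerically (Brent on the truncated-Gamma mean) so the expected length
equals the configured mean (367 bp); the hard maximum is 695 bp. A
reflected Gamma was chosen over a reflected Beta because matching the
instrument's mean-below-median left skew with a unimodal Beta is not
possible on any support (a left-skewed Beta forces the mean above the
support midpoint). The model reproduces mean, maximum and the direction of
the skew; the realized mean–median gap (~12 bp) is smaller than the real
instrument's (~28 bp), which no test depends on.

**Errors.** The per-base error budget (1 − accuracy, default 0.005) is
split 60 % substitutions / 40 % homopolymer-length indels. A run of length
r gains or loses one base with probability c·(r−1); on random DNA the
expected per-base indel rate is c/4, which fixes c from the budget.
Calibration is verified over > 10⁶ simulated bases (realized accuracy
within 0.002 of configured). Quality strings are flat; chimeras and rRNA
contamination are not modeled.

**Determinism.** One seeded NumPy generator per run; the library label is
folded into the seed stream (CRC32 of the label) so libraries differ but
are individually reproducible. Identical configs give byte-identical
outputs.

## Cleaning (`clean`)

Order: adapters → poly-A/T → contaminant screen → length filter; the
length rule is strict (< 100 bp removed, exactly 100 kept) and applied
after all trimming. Adapter matches are terminal-only, ≥ 8 bp, allowing a
10 % mismatch fraction; a prefix match compares the adapter's 3′ end to
the read start so truncated adapters are handled. Poly-A/T trimming
removes the longest terminal window that is ≥ 90 % A (3′) or T (5′) —
"one interruption per ten bases" — of length ≥ 8; this tolerance is not a
published rule but is needed for tails that have passed through the error
model. The contaminant screen flags a read when any local alignment covers
≥ 80 % of it at ≥ 90 % identity; both thresholds are exposed because no
standard values exist. Every run satisfies
raw = kept + removed_short + removed_contaminant + removed_empty exactly,
and cleaning is idempotent and order-independent per read.

## Alignment engine (`align`)

One seeded local aligner serves clustering, reference mapping, fragment
mapping and the screens. Exact k-mers (k = 11 nucleotide) against an index
locate candidate targets; seeds are grouped into diagonal bands; each band
is resolved by an exact affine-gap Smith–Waterman (match +1, mismatch −2,
gap open −5, extend −2) restricted to the seeded window. Window DP was
preferred over heuristic x-drop extension because the window is small
enough that exactness is affordable, and it makes the engine's score
provably ≤ and empirically ≈ the full-DP optimum (property-tested).
E-values use E = K·m·n·exp(−λS) with fixed constants (K = 0.13, λ = 0.55
for the nucleotide system; 0.041/0.267 for BLOSUM62). These are relative
gates for thresholding within the toolkit, not NCBI-calibrated statistics
— the screens' 10⁻⁶/10⁻¹⁰ thresholds are meaningful only against this
engine's own score scale. Translated mode enumerates all six reading
frames, truncates at stop codons, prefilters frame/protein pairs by shared
amino-acid 4-mers and aligns with BLOSUM62 (−11/−1); hit lengths count
residue columns so the ≥ 30-residue ortholog rule applies directly.
Best-hit selection is by score, then identity, then lexicographic target
id — fully deterministic.

## Clustering and assembly (`cluster_assemble`)

Overlap detection seeds with 16-mers (every 5th query position), infers
the implied diagonal, and verifies the overlap with a banded edit-distance
alignment (edlib), accepting dovetail/containment overlaps of ≥ 40 bp at
≥ 94 % identity. Pre-clustering is seed-based and greedy: reads sorted by
descending length (ties by id); each read not yet in any cluster seeds a
new cluster and *every* read overlapping the seed joins regardless of
prior membership. This is the concrete realization of multi-membership
clustering: it is order-deterministic and lets one read sit in several
clusters without any global partitioning step.

Within a cluster, connected overlap components are oriented by BFS (an
orientation conflict demotes the offending read to its own contig),
placed by overlap-implied offsets, chained into a backbone with
edlib-refined junctions, and every member is realigned to the backbone for
a per-column weighted vote: ties produce IUPAC ambiguity codes, a
gap-majority column is deleted, and insertions relative to the backbone
are dropped (the residual consensus error this causes is bounded by the
per-read deletion rate, ~1 base/kb, and is invisible at the 95 %-identity
recovery criterion). Column weights are the per-column read depths of the
input sequences, so depth always counts original reads.

Iteration: four refinement cycles re-overlap and re-assemble the previous
cycle's contigs plus carried singletons, then one merge cycle at 97 %
identity. Membership is traced through cycles; duplicate contigs (same
original-read set, produced by overlapping clusters) are collapsed; a
contig needs ≥ 2 distinct reads, everything else is a singleton. The
package asserts after every run that each input read appears in ≥ 1 contig
or the singleton list. The 40 bp / 0.94 / 0.97 thresholds are not
published values; they follow common EST-assembler practice and are
config-exposed. Note an interaction worth knowing: at the default 0.94
floor, families less than ~6 % diverged will co-cluster; separating 5 %
divergent homeologs requires the 0.97 setting (this is exercised in the
tests and is exactly the lever the two-stage design exposes).

## Reference-guided path (`refmap`)

Queries are placed by best hit; locus groups are single-linkage clusters
of ≥ 1 bp interval overlaps on the same chromosome and strand
(single-linkage because genomic tiling is transitive and the rule is
deterministic). The reference supplies only layout — orientation and
offsets — never bases; consensus is voted from the queries. Binned
coverage uses the interval midpoint's bin for counts (unambiguous for
spanning alignments) but splits aligned bases exactly at bin boundaries,
storing integer base counts per bin; mean depth is derived by division at
read-out, so Σ(depth × span) equals total aligned bases exactly.

## SSR mining (`ssr`)

For each unit length 2–6 the detector scans the self-match array
s[i] == s[i+u] (N never matches), takes maximal runs, and emits the
left-anchored whole-unit locus of each qualifying run. Unit-count floors
are read as ≥ (di ≥ 8 → 16 bp, penta ≥ 3 → exactly 15 bp), which makes the
class floors and the 15-bp total-length floor mutually consistent; both
are config-overridable. Partial trailing units never extend a locus (so
total_len = unit_len × unit_count holds identically), non-primitive units
(themselves tandems of a shorter unit) are suppressed so a span is
reported once at its shortest period — a consequence is that homopolymer
runs are never reported, and that mirror-image loci on the reverse
complement may shift by up to unit_len − 1 when the maximal span is not a
whole number of units. Compound (adjacent distinct-motif) repeats are
reported as separate loci. The detector is verified identical to an
independent enumerate-and-extend oracle on 1,000 random sequences.

## Quantification (`quantify`)

Shredding is a non-overlapping 40-bp tiling from position 0, remainder
discarded — a partition, not a sliding window, so each read base is
counted at most once and the RPKM denominator stays interpretable.
Fragments map to the fewest-mismatch contig position on either strand,
candidates located by the pigeonhole anchors at offsets 0/13/26 (with ≤ 2
mismatches in 40 bp one 13-mer must be exact); ties go to the
lexicographically smallest contig id (deterministic single assignment;
fractional multi-mapping is a non-goal). Fragments carrying an indel
error are left unmapped by design, matching mismatch-only short-read
mappers. RPKM uses mapped fragments as the denominator (both totals are
recorded). log₂(RPKM + 1) is used for clustering because post-filter
profiles legitimately contain zeros; UPGMA on Euclidean distances is
delegated to scipy and re-exported with a Newick writer.

## Screens (`screen`)

A sequence counts once toward retroelement abundance however many
elements it hits (fraction printed at two decimals). Ortholog detection
requires both the E-value gate and, for the stringent screen, ≥ 30 aligned
residues; the tribe screen is the same machinery at 10⁻⁶ without the
length rule. Comparative coverage counts a reference transcript as
represented when ≥ 1 contig best-aligns to it; the direction
(contig → reference) is a choice — the detection rule is presence-based
and symmetric in practice. Percentages are *truncated*, not rounded, at
the reporting precision: coverage statements of the form "represents up
to X %" floor the fraction so the printed figure never overstates it.

## Pipeline (`cli`)

`estforge pipeline` chains all stages on synthetic data, validates its
YAML config against the typed per-stage parameter sets (unknown fields are
reported with their section path), and writes a manifest containing the
seed, a SHA-256 parameter hash and per-stage record counts, including the
cleaning balance and the read-accounting assertion at assembly. No
timestamps are written, so a re-run with the same config is byte-identical.

## Test and demo problem sizes

Tests run the generator at deliberately desk-sized conditions — tens of
genes and a few thousand reads per library, with the assembly-recovery
check at 100 transcripts tiled to ~20× depth (~5,800 reads) — sizes at
which every statistical check (error calibration over > 10⁶ bases,
length-model moments over 10⁴ draws, abundance recovery at ≥ 0.9 Spearman)
is already stable. The abundance-recovery condition uses a paralog-free
transcriptome: with paralog families present, tie-broken multi-mapping
reallocates conserved-region fragments within a family, which measures
paralog resolution rather than quantification fidelity.

## What passing tests do and do not show

The generator emulates the read-level statistics and the contaminating
structures the pipeline must survive, but real 454 data also contain
chimeric molecules, position-dependent quality, rRNA carry-over, and
splice variants sharing exons — none of which are modeled. Passing the
recovery criteria here shows the algorithms are correct under the stated
noise model, not that the thresholds are optimal for any particular real
dataset. The E-value scale is engine-relative; results at the 10⁻⁶/10⁻¹⁰
gates should be compared between runs of this toolkit, not against BLAST
output. Known limitations, summarized: no spliced alignment; no
quality-aware trimming; single deterministic assignment of multi-mapping
fragments; consensus insertions relative to the backbone are dropped;
SAM/BAM emission is out of scope.
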