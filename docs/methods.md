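# Methods

This note documents the models and procedures implemented in `sortvir`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate about real data.

## Sequence primitives

**Quality trimming.** Trimmomatic-style semantics with the settings
LEADING:3 TRAILING:3 SLIDINGWINDOW:25:30 MINLEN:50 as defaults: leading and
trailing bases below q = 3 are removed, then the read is truncated at the
*start* of the first 25-base window whose mean quality falls below 30 (the
documented sliding-window behaviour: the failing window's leading bases are
discarded, not kept). Survivors shorter than 50 bp are dropped. Quality
encoding is fixed to Sanger phred+33; other encodings are rejected, never
guessed.

**Canonical k-mer composition.** Each k-mer is pooled with its reverse
complement under the lexicographically smaller representative, giving 136
classes at k = 4 (120 pairs + 16 palindromes). k-mers containing N are
skipped and vectors are simplex-normalized. Strand invariance and the class
count are property-tested against brute-force pooling.

**Local alignment.** Smith–Waterman through Biopython's `PairwiseAligner`:
nucleotide mode at +1/−2 with affine gaps −5/−2 (both query strands tried),
translated mode as six-frame BLOSUM62 with gaps −11/−1, stop codons
breaking candidate peptides. Bit scores use fixed Karlin–Altschul constants
per scoring scheme (nucleotide λ = 1.28, K = 0.46; BLOSUM62 gapped
λ = 0.267, K = 0.041) and e-values the m·n·2^(−bit) form. These serve as
*thresholds*, not calibrated significance claims — absolute e-value
calibration is deliberately out of scope, so the constants are library
fixtures rather than estimated quantities. Coordinates are 0-based
half-open everywhere; reverse-strand features are reported on forward
coordinates with a strand flag.

## Synthetic sorted-cell communities

The generator emulates the statistical structure the analysis relies on,
with defaults matching the study conditions the pipeline targets:

- **Organisms.** One eukaryote host (~1 Mb, GC 0.45, one 18S-like rRNA
  operon) and one giant virus (~300 kb, GC 0.28, 30 planted ancestral
  markers). Giant-virus GC defaults must lie in 0.25–0.31 and the host must
  exceed the virus by ≥ 0.08 — the contrast that makes composition binning
  work; the constructor enforces both.
- **Genome backbones** are drawn from an order-3 Markov chain whose
  emissions interpolate between a GC-matched order-0 model and a random
  per-entity signature (log-normal perturbation, strength 0.6, with AT/GC
  mass re-normalized per context so GC stays on target). This guarantees
  both GC control and distinct tetranucleotide signatures — the two binning
  axes — without modelling real oligonucleotide biology.
- **Planted genes.** Marker proteins are sampled from the family
  alignments, mutated at 30% amino-acid distance (within PSSM detection
  range while non-trivial), reverse-translated with codon choice weighted
  by per-base probabilities at the target GC, and inserted flanked by
  in-frame stop codons so that stop-to-stop ORF calls recover exact truth
  coordinates. Because synonymous codon choice cannot reach extreme GC, the
  backbone GC target is adjusted to compensate for the realized GC of the
  inserts; realized genome GC lands within ±0.01 of target.
- **MDA coverage bias** is modelled as per-window (2 kb) log-normal
  sampling weights with scale `mda_sigma` = 1.5, not as a branching
  process: it reproduces the qualitative unevenness that motivates
  single-cell assembly tooling without modelling amplification chemistry.
  No quantitative coverage-bias statistic was available to fit, so the
  default is a realism judgement: it produces windowed depth CVs well above
  1 while leaving > 90% breadth at ~20× mean depth.
- **Reads** are substitution-only (rate 0.002) with linear quality decay
  (37 → 28); indels, chimeras and platform-specific error profiles are out
  of scope. Mate 2 is the reverse complement of the fragment end.
- **Reference stand-ins.** The 47 marker families and the ranked-lineage
  SSU set shipped by `synthetic_marker_alignments` /
  `synthetic_rrna_references` are synthetic (random consensus proteins;
  genera diverged ~25% from a shared rRNA root, members ~2% within genus).
  They reproduce the *separability structure* of the real references, not
  their sequences.

Everything is deterministic under a fixed seed; this is tested
byte-for-byte.

**What passing tests show.** On these fixtures the pipeline separates virus
from host essentially perfectly. Real sorts add contaminant bacteria and
phage, shared compositional signal between virus and host, repeats,
chimeric MDA artifacts and assembly errors; the fixtures demonstrate
correctness of the machinery, not field-grade sensitivity.

## Composition binning

Features are the 136-dimensional TNF vector and GC, each z-scored per
dataset, with GC down-weighted to 0.1 before concatenation: both signals
named by the workflow contribute, TNF dominates. Clustering is
average-linkage on Euclidean distance. When the bin count is not given, the
tree is cut at the largest relative gap between successive merge heights —
an automatic replacement for the interactive curation the original
workflow used (no objective stopping rule is recoverable from it).
Contigs are sorted by id before clustering, so the result is invariant to
input order. Depth is carried on profiles and reported, but is *not* a
clustering feature: the binning axes are composition and GC only.

## Marker screen and rRNA exclusion

**Profiles.** Per-family PSSMs: columns with > 50% gaps dropped, log2-odds
with background pseudocounts (α = 0.5, Robinson–Robinson background),
entries floored at −10 in the zero-pseudocount limit.

**ORFs.** Maximal stop-to-stop stretches ≥ 60 aa in all six frames; start
codons are ignored (marker detection tolerates N-terminal overhang, and a
gene-start model is out of scope).

**Scan.** Candidate (ORF, profile) anchors require an exact 4-aa word
shared with the profile consensus; anchors are scored ungapped along their
diagonal and the best anchor is refined by a banded (±5) gapped pass with
linear gap penalty −4. The statistic is in bits because PSSM entries are
log2-odds.

**Significance.** The tool-specific e-value cutoff of profile-HMM searches
does not transfer to a PSSM scan, so significance is empirical and
composition-aware, in three layers:

1. *Pooled null:* residues of the query ORFs themselves are shuffled
   (composition-preserving) and pushed through the identical seeded scan;
   per profile, the conditional (given-seeded) score distribution is
   summarized by a peaks-over-threshold tail — exponential above the 80th
   percentile with the mean-excess scale. Location is shifted upward (never
   downward) for queries longer than the null's reference length, since
   conditioning on seeding makes the score distribution nearly length-free
   below it.
2. *Per-query multiplicity:* the p-value is Bonferroni-corrected by the
   number of profiles the ORF seeded against, making the threshold a
   per-query error rate.
3. *Query-specific confirmation:* any candidate that passes the pooled
   null is re-tested against shuffles of that specific ORF versus that
   specific profile, because score nulls vary with query composition
   (shuffles of a marker scored against its own family's profile run
   hotter than pooled shuffles).

Defaults: null exceedance < 10⁻⁴ at score ≥ 25 bits. Planted markers at
30% divergence score in the hundreds of bits, so the design margin is
large; 3000 composition-preserving shuffles of planted markers produce zero
hits, and whole-genome screens of the synthetic host produce at most a
stray hit or two — far below the 5-marker verdict threshold.

**Verdict.** A bin is NCLDV iff it has ≥ 5 distinct markers (`min_markers`)
and no rRNA; rRNA presence forces `cellular` regardless of marker hits;
anything else is `ambiguous`. The threshold 5 leaves wide margin: real and
simulated viral bins carry ~30, and the screen's false positives are ~1 per
genome. rRNA detection is seeded nucleotide alignment against the SSU set
at ≥ 75% identity over ≥ 300 bp.

## rRNA classification

A pair enters classification only when both mates independently align to
the SSU reference above 80 bits — the strict mapping of the original
two-stage rRNA confirmation (a tool-specific e-value cutoff again does not
transfer; 80 bits plays the same near-certain-rRNA role at read length).
Mates are joined as `fwd + N + revcomp(rev)`. The classifier is RDP-style:
per-genus 8-mer presence probabilities (m + 0.5)/(M + 1), uniform priors,
scored over the query's *distinct* words; words containing the joining N
carry no signal, which is tested by comparing joined against plain
concatenation. Bootstrap confidence resamples ⌈W/8⌉ words 100 times;
assignment is truncated at the deepest rank with confidence ≥ 0.8 (word
size, bootstrap count and cutoff are the classical defaults of this
classifier family). Composition summaries report nested counts and
percentages; 16S- and 18S-origin assignments are pooled in one table
(domains remain distinguishable by rank).

## Genome finishing

**Exact-overlap merging** joins contigs whose terminals overlap by
*more than* 100 bp at 100% identity, both orientations, iterated to
fixpoint. A contig end with two distinct qualifying partners is left
unmerged and logged: the original merge order of an interactive finishing
session is unrecoverable, and silently creating a chimera is worse than
leaving fragments. Overlap length is computed by a KMP prefix-function
pass gated by a fast substring probe.

**N50** is the length of the contig at which the descending cumulative
length first reaches half the total (brute-force-oracle tested on 1000
random length sets).

**ANI** follows the common fragment convention, since no specific method
was named for this statistic: 1 kb fragments, qualifying at ≥ 70% identity
over ≥ 50% of fragment length, mean identity of qualifying fragments,
reported in both directions plus their mean. On a 0.7%-substituted copy of
a 200 kb genome the estimator returns 99.3 ± 0.05 across seeds. Seeded
placements are verified gaplessly and fall back to Smith–Waterman only
when gapless identity fails the 70% gate.

**Read mapping** is seed-and-extend (21-mer seeds) with gapless mismatch
verification at a 99% identity gate; the simulator is substitution-only, so
gapped extension could not change a placement at that gate. A read with
several equally good placements goes to the first best site in scan order
(contig order, ascending position, forward before reverse strand) — the
deterministic "first best site" convention for ambiguous reads. SNV calls
require depth ≥ 5 and alternate-allele fraction ≥ 0.2; these caller
parameters were chosen so that a clean clonal genome yields ≪ 1 SNV/kb
while a 50:50 two-strain mixture at 1 variant/kb is fully recovered, as no
caller configuration was specified for the original statistic.

## Orthogroups and presence/absence clustering

Orthogroups are connected components of the all-vs-all protein graph with
edges at bit ≥ 50 and ≥ 50% coverage of the shorter sequence (4-aa word
prefilter). Components replace MCL-style orthology refinement because the
downstream consumer is binary presence/absence, not fine orthology.
Proteins whose component spans a single genome count as that genome's
private proteins.

Genome clustering is average linkage on Jaccard distance over the binary
matrix. Node support: BP is the fraction of 500 column-resampled trees
containing the node's leaf set; AU comes from the multiscale bootstrap —
resampling at scales r ∈ {0.5, …, 1.4}, fitting
z_r = Φ⁻¹(1 − BP_r) = v√r + c/√r by least squares and reporting
AU = 1 − Φ(v − c). Nodes saturated at every scale are assigned AU = 1
directly (the regression is degenerate there). Jaccard is a choice, not a
reconstruction: the original distance metric for binary data is unstated,
which is why BP is always reported alongside AU and the acceptance checks
rest on BP.

On planted two-block ("lifestyle") matrices the blocks come back as sister
clades at BP ≥ 0.95 even when one genome's concatenated-marker NJ position
is planted inside the other block — the testable form of content clustering
dissociating from phylogeny.

## Taxonomy affiliation, rhodopsin typing, marker tree

Affiliation takes the top ten hits below e-value 10⁻⁵ per protein; the
category is the *set* of lineages among them (archaea and bacteria pooled
as Prokaryote upstream of this function; whether phage hits belong in that
pool is left to the caller's labels). Rhodopsin typing aligns the query to
the ungapped anchor sequence of a reference alignment and reads off the
three motif columns and the spectral-tuning column; only methionine at the
tuning site yields a spectral call ("green") — any other residue is
reported without a claim, as that is the only anchored rule. The marker
tree is canonical neighbor joining on p-distances over concatenated
alignments with pairwise deletion for missing markers; NJ is exact on
additive matrices, which is the oracle used.

## Competitive recruitment

Stage 1: translated search of each read against the viral proteins, keep
reads with any hit ≥ 50 bits. Stage 2: re-search survivors against viral ∪
decoy; retain a read only when its single best hit is viral, with ties
broken by a seeded uniform draw over the tied references. The decoy is a
labeled synthetic proteome: the computation under test is competitive
best-hit retention, not the contents of any particular database. A gene
counts as expressed at ≥ 1 retained read (configurable); cross-sample
comparison correlates log10(RPKM + 1) over genes expressed in either
sample (the exact transformation behind the original regression statistic
is unstated, so the log form is this package's choice, stated here).
Identity histograms are 1%-binned; an "endemic-like" flag marks genomes
whose > 90%-identity mass stays below 10% — recruiting only distant
relatives.

## Problem sizes

The default test and acceptance scenario uses a 1 Mb host + 300 kb virus
with 200k read pairs, 47 marker families, 500 bootstrap replicates for
presence/absence support, 2000 rRNA pairs and a few hundred recruitment
reads; the full suite runs in about two minutes and the acceptance script
in about one. These sizes were chosen so that every stochastic check has
comfortable statistical margin while the whole pipeline remains a desk-
scale computation.

## Known limitations

- The marker screen is a PSSM scan, not a profile HMM; insertion-heavy
  homologs would score worse than under a full Plan7 model.
- The read mapper and ANI verifier assume substitution-dominated
  divergence; indel-rich data would need the Smith–Waterman fallback to
  carry more weight than it does here.
- AU support is a regression approximation; BP is the load-bearing
  support value.
- The simulator omits chimeras, indels and real MDA branch processes, so
  sensitivity numbers on fixtures bound real-data performance from above.
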