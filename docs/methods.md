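# Methods

This note records the models, decision rules, parameters and numerical
choices behind genokit, and what the synthetic benchmarks do and do not
demonstrate.

## Coordinates and formats

All internal intervals are 0-based half-open. GFF3 is read as 1-based
inclusive and converted on parse; BED output is 0-based half-open. Genome
FASTA access is indexed and lazy (pyfaidx), so region extraction never
loads a whole chromosome. GFF3 hierarchy assembly (gene → mRNA/transcript →
exon/CDS/UTR) is delegated to gffutils over an in-memory database; a cheap
pre-scan adds line-numbered errors for coordinate violations, which the
database layer does not report. When a transcript has exon and CDS rows but
no explicit UTR rows, UTRs are inferred as the exonic intervals outside the
CDS span (5′/3′ assigned by strand); explicit `five_prime_UTR` /
`three_prime_UTR` rows take precedence. Children citing unknown parents are
skipped with a logged warning rather than aborting a batch.

## Feature extraction

Multi-segment features are concatenated in ascending genomic order and
reverse-complemented once for minus-strand models, so every sequence is
reported in transcription orientation. The promoter is the `promoter_len`
bases immediately upstream of the gene's transcription start, strand-aware
and truncated at the contig edge; the default of 2,000 bp is a common
convention for plant promoter analysis and is overridable everywhere it
appears. For gene-level requests on multi-isoform genes the longest-CDS
isoform is used. Translation uses the standard codon table, frame 0, stops
at the first stop codon, and tolerates a trailing partial codon with a
warning — annotation-derived CDSs are frequently one or two bases off a
clean multiple of three and aborting a batch for that is unhelpful.

Windowed tracks tile each contig left-to-right with a fixed width (last
window short). GC content excludes N from the denominator (an all-N window
scores 0 and carries a flag); k-mer counts are exact, overlapping, and
assigned to the window containing the occurrence start; gene density counts
genes whose start lies in the window — start-only assignment keeps counts
integral and independent of gene length.

## Homology

The standard 12-column tabular alignment format is the interchange point:
any external all-against-all protein aligner can feed the pipeline. The
built-in aligner exists so the whole toolkit runs without third-party
binaries at desk scale; it is a local aligner (Biopython's PairwiseAligner)
with BLOSUM62, gap open 11 / extend 1 for proteins and
match 2 / mismatch −3, open 5 / extend 2 for nucleotide template matching.
Identity is identical columns over all alignment columns (gaps included).
Alignments shorter than 30 columns are discarded in all-vs-all mode: a raw
local-alignment score has no significance model, and without this floor a
chance 6-residue perfect match between unrelated proteins would sail
through an identity-only filter that a real aligner's e-value cutoff would
catch. Tests validate the aligner's scores against an independent
pure-Python Gotoh dynamic program.

Homolog filtering: self-hits removed; per query the top 5 distinct subjects
by bit score (the best-5 convention of MCScanX-style pipelines; the
identity threshold is user-set, default ≥ 60%, applied inclusively to the
best-scoring record per pair); unordered pairs de-duplicated keeping the
best score. Filtering is order-independent by construction.

Representative-transcript selection aligns every transcript to every CDS
template, computes identity and template-side coverage (the template is
the trusted annotation; coverage on that side asks "how much of the real
CDS does this transcript account for"), applies identity ≥ 90% and
coverage ≥ 50% inclusively, groups by locus via the underscore rule
(template id up to the *last* underscore, whole id when there is none) and
picks the longest qualifying transcript, breaking length ties
lexicographically for determinism. The per-locus density table counts
transcripts *after* thresholding — the count is then interpretable as
"isoforms supported by the template", at the cost of hiding sub-threshold
matches.

## Collinearity

Anchors are homolog pairs mapped to gene ranks (0-based order along each
chromosome by start, ties by gene id). The chain DP is run per chromosome
pair and per orientation — a plus pass over ascending subject ranks and a
minus pass over descending ones; handling inversions as a second pass is
simpler than signed DP and independently testable. Score: `match_score`
per anchor, minus `gap_penalty` per intervening gene rank summed over both
genomes; rank gaps larger than `max_gaps` on either side break a chain.
Defaults (match 50, gap penalty 1, minimum block 5, max gaps 25, overlap
ratio 0.5) mirror the conventions of MCScanX-family tools and are all
overridable.

Chains are extracted greedily: the DP runs, the best chain is emitted and
its anchors removed, and the DP re-runs on the remainder until the best
chain falls below the minimum block size. Re-running after each emission
guarantees every emitted chain is optimal over the anchors still available
— the property the exhaustive-enumeration oracle in the tests checks — at
O(k·n²) cost, which is negligible at the anchor counts per chromosome pair
seen in practice. Each anchor joins at most one block per orientation pass;
cross-orientation redundancy is left to the overlap filter, which processes
blocks in descending score order (ties: more anchors, then lexicographic
chromosome pair) and keeps a block iff its shared-anchor fraction against
every kept block, measured against the smaller block, stays within
`max_overlap_ratio`. The smaller-block denominator makes a sub-block of an
already-kept block score ratio 1 and be dropped, which is the intended
redundancy semantics.

Intra-species runs (same files for both sides) drop self-pairs and collapse
(a,b)/(b,a) duplicates before chaining. Block headers in the
MCScanX-dialect output carry `e_value=0`: no block significance model is
defined here, and consumers that parse structure only are unaffected.
`concordance(test, reference)` is |test ∩ reference| / |test| over
unordered block gene pairs — the directional agreement measure used to
compare two synteny callers, 0 (with a warning) for an empty test set.

## Gene families

The contract begins at the HMMER3 per-domain table (`domtblout`); running
the scan is the job of an external engine, so no binary is needed to test
the decision rules. Parsing is delegated to Biopython's SearchIO
(`hmmsearch3-domtab`) behind a row pre-filter that skips malformed rows
with a warning instead of aborting. Per (protein, model) the best hit is
the lowest *independent* (per-domain) e-value — multi-domain proteins must
be judged per domain, and the full-sequence e-value can be carried by an
unrelated domain — with larger coverage breaking ties. Coverage is
model-side, `(hmm_to − hmm_from + 1)/model_len`: the question is whether
the conserved domain is complete, and completeness is defined against the
model's match states. Membership requires, for every required model of the
family, e-value ≤ 1e-5 (inclusive) and coverage strictly > 0.80; a hit
covering exactly 80% of the model fails. Membership is monotone in both
thresholds (relaxing never removes a member), which the tests assert.
Identical member sequences collapse to one representative with the
duplicates noted; at sequence extraction, isoforms sharing a locus
(underscore rule) reduce to the longest — grouping "longest" by locus was
chosen over identical-sequence clusters because locus-level redundancy is
what downstream phylogenetics cares about.

Precision and recall are TP/(TP+FP) and TP/(TP+FN) against disjoint
planted truth sets; undefined ratios (empty denominators) are reported as
absent rather than 0.

## Primers

Round 2 is deliberately literal: forward = `cds[0:20]`, reverse =
`revcomp(cds[-20:])`, product = whole CDS; it exists to re-amplify the
round-1 product with maximal specificity inside it, and a CDS under 40 bp
is an error. Round 1 enumerates oligos of 18–25 nt fully inside each UTR of
the spliced transcript. Hard constraints: per-oligo Tm within ±3 °C of the
60 °C target and pair ΔTm ≤ 3 °C; GC 40–60% is a soft preference. Ranking
minimises Tm deviation plus a GC penalty (distance to the band / 10) plus
ΔTm/3; the top 5 pairs are returned, and an empty list (with a warning) is
a legitimate outcome for unfavourable UTRs. Pairing uses a bounded beam
(top ~25 candidates per side) so candidate explosion on long UTRs cannot
blow up the search; thermodynamics are engine-agnostic, so an external
primer-design engine can replace the built-in scorer behind the same
contract without changing callers.

Melting temperature: Wallace rule `2(A+T) + 4(G+C)` below 14 nt, else
nearest-neighbor thermodynamics (Biopython's default unified parameter
set) at 50 mM monovalent salt and 250 nM oligo. Self-complementarity is the
longest complementary run between the oligo and itself over all ungapped
offsets; hairpin potential is the longest self-foldback stem with a loop of
at least 3 nt. Both are exact brute-force computations — oligos are ≤ 25 nt,
so cleverness would buy nothing.

## Synthetic fixtures, and what the tests show

The genome-pair generator emulates the input shape of a two-species
collinearity study: single-chromosome genomes of single-transcript,
single-exon gene models (60 bp UTRs flanking a 300–750 bp CDS back-translated
from a random protein), random intergenic spacers of 100–300 bp, genes on
both strands; genome B carries copied segments of A whose proteins are
point-substituted to a target identity (default 12 genes at 90%, matching
the defaults of the recovery benchmarks) and optionally inverted in gene
order. Everything derives from one `random.Random(seed)` stream, so a fixed
seed yields byte-identical files.

The family benchmark plants, per family, ≥ 33 positives bearing qualifying
hits for all required models (e-value ≤ 1e-6, coverage ≥ 0.9 — comfortably
inside the calling thresholds, as curated family members would be) and
1,000 negatives that carry no hit, one domain of a two-domain family, or
sub-threshold hits (e-value 1e-3, or coverage exactly 50%). Sizes mirror a
published composite benchmark design: five families, one composite,
33 positives each, 1,000 negatives.

What passing does *not* show: real genomes have multi-exon genes,
alternative isoforms, tandem arrays, transposon-derived repeats and
segmental duplications that stress anchor chaining far harder than clean
planted segments; real domain hits have borderline e-values and fragmented
envelopes rather than a designed margin; and real UTR annotation is often
missing, which round-1 primer design treats as an error rather than
falling back to flanking genomic sequence. The planted benchmarks validate
the decision rules and the chaining optimality, not robustness to
annotation noise.

## Scale choices

Test and benchmark sizes (30–250 genes per genome, ≤ 20 anchors for the
enumeration oracle, 200 oracle instances, 1,000-negative family benchmark)
were chosen so the full suite exercises every code path in well under a
minute per component on a laptop-class single core; the oracle instance
cap exists because the exhaustive chain enumeration is exponential in the
worst case, and 20 anchors keeps it exact yet tractable.

## Known limitations

- One transcript hierarchy level (gene → mRNA/transcript); trans-spliced
  or parentless models are skipped with warnings.
- The built-in aligner is quadratic per pair; all-vs-all is for desk-scale
  inputs, and genome-scale runs should supply a precomputed table from a
  production aligner.
- No tandem-array detection or block significance statistics; block
  e-values are emitted as 0 in the MCScanX-dialect output.
- qPCR-style short-amplicon design is exposed only as a constraint preset
  (product inside the CDS) and has not been tuned against any wet-lab
  reference.
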