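# Methods

## Scope and data model

`mispath` classifies missense (and stop-gained) single-nucleotide variants
using only local files: per-gene protein and CDS reference sequences
(FASTA), multiple sequence alignments of homologs (aligned FASTA or CLUSTAL
`.aln`), a curated known-variant table (TSV), and a spliced-exon-length
table. One *combined* ortholog+paralog protein alignment drives
classification; separate ortholog/paralog alignments (protein and
nucleotide), when present, feed only the conservation report. The human
reference row of every alignment must, once ungapped, equal the reference
sequence; this is validated at load time.

All coordinates are 1-based and inclusive. Everything nucleotide-level
operates in spliced CDS space: genomic coordinates, strands and intron
sequences are out of scope, because the only intron-dependent quantity the
pipeline needs — the position of the last exon–exon junction — is fully
determined by the spliced exon lengths. The standard genetic code is
assumed throughout (no selenocysteine or alternative codes).

## Conservation scores

**WPC.** At the variant's column, `WPC = 100·a/n` where `a` counts non-human
rows whose residue equals the unmutated human residue and `n` counts
non-human rows with any residue there. Two choices the score's definition
leaves open are fixed as follows: gapped rows are excluded from both
numerator and denominator (a gap carries no residue evidence), and the human
row itself is excluded so the score measures homolog support rather than
self-match. A column at which every homolog is gapped has no defined WPC;
this surfaces as an explicit error rather than a silent default, and the
caller decides how to proceed. WPC is reported on a 0–100 percent scale —
the operating cutoffs (40 with the profile score, 49 without) are
percentages.

**PSIC-style profile.** The profile score follows the
position-specific-independent-counts idea — judge a substitution by the
whole column profile rather than a single match count — but its published
description does not pin down an implementation, so the internals here are
the package's own and are deliberately simple:

* Row redundancy weights: rows are clustered by single-linkage at ≥ 94 %
  identity (computed over mutually ungapped columns); each cluster shares
  one unit of weight equally among its members. An exact duplicate row
  therefore changes nothing — a property the tests assert to 1e-6 — and the
  total non-gap weight `N` at a column approximates the number of
  independent observations.
* Per-column value for residue `r` with weighted count `W_r`:
  `value = ln( ((W_r + q) / (N + 20q)) / (1/20) )`, pseudocount `q = 1`,
  uniform 1/20 background. Values are finite for all 20 residues at every
  column.
* The score of a substitution is the absolute value difference between
  reference and alternate residues at the column (symmetric, ≥ 0, 0 for a
  self-substitution). Stop codons are never profile-scored; stop-gains are
  handled by the decay rule upstream.

Because these internals are a reimplementation, the shipped 1.03 cutoff may
not transfer exactly to other alignment collections; the evaluation module
exists precisely to re-derive cutpoints on whatever labeled data is at hand.

**BLOSUM62** (reported, not used for decisions) comes from the published
matrix as shipped with Biopython.

## Coordinate mapping

Protein→CDS mapping anchors a ten-residue peptide starting at the variant
(taken backwards when the variant lies within ten residues of the
C-terminus) and searches the CDS for a codon window translating to it; the
match must be unique, and the search is order-independent — any traversal
order yields the same answer or the same ambiguity error. All
single-nucleotide edits of the reference codon producing the alternate
residue are then enumerated (validated in tests against exhaustive
9-neighbour enumeration for every sense codon × every target residue).
When more than one edit is causal the DNA location is ambiguous:
nucleotide-level conservation output is suppressed, but protein-level
classification is unaffected. CDS→protein mapping is direct
(`prot_pos = ceil(cds_pos/3)`); synonymous changes are visible as
`alt_aa == ref_aa`. Flanking-sequence input (≥ 100 nt, beginning at the
mutated base) is located by exact search with position 1 restored to each
of the four possible reference bases; zero or multiple matches are errors.

**Stop-gain rule.** A premature stop is auto-pathogenic iff the first
nucleotide of its codon lies strictly more than 50 nt (configurable)
upstream of the last exon–exon junction — i.e. the transcript is expected
to be degraded by nonsense-mediated decay. Measuring from the codon's
*first* nucleotide, and treating stops in the final exon (negative
distance) or in single-exon genes as not auto-pathogenic, are the package's
choices where the rule's prose is silent. Stops that fail the distance test
fall through to the normal pipeline.

## Decision pipeline

Ordered rules: (1) qualifying stop-gain → Pathogenic; (2) outside any
functional hotspot → Benign (h); (3) profile delta below cutoff (only when
the PSIC feature is on) → Benign (a); (4) WPC ≥ cutoff → Pathogenic, else
Benign (a). Threshold senses are: WPC pathogenic at ≥ cutoff, PSIC benign
at strictly < cutoff. Two printed statements about the two-feature mode
conflict (a WPC ≥ 40 call vs a PSIC-benign call for the same variant); the
pipeline ordering — PSIC-benign tested first — is what is implemented, and
the exhaustive decision-table test pins every branch including the exact
boundary values 40, 49 and 1.03. Both the hotspot gate and the stop-gain
step are config toggles (the stop-gain step is conventionally disabled when
benchmarking against catalogues that exclude nonsense variants).

A hotspot is any window of ±`range_aa` residues (default 100, inclusive at
both ends) containing at least one known disease-associated variant
(classifications `pathogenic` or `unspecified_functional`). A catalogue
record at the query's own position is not evidence for the query. The
predicted phenotype is the modal named phenotype among in-window pathogenic
records, each record counting once (per-variant, not per-publication);
`unspecified_functional` records count toward hotspot status and window
totals but never contribute a name. Frequency ties break to the phenotype
of the nearest record, then lexicographically — deterministic and
documented, since the underlying procedure is silent. Distance weighting
was considered and rejected in favour of unweighted counting (simplest rule
consistent with "most frequent in range").

## Training and evaluation

Pathogenic is the positive class everywhere. Balanced accuracy =
(sensitivity + specificity)/2 on a 0–100 scale. The trainable pipeline is
exposed as a scikit-learn estimator (`CutpointClassifier`): `fit` grid
searches the WPC cutoff in steps of 1 over 0–100 and (in two-feature mode)
the PSIC cutoff in steps of 0.01 over the observed range — the grid
resolutions match the precision at which cutpoints are reported — maximizing
balanced accuracy of the *full gated pipeline* on the training rows; ties
break to the smallest cutoff, making the result row-order invariant.
`GeneGroupedKFold` shuffles genes with a seeded RNG and assigns each gene
greedily to the currently smallest fold by variant count, so folds are
approximately equal in variants (not genes) and no protein appears in two
folds. Cross-validation optimizes on k−1 folds, evaluates on the held-out
fold, and reports fold means for accuracy and cutpoints. The averaged ROC
is vertical averaging of fold curves on a fixed 101-point FPR grid with
trapezoid AUC — one concrete choice of multi-fold ROC averaging, which the
source procedure names but does not define. Per-fold curves use the gated
decision score (WPC where the benign gates pass, shifted below the passing
range where a gate forces benign) and sklearn's threshold sweep; AUC equals
the Mann–Whitney pairwise statistic, which the tests assert to 1e-9 against
an independent pairwise oracle.

## Synthetic data: what it emulates and what it does not

The generators stand in for curated catalogues and database-derived
alignments. Per gene: a random M-initial protein (uniform residues), a CDS
assembled from uniformly chosen synonymous codons plus a stop, 2–6 exons
with random lengths, and a homolog alignment in which each row matches the
human residue at column *j* with probability `profile[j]`, is otherwise
uniform over the remaining 19 residues, and is gapped independently at 5 %
per cell. Study defaults — 100 genes, 400-residue proteins, 30 homologs,
per-column conservation uniform on [0, 1], one planted hotspot region of 60
residues per gene with a phenotype from a fixed pool, 8 pathogenic + 8
benign catalogue records per gene, 2000 labeled queries, generative
pathogenicity threshold 0.55 — were chosen once as a realistic desk-scale
benchmark. A query's true label is pathogenic iff it lies in the hotspot
window of a planted disease record *and* its column's generative
conservation reaches the threshold, so the generative truth has the same
gated structure as the pipeline and the only score noise is binomial
sampling from the finite alignment.

Not emulated: phylogenetic correlation between homologs, indel structure
beyond i.i.d. gaps, residue-exchange biases, realistic codon usage, and
annotation noise in the catalogue. Passing recovery tests therefore
demonstrates correctness of the machinery (scores, gates, training,
folding) under known conditions — not clinical accuracy on real variant
databases, which would require the original curated catalogues and
alignments.

For cutpoint-recovery experiments the labels are planted directly on the
features (uniform WPC/PSIC values, label = the planted rule), so the
optimum is exactly recoverable and "recovered within one grid step" is
well-defined; the catalogue-based experiments instead quantify behaviour
under sampling noise (balanced accuracy ≈ 94 % at the generative cutpoint
with 30-row alignments).

## Numerical and degenerate-input choices

* WPC/percent-conservation with an all-gap column raise; classification
  surfaces the error rather than guessing.
* Single-class training sets, fewer genes than folds, and single-class ROC
  inputs are errors, not silent degenerate outputs.
* Alignment rows containing `.` are read as gaps in CLUSTAL-style input;
  `*` and `.` inside stored alignment rows are rejected to avoid stop/gap
  confusion.
* Known-variant tables accept common classification spellings
  ("Disease", "Polymorphism", "Unclassified") via an alias map onto the
  closed internal vocabulary; unknown tokens fail with the line number.
* Batch classification isolates row-level failures; order of results is
  input order; every row equals a standalone classification on the same
  inputs.
* All generators and training procedures are deterministic per seed; CLI
  runs write a JSON manifest and deterministic commands are
  byte-reproducible.

## Known limitations

* The profile-score internals are a documented approximation; absolute
  delta values (and hence the 1.03 default) are implementation-specific.
* Hotspot evidence is position-window-based only; no weighting by
  recurrence, review status or allele frequency.
* The ten-residue anchor search can legitimately fail on extremely
  repetitive proteins (ambiguity error) — by design, since a unique DNA
  location cannot be certified there.
* Isoform/splice-variant redundancy in user-supplied alignments is not
  deduplicated; alignments are scored as given (the profile's redundancy
  weighting mitigates, but does not remove, heavy duplication).
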