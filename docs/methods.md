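# Methods

This note documents the models, parameter choices and numerical
conventions behind `fltkit`, and what the synthetic-data generators do
and do not emulate.

## Coordinate model

All internal coordinates are 0-based half-open on the forward genomic
strand. Transcript-relative coordinates count from the biological 5′
end, so on the minus strand transcript position 0 is the highest
genomic coordinate. "5′ end of the first exon" and "3′ end of the last
exon" are strand-aware throughout (TSS/TES semantics). Unstranded
annotation records are rejected rather than guessed, because locus
clustering and tag-cluster calling are defined per strand. GTF/GFF3
(1-based closed) and BED (0-based half-open) are converted only at the
I/O boundary, so round trips preserve boundaries exactly.

## Iterative short-read-voting correction

Each iteration locally aligns the short-read pool to the current
long-read sequence and corrects each covered column by strict-majority
vote; insertions vote as whole strings keyed to the boundary they fall
in, and only reads spanning a boundary vote on it. Positions covered by
fewer than `min_votes` (default 3) reads, or without a strict majority
(> 50% of the column), are left untouched — an uncovered or ambiguous
base is better left wrong than flipped on thin evidence. Iteration
stops when fewer than `converge_frac` (default 1%) of bases change, or
after `max_iter` (default 5) rounds; in practice two iterations
suffice at 50× coverage. Per-column pileup depth is capped at 100 to
bound cost on deep pileups.

The built-in aligner is seed-and-extend: exact k-mer seeds (k = 13,
sampled every 2 positions) locate each short read's best diagonal, and
a local alignment over a ±30 nt window is computed with
`Bio.Align.PairwiseAligner` using match +2, mismatch −6, affine gap −6
open / −3 extend — the economy of the common short-read-mapper local
mode this mirrors. Alignments scoring below 30 are discarded. At an
11–12% long-read error rate a 100-nt error-free short read still
carries ~18 clean 13-mers in expectation, so seeding is not limiting.
Voting is unweighted (no base-quality or alignment-score weights), and
whole reads are re-aligned each iteration. Production-scale users can
bypass the built-in aligner by importing SAM local alignments.

Accuracy is measured as matched columns over total columns of the
optimal unit-cost global alignment (computed with edlib). Residual
post-correction error concentrates in the first/last ~5 nt of a read,
where uniform short-read sampling leaves coverage below `min_votes`.

## Collapsing and locus clustering

Reads are processed in order of decreasing exon count (ties: longer
aligned span, then id, for full determinism). A read enters the
non-redundant set iff (i) its junction chain is absent, or (ii)/(iii)
its strand-aware 5′/3′ end lies ≥ 100 nt (`end_distance_min`) from the
corresponding end of every current member with an identical chain.
Criteria (ii)/(iii) are evaluated against same-chain members only
(members with different chains are admitted by (i) anyway); a switch
(`same_chain_only=False`) selects the all-members reading. Mono-exonic
reads share a "chain" only when their spans overlap, preventing
genome-wide collisions of unspliced reads. Absorbed reads are recorded
as support of their closest same-chain member and do not update member
coordinates. Loci are single-linkage clusters of span overlap (≥ 1 nt)
per chromosome and strand; spans that merely touch do not overlap.

## Tag clusters and end validation

A position is signal iff its tag count strictly exceeds the local
background, the maximum of (i) mean tag coverage in a centred 500-nt
window and (ii) depth-normalised RNA-seq coverage over −500…+1500 nt in
transcript orientation. Strict inequality keeps perfectly uniform
tracks from clustering; windows are clipped at chromosome bounds and
means use the clipped width. The depth normalisation factor defaults to
total tags / total RNA-seq coverage. Signal positions within 20 nt on
one strand merge; a cluster carries the summed tag count and the peak
position. 3′-end clusters may be imported directly (BED6) or called
with the same algorithm without the expression term.

End distances are signed — positive when the transcript end lies
downstream of the cluster in transcript orientation — and measured to
the cluster boundary (a switch selects the peak instead); an end inside
a cluster is at distance 0. Validation keeps transcripts with both
ends within 50 nt *inclusive*. With Gaussian tag noise of sd ≤ 10 nt
and depth ≥ 20, ≥ 95% of true start sites acquire a cluster within
20 nt, and reads truncated by > 50 nt are rejected at ≥ 90%.

## Event decomposition

The nine event types are operationalised as follows (the source
workflow names but does not formalise them). Terminal ends are
evaluated first: if the 5′ (or 3′) end differs and the terminal exons
overlap with an identical internal splice junction, the event is a
tandem 5′ (3′) UTR; if the junction differs or the exons do not
overlap, an alternative first (last) exon. A terminal-exon
donor/acceptor shift with an *unchanged* end is treated as an
alternative splice site, not an alternative terminal exon. Internal
differences are maximal genomic blocks where exactly one transcript is
exonic, classified with precedence intron retention > exon skipping >
mutually exclusive exons > alternative splice site:

* **intron retention** — the block is a complete intron of one
  transcript and both flanking positions are exonic in both;
* **exon skipping** — the block is a complete internal exon and the
  other transcript has the exact flanking junction;
* **mutually exclusive exons** — two leftover complete-exon blocks,
  one per transcript, non-overlapping, between the same neighbours;
* **alternative 5′/3′ splice site** — the block is flanked by shared
  exon on one side and shared intron on the other; donor vs acceptor
  follows transcript orientation.

Complex residual blocks fall back deterministically (complete exon →
skipping; complete intron → retention). Subtypes: distal/proximal
compare the FLT end with the reference end relative to the gene body;
upstream/downstream compare splice-site coordinates in genomic
orientation (lower coordinate = upstream). Decomposition is symmetric
in event count, and `decompose(t, t) = []`.

## Co-occurrence statistics

Only isoforms with ≥ 2 events enter. For a type pair (A, B), observed
is the number of such isoforms containing both types; expected is
N·p̂A·p̂B with marginals over the same multi-event isoforms
(independence assumption — the source gives no formula). The p-value
is the one-tailed binomial tail (upper if observed ≥ expected, lower
otherwise) with n = N and p = p̂A·p̂B. Self pairs (A, A) use isoforms
with ≥ 2 events of the type against p̂A². Benjamini–Hochberg q-values
are reported alongside raw p. Note the ≥ 2-event conditioning couples
marginals: coupling between two event types is only detectable when
isoforms lacking both types can still qualify via other events. An
optional TPM > 1 filter restricts the input when expression is
supplied. Cassette-exon 3-divisibility is tested one-sided against
p = 1/3 (microexons: 3–27 nt inclusive).

In-silico random isoforms use the constitutive scaffold (segments
exonic in every isoform of the locus) plus an independent uniform
inclusion choice per maximal alternative block; `n="all"` enumerates
all 2^k combinations.

## Translation

P-sites are the +12 nt position of footprints of length 28–30 nt
(other lengths discarded). The frame-bias statistic is evaluated
exactly as stated in the package README; all-zero counts score 0 (the
0/0 case, continuous with the uniform case), so unsupported ORFs can
never pass the threshold of 5. P-sites on the stop codon are excluded
by default (terminating ribosomes distort periodicity; switchable).
Candidate ORFs are every ATG → first in-frame stop with ≥ `min_codons`
codons (default 10, stop included); among qualifying ORFs the longest
wins, ties by higher score. Note that under the uniform null the score
mean is slightly *negative*, because the sign is −1 whenever frame 0
is not maximal; tests compare against a Monte-Carlo null rather than 0.

The status classifier is a voting ensemble of 21 RBF-kernel SVMs, each
trained on all minority-class samples plus an equal-size seeded
subsample of the majority class, with per-member grid search (defaults
C ∈ 2^−5…2^15, γ ∈ 2^−15…2^3, steps of ×4) under 10-fold CV and a
strict-majority vote (≥ 11 of 21). Features are the six fraction ×
replicate TPMs, six pairwise log2 ratios with pseudocount ε = 0.01,
and the longest-ORF length. Isoforms below 0.01 TPM in every cell are
excluded as unclassifiable. Tests and the acceptance run use a reduced
3 × 3 hyperparameter grid and a few hundred isoforms; the synthetic
profiles are cleanly polysome- vs free-shifted, so recovery there
bounds label noise, not biological ambiguity.

ORFeome collapsing merges ORFs with identical genomic codon chains
(position triplets per codon), which also fixes the reading frame;
isoforms differing only in UTRs therefore share one ORF.

## ORF taxonomy

The best-matching reference ORF maximises shared in-frame genomic
codons (ties: longer reference, then smallest id). Identical chain →
annotated. Variant subtypes compare common prefix/suffix of the codon
chains: suffix-only + exact containment → N-terminal
truncation/extension; suffix-only otherwise → N-terminal divergence;
prefix + suffix with one-sided middle → internal insertion/deletion,
two-sided → internal divergence; prefix-only → C-terminal divergence;
identical codon *set* via a different chain → in-frame; shared internal
run with both termini differing → partial-in-frame (one consistent
reading of an under-specified boundary). Novel ORFs (no shared
in-frame codon) are sub-typed by context: no reference-locus overlap →
novel locus; genomic overlap with a reference ORF → different frame;
else full containment in an annotated 5′UTR/3′UTR/intron of any
overlapping reference isoform.

Tryptic digestion cleaves C-terminal to K/R except before P, emits up
to 2 missed cleavages, and filters to 6–40 aa (standard search-engine
defaults; the source is silent). I and L are kept distinct
(conservative for specificity). FLT-specific peptides are exact-string
absentees from the reference peptide universe; N-terminal truncations
and internal deletions whose breakpoints fall on tryptic boundaries
yield none by construction.

## Synthetic data: scope and limits

The generators emulate: constitutive scaffolds with cassette exons
(3-divisible, stop-sanitised in the scaffold CDS frame), tandem UTR
extensions, donor shifts and retained introns; uniformly placed
long-read errors at 11.45% in a 1:1:1 substitution:insertion:deletion
ratio; geometric-free uniform 5′ truncation over the 5′ half;
Gaussian end-tag noise (sd 5 nt, depth 20 per site); footprints with
frame-0 probability 0.9 and 60 per ORF by default; and log-normal
replicate noise (sd 0.3 in log2) on polysome fractions with a 10:3:1
polysome:monosome:free abundance shift for translated isoforms
(reversed otherwise). Every generator is a pure function of
(truth, seed): fixed seeds give byte-identical output.

Not emulated: homopolymer-biased long-read error profiles, fragment
size selection, cDNA normalisation chemistry, mapping ambiguity,
expression-dependent tag depth, asymmetric (downstream-biased) end-tag
noise (a skew parameter exists but defaults to symmetric), and
partially coding/ambiguous biotypes. Passing recovery tests therefore
demonstrates algorithmic correctness under the stated noise models,
not performance on real libraries.

## Problem sizes

Desk-scale defaults keep every stage in seconds-to-minutes on one CPU:
2–8 chromosomes of 120 kb, 10–120 genes, one long read per isoform,
50× short reads. The correction benchmark uses 50 single-isoform genes
of 1–3 kb per seed and five seeds (250 reads). These sizes are the
package's chosen test conditions; all are configurable.
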