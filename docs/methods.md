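# Methods

This note documents the models, conventions and parameter choices behind
`rrgenesis`, and what the synthetic scenarios do and do not establish about
real data.

## The evolutionary-trap model

After a whole-genome duplication, most duplicated genes are lost.  A locus
that lost its gene can retain an alignable relic of a coding exon only if
the relic does something — the parsimonious explanation being a de novo
regulatory function acting on a neighbouring gene.  The pipeline encodes
this as a conjunction of observable signals: alignability to the reference
exon, location in the gene-lost (not the retained) duplicate locus,
non-coding status in the target annotation, conserved synteny with a
developmental neighbour, and a broken reading frame.  Each signal is one
filter; the funnel is their intersection.

## Coordinates and distance conventions

All internal coordinates are 0-based half-open; GFF3 I/O converts to/from
1-based inclusive.  The distance between a hit and a gene is the minimum
gap between their intervals (0 when they overlap).  "Intervening genes"
are annotated genes lying strictly between the hit and the ortholog.
Overlap for the exon/EST filter means ≥ 1 shared bp; intervals that merely
touch (half-open adjacency) do not overlap.  Hit fusion treats "within
1 kb" as inter-interval gap ≤ 1000 bp (boundary inclusive) and fuses across
strands, recording `mixed` strand when members disagree.

The funnel thresholds default to their literal values — 1 kb fusion, 2 Mb
ortholog proximity, 300 kb synteny window, 100 kb maximum distance, ≤ 5
intervening genes — and a single `scale_divisor` divides all of them
consistently so that toy genomes of a few kb exercise the same comparison
logic.  The tests and the acceptance script run at `scale_divisor=100`,
chosen once as the desk-scale operating point; `1` restores paper-scale
coordinates.

The per-gene multi-hit rule ("more than one hit per gene within 300 kb
discards all of that gene's hits") is evaluated on the hits *entering* the
synteny stage, so a gene presenting two clustered hits loses even a hit
that passed the distance test.  The developmental-flank condition is
evaluated on the target genome (nearest annotated gene on each side within
the synteny window), since those genes are the putative regulatory targets.

## Alignment

Pairwise global alignment uses match/mismatch 5.0/−4.0 and affine gap
penalties 12/3 (a gap of length k costs 12 + 3(k−1)).  Ties between
equally optimal alignments are broken by taking the first alignment in
Biopython's deterministic enumeration, which keeps every downstream number
reproducible.  The internal exon-to-genome aligner is an exact affine-gap
Smith–Waterman over an ACGTN matrix in which N never matches anything;
multiple hits per contig are found by N-masking each reported interval and
re-aligning.  Its score threshold is a fraction of the exon's maximum
attainable score (default 0.5) rather than an absolute value, because
absolute cutoffs are only meaningful within one scoring scheme.  An
external 12-column BLAST-tabular hit file can replace the internal aligner,
with its own (tool-specific) score cutoff.

## Frame assessment

A hit region is *intact* when some single reading frame (six tested)
translates with zero stop codons and its peptide locally aligns (BLOSUM62,
gap 11/1) to the exon peptide over ≥ 95% of the region's codons; "the
entire region" is thus a configurable coverage threshold with 0.95 as the
default.  Everything else is disrupted, with per-frame stop positions and a
frameshift flag as evidence.

## Identity, similarity and Ka/Ks

Percent nucleotide identity divides identical aligned columns by the
alignable reference-exon length (a `shortest`-sequence denominator is
selectable, since both conventions exist in practice).  Amino-acid
similarity is computed per reference codon on the nucleotide alignment: a
codon counts as similar when both triplets are gap-free and the translated
pair has a positive BLOSUM62 score.  Under protein-level constraint AA
similarity stays at 100% while NT identity decays; under DNA-level
constraint (the RR regime) NT identity exceeds AA similarity because a
single nucleotide change can delete a whole codon from the AA numerator.

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions averaged over both sequences, substitution counts averaged with
equal weight over all orderings of multi-hit codon differences, and
Jukes–Cantor correction of both proportions.  Steps through stop codons
count as nonsynonymous, and mutations *to* stops count as nonsynonymous in
the site calculation.  Indels and stop codons are removed before counting,
whole reference codons at a time, with removal counts reported.  Degenerate
cases carry sentinels: `undefined_no_sites` (no differences),
`infinite_ks_zero` (Ka > 0, Ks = 0), `saturated` (JC undefined, p ≥ 3/4).
A pair with zero nonsynonymous differences has ratio 0 even when the
synonymous distance saturates, which happens in very short test alignments.
This is a deliberate method substitution for the maximum-likelihood dN/dS
the original workflow obtained via PAML/PAL2NAL: NG86 is deterministic,
oracle-checkable by pathway enumeration, and adequate for the qualitative
contrast (coding ≪ 1 vs relic ≈ 1); numerical equality with
codeml-derived values is not claimed.

## Ancestral reconstruction and TFBS calling

Ancestral sequences are reconstructed per alignment column by uniform-cost
small parsimony (the Sankoff recursion, which reduces to Fitch's
union/intersection sets on binary trees and handles multifurcating roots
correctly).  The tree is re-rooted at the requested node, and the set of
states attaining the minimum change count is emitted as an IUPAC code.
This replaces probabilistic reconstruction (Prequel in the original
workflow) with a deterministic, exhaustively checkable method.

PWMs take a pseudocount of 0.8 distributed by the background (uniform by
default) before log-odds; scanning covers both strands and reports hits at
relative score ≥ 0.8, where relative score is (raw − min)/(max − min) over
the matrix's score range — invariant to affine rescaling of the matrix.
Uninformative (flat) matrices are rejected.  A site "present in the
ancestor" is scored optimistically: ambiguous positions contribute the best
base in their IUPAC set, so any disambiguation reaching the threshold
counts as presence.  Teleost-specific sites must appear in *every* supplied
teleost sequence (configurable to `any`) and in no other vertebrate nor the
ancestor; sites are identified across species by matrix id plus ≥ 1 shared
alignment column.

S200 is (total PWM hits) × 200 / sequence length per sequence; the
regulatory potential of one set against another is the sum over common
histogram bins (width 1.0 site/200 bp by default, from 0) of the minimum of
the two bin proportions, × 100.

## The synthetic generator

The generator is the package's study system.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| exon length | 60 codons | typical internal coding exon (~180 bp), comfortably above the 20 bp alignability floor |
| nt substitution rate | 0.10/site | deep-divergence relic still alignable (~80–90% identity), as expected for an element conserved by function |
| indel rate | 0.01/site | a few short (1–3 bp) indels per relic |
| planted stops | 2 | unambiguous ORF disruption without destroying alignability |
| flanking genes | 2 per side | enough neighbourhood for flank/synteny logic |
| intergenic spacer | 2000 bp | compact loci; compressed by the scale divisor |
| scale divisor | 1 | literal kb/Mb thresholds; tests use 100 |

Each reference locus yields two target contigs: a retained locus with the
full ortholog complement (the coding ortholog evolves under protein-level
constraint) and a gene-lost locus whose relic is produced by
`degrade_coding_sequence`: substitutions (binomial per site, never creating
an in-frame stop on their own), then exactly `n_planted_stops` stop codons
planted in the coding frame away from the first/last three codons, then
indels that never touch a planted stop.  Planting stops *before* indels
guarantees the stops disrupt whichever frame locally corresponds to the
exon, so a planted relic can never present a stop-free covering frame.
With indels disabled the frame-0 stop scan recovers the planted positions
exactly; with indels, positions are recorded post-shift and incidental
frame-0 stops may add to the disruption.

Exactly one flanking gene per relic carries a developmental GO term (brain
development, a descendant of developmental process in the bundled
mini-ontology); decoy loci re-use the same construction but violate exactly
one filter each — absent ortholog, ortholog on the relic's contig, EST
overlap, dev-ortholog beyond 100 kb (but inside the flank window), a
non-developmental gene shielding the relic from its developmental
neighbour, or an intact (synonymously diverged) relic for the frame stage.

Each planted locus also carries a seven-species substitution-only cohort
(human, mouse, chicken, shark with intact ORFs under protein constraint;
zebrafish, stickleback, medaka sharing the planted stops and one planted
binding motif, diverging under DNA-level constraint with the motif and
stops anchored).  Because the cohort is substitution-only it is its own
alignment.  A bounded, seed-deterministic redraw rejects cohorts in which
genetic drift creates a spurious teleost-specific binding site, so the
planted motif is provably the only one — truth labels stay exact.

A single numpy Generator seeded from the config drives every draw in a
fixed order, so identical configs give byte-identical bundles.

### What the synthetic scenarios do not show

Substitution counts per branch are stylised, not calibrated to real
divergence times; no rate heterogeneity, transition/transversion bias, CpG
effects, or selection on codon usage.  Genomes are few-kb contigs without
repeats, so the repeat-masking step of a real screen is out of scope (inputs
are assumed pre-masked).  The cohort alignments are gap-free by
construction, so MSA error — a real confounder for Ka/Ks and TFBS mapping —
is not exercised.  Passing tests therefore demonstrate the correctness of
the comparison logic, counting methods and truth recovery at desk scale,
not genome-scale sensitivity or specificity.

## Numerical and degenerate-input choices

Alignment of empty sequences, invalid frames/strands, malformed tabular
rows (reported with line numbers), out-of-bounds annotation records,
missing GO roots and tree/alignment name mismatches all raise typed errors
naming the offending field.  Fewer than three codons after indel/stop
stripping raises an insufficient-data error rather than returning a
meaningless ratio.  Fusion with a negative gap, thresholds outside their
domains and unknown config keys are configuration errors.  Zero-length
sequences in S200 sets are skipped with a warning; mismatched histogram
binning triggers a rebin with a warning.

## Problem sizes

The test suite and acceptance script run the full funnel on bundles of 3
planted loci + 6 decoys (≈ 15 query exons against ≈ 16 contigs of 0.3–3 kb)
at `scale_divisor=100`; recovery statistics use 10–20 seeded bundles,
selection signatures 200 paired replicates of 60-codon sequences, and the
parsimony cross-check 20 random topologies of 3–6 leaves on length-30
alignments.  These sizes were chosen as the smallest at which every
statistic of interest is comfortably away from its decision boundary.
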