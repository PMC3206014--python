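# rrgenesis

Discovery and evolutionary characterization of **recycled regions (RRs)**:
genomic segments that were protein-coding exons in a common ancestor, lost
their coding role after a whole-genome duplication (WGD), and survive in the
"gene-lost" duplicate locus because they acquired a new, regulatory
(enhancer) function.

## Who this is for

Comparative and regulatory genomicists studying de novo enhancer birth in
lineages with a WGD (teleost fish being the canonical case).  The teleost
WGD was followed by loss of most duplicated gene copies, so each
human/reference locus typically corresponds to two syntenic fish loci — one
with the functional gene, one where it was lost.  A reference exon that
still aligns to the gene-lost locus, with its open reading frame visibly
broken, but that has been retained next to a developmental gene, is a prime
candidate for an exon recycled into an enhancer.

## The method

**Discovery funnel.** Reference exon sequences (> 19 bp) are locally aligned
to the target genome; hits within 1 kb of each other are fused into one
putative regulatory unit.  Fused hits then pass six filters, in order:

1. *ortholog presence* — the source gene must have an annotated target
   ortholog (removes un-annotated genes);
2. *ortholog proximity* — hits within 2 Mb of any ortholog locus of the
   source gene are removed (those are the retained coding copy);
3. *exonic overlap* — hits overlapping an annotated exon or EST by ≥ 1 bp
   are removed (the relic must be non-coding);
4. *synteny* — developmental genes within ±300 kb of the source exon are
   mapped to their target orthologs; a hit is kept only if it lies < 100 kb
   from such an ortholog with ≤ 5 genes in between, and a gene with more
   than one hit inside a 300 kb span loses all its hits;
5. *developmental flank* — a flanking target gene must carry a GO
   annotation inside the developmental closure (GO:0045165, GO:0032502,
   GO:0030528, GO:0003700 plus all descendants);
6. *frame disruption* — six-frame translated alignment against the source
   exon; a region that aligns over its whole span in a single stop-free
   frame is still coding and is discarded.

**Evolutionary diagnostics.** Surviving candidates are characterized
across species: percent nucleotide identity vs percent amino-acid
similarity relative to the reference exon (RRs show NT > AA — selection on
the DNA, not the protein), and Ka/Ks by Nei–Gojobori (1986) counting with
Jukes–Cantor correction after codon-consistent removal of indels and stop
codons (Ka/Ks ≪ 1 marks coding constraint; relics drift toward 1).
Pairwise global alignments use match/mismatch 5.0/−4.0 with gap
open/extension penalties 12/3.

**TFBS gain.** JASPAR-format PWMs are scanned at an 80% relative score
threshold (min–max normalized, both strands); the ancestral sequence at the
bony-vertebrate root is reconstructed by uniform-cost parsimony on the
alignment; binding sites present in every teleost but absent from all other
vertebrates *and* from the ancestor are called teleost-specific.  S200
(binding sites per 200 bp) summarises sequence sets, and the histogram
overlap of two S200 distributions gives a "regulatory potential"
percentage.

**Synthetic scenarios.** Because real discovery needs whole genome
assemblies, the package ships a first-class generator of desk-scale
evolutionary-trap scenarios: a reference locus with a coding exon, two
duplicated target loci (retained + gene-lost with a planted, stop-disrupted
relic), flanking genes with GO annotations, outgroup cohorts with intact
ORFs, a planted teleost-specific binding motif — plus one decoy per filter,
each violating exactly its named filter.  Every byte of a bundle is
deterministic in the seed.

## Worked example

```bash
cat > demo.yaml <<'YAML'
scenario:
  n_reference_genes: 2
  decoy_classes: [synteny, frame_disruption]
  genome_scale_divisor: 100
funnel:
  scale_divisor: 100
YAML
rrgenesis all --config demo.yaml --seed 42 --out demo_out
```

prints:

```
RECYCLED-REGION DISCOVERY REPORT

Filter funnel:
  stage                     in   out  dropped
  fusion                    28    28        0
  ortholog_presence         28    28        0
  ortholog_proximity        28     4       24
  exonic_overlap             4     4        0
  synteny                    4     3        1
  developmental_flank        3     3        0
  frame_disruption           3     2        1

Candidates: 2
  g1.e1:tgt_1_lost:910-1082  gene=g1  flanks=g1_L1_tb,g1_R1_tb  frame0_stops=2
  g2.e1:tgt_2_lost:910-1090  gene=g2  flanks=g2_L1_tb,g2_R1_tb  frame0_stops=2

Evolutionary diagnostics:
  g1.e1:tgt_1_lost:910-1082  NTid=82.78%  AAsim=71.67%  Ka/Ks=0.802  teleost_TFBS=1
  g2.e1:tgt_2_lost:910-1090  NTid=91.11%  AAsim=88.33%  Ka/Ks=0.8068  teleost_TFBS=1
```

Reading the output: 28 raw alignment hits enter the funnel; the proximity
filter removes the hits on the retained (still-coding) duplicate loci; the
planted synteny decoy dies at the synteny stage and the intact-ORF decoy at
the frame stage; the two planted relics survive.  Both candidates sit in
the gene-lost locus flanked by a developmental gene (`*_L1_tb`), carry two
in-frame stops, show nucleotide identity above amino-acid similarity and a
relic-like Ka/Ks near 1 (versus ≈ 0 for coding orthologs), and contain
exactly one teleost-specific binding site — the planted motif.

The `genome_scale_divisor: 100` maps the funnel's kb/Mb thresholds onto
desk-scale toy contigs; set it to 1 for paper-scale coordinates.

Subcommands `simulate`, `map`, `discover`, `evo` and `tfbs` expose the
individual stages; see `rrgenesis <cmd> --help`.

## Layout

- `src/rrgenesis/synthetic_data.py` — scenario generator (planted RRs,
  per-filter decoys, species cohorts, PWMs, GO, trees)
- `src/rrgenesis/homology_mapping.py` — exon loading, BLAST-tabular input,
  internal local aligner, 1 kb hit fusion
- `src/rrgenesis/rr_filtering.py` — the six-filter funnel and its report
- `src/rrgenesis/evo_analysis.py` — global alignment, identity/similarity,
  NG86 Ka/Ks
- `src/rrgenesis/tfbs_analysis.py` — PWM scanning, ancestral
  reconstruction, lineage-specific sites, S200
- `src/rrgenesis/pipeline.py`, `cli.py` — orchestration, reporting, CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
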