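# y2hseq

Analysis toolkit for **pooled yeast-two-hybrid screens read out by
short-read sequencing** (Y2H-seq), built around the empty-bait background
calibration used to separate genuine bait interactors from the two dominant
artifact classes of pooled selection screens: prey **self-activation** and
**multi-plasmid colonies**.

The motivating experiment is an interactome screen for an ER cargo receptor
(an Erv/cornichon-family protein escorting transmembrane cargo, notably
transporters, into COPII vesicles): a cDNA prey library is transformed into a
split-ubiquitin bait strain, surviving colonies are picked ten to a PCR tube,
and all products are sequenced as one pool per screen. A parallel screen
against the **empty bait vector** measures the library's selection
background. Because no raw data from such screens are bundled here, the
package ships a first-class **synthetic screen generator** that emulates the
wet workflow down to FASTQ reads with full ground truth, so every downstream
stage is testable end to end.

## The model

For each gene *g* with assigned read count *c_g* and CDS length *L_g* (bp),
abundance is expressed as fragments per kilobase per million mapped
fragments,

    FPKM_g = c_g * 10^9 / (L_g * M),      M = total assigned reads.

With the empty-screen FPKM as baseline, a gene identified in the bait screen
(≥ 1 assigned bait read) is **accepted** as an interactor iff, strictly,

    log2((FPKM_bait + c) / (FPKM_empty + c)) > 1.5   and   p < 0.05,

where *c* = 0.5 FPKM is a pseudocount and *p* is a one-sided Fisher's exact
test on the 2×2 read-count table of the two screens. Self-activating preys
survive both screens, so the background baseline cancels them; pure
sequencing depth cannot rescue a gene that is equally abundant in the empty
screen.

Downstream stages mirror a complete screen analysis:

* **quantify** — deterministic exact-seed-and-extend read assignment with
  the standard filtering semantics (unmapped reads dropped; equally good
  multi-gene matches discarded as ambiguous), or direct import of count
  TSV / MAPQ≥30-filtered BAM;
* **tm** — Kyte–Doolittle sliding-window (19 residues, threshold 1.6)
  transmembrane-segment calls, and the fraction of transmembrane proteins
  per FPKM bin among accepted interactors;
* **enrichment** — offline hypergeometric term over-representation with
  Benjamini–Hochberg correction against user-supplied annotations;
* **proteome** — Welch *t* on log2 replicate abundances of a deletion-vs-
  control membrane proteome (UP: log2FC > 1 and p < 0.05; DOWN: log2FC < −1
  and p < 0.05), and the intersection of the down-regulated set with the
  Y2H interactome — the high-confidence receptor-cargo candidates.

## Worked example

Run the default demonstration screen (500 genes, 5% true interactors, 2%
self-activators, 1200 colonies and 100,000 reads per screen):

```sh
y2hseq run --outdir demo_run --seed 1
cat demo_run/report.md
```

```
# Pooled Y2H screen run report

y2hseq version 0.1.0

* library genes: 500
* reads: bait 100000, empty 100000
* bait assignment: 99994 assigned, 0 ambiguous, 6 unassigned
* empty assignment: 99993 assigned, 0 ambiguous, 7 unassigned
* identified (>= 1 bait read): 42
* accepted interactors (logFC/p filter): 29
* Venn bait-identified vs empty-detected: only bait 29, shared 13, only empty 0
* accepted TM / non-TM: 8 / 21
* proteome: 300 quantified, 27 up, 40 down, 233 unchanged
* Y2H x down-regulated overlap: 7 proteins
```

Reading this: 42 genes received bait-screen reads ("identified"); 13 of them
also appear in the empty screen (self-activators and carry-over). The
logFC/p filter accepts 29 — the genes enriched over background. The
calls table (`demo_run/calls.tsv`) holds per-gene counts, FPKM, log2 fold
change, p, BH q and the accept flag, e.g.

```
gene_id  count_bait  count_empty  fpkm_bait  fpkm_empty  logfc  p_value  accepted
g0015    6185        0            71589.9    0.0         17.13  0.0      True
```

Because this is a simulation, `demo_run/truth.tsv` lets you benchmark the
calls; `y2hseq.evaluate_against_truth` reports sensitivity 1.0 and FDR 0.0
for this run. Each stage is also available separately (`y2hseq simulate |
quantify | call | annotate-tm | enrich | proteome`) on FASTA/FASTQ/TSV
inputs you provide.

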