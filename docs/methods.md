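# Methods

This note documents the generative model, the statistical procedures, the
default parameters and the numerical conventions of `y2hseq`, and states what
the synthetic-data experiments do and do not demonstrate.

## Generative model of a pooled selection screen

`simulate.generate_library` builds a prey library of `n_genes` protein-coding
genes. Protein lengths are lognormal (median 400 residues, σ = 0.25, floor
80), matching typical cDNA insert sizes around 1.2 kb; sequences are drawn
from a hydrophilic-biased residue distribution, and a configurable fraction
(`tm_fraction`, default 0.30) of proteins receives 1–3 designed
membrane-spanning stretches of 21 strongly hydrophobic residues. CDSs are
random back-translations (uniform codon choice); a reject-and-resample step
guarantees no two genes share any exact `read_length`-mer, so read ambiguity
can arise only through sequencing error. Library abundances are lognormal
(σ = `abundance_sigma`, default 1 — cDNA libraries are heavy-tailed),
optionally multiplied by `tm_abundance_multiplier` for designed-membrane
genes, then normalized to sum to one.

Ground truth designates independent interactor and self-activator subsets
(`interactor_fraction`, `self_activator_fraction`); a gene may be both. Truth
is written to a separate TSV and never to FASTQ headers.

`simulate.simulate_screen` then models, per screen (BAIT or EMPTY):

1. **Colonies.** Each colony carries one prey plasmid (probability 1 − m) or
   two distinct plasmids (probability m = `multi_plasmid_prob`), drawn by
   library abundance. A colony survives selection iff it carries ≥ 1
   qualifying gene — interactors qualify only under BAIT, self-activators
   always — or leaks through with probability ε = `leak_prob`. Colonies are
   drawn until `n_colonies_picked` survivors (pick-until-n, matching the
   protocol of picking survivors off selective plates), with a bounded draw
   budget raising `SimulationExhaustedError` when survival is impossible.
2. **PCR.** Each colony's inserts are amplified by one independent lognormal
   factor with coefficient of variation `pcr_amplification_cv` (default 0.3),
   mean 1.
3. **Reads.** Exactly `total_reads` single-end reads are drawn multinomially
   with per-gene mass (amplified copies × length) — fragmentation
   proportional to length, so FPKM is unbiased — each read a uniform CDS
   substring with per-base substitution probability `seq_error_rate`
   (default 10⁻³; no indels).

Not modelled: mating efficiency, plate geometry, PCR chimeras, paired ends,
per-pool barcodes (all PCR products are pooled into one sequencing sample per
screen, so per-pool deconvolution is impossible by design; `pool_size`,
default 10, is descriptive only).

### Default artifact rates and what the demo shows

The demonstration defaults (500 genes, 5% interactors, 2% self-activators,
1200 colonies and 10⁵ reads per screen) describe a **stringent** screen:
`multi_plasmid_prob` = 2×10⁻⁴ and `leak_prob` = 2×10⁻⁵. The reason is a
structural property of the accept rule, visible from a Poisson argument
rather than from tuning: at ~90 reads per colony-insert, any colony whose
insert appears in the bait screen and not in the empty screen makes that gene
an accepted call regardless of truth (Fisher p ≈ 2⁻⁹⁰, log2FC ≫ 1.5). The
expected number of such false calls equals the expected number of random
(hitchhiker + leak-through) bait inserts, so low false-discovery regimes are
*only* reachable when artifact colonies are rare — exactly why highly
stringent multi-dropout selection matters in practice. The artifact
mechanisms themselves are exercised at elevated rates in dedicated unit
tests (forced-support and exhaustion cases), and the demo's recovery numbers
should be read as "what the filter achieves when selection is stringent",
not as a general guarantee.

Sensitivity is benchmarked over *pure* interactors (interactor and not
self-activator): a prey that also self-activates is enriched in both screens
and is structurally invisible to background subtraction — the filter rejects
it by design, which the self-activator-rejection metric checks from the
other side.

## Read assignment and FPKM

`quantify.assign_reads` uses exact, non-overlapping seeds of
`min_seed_len` = 20 looked up in a k-mer index and extended to a full-read
Hamming comparison with `max_mismatches` = 2. With ⌊75/20⌋ = 3 seeds and ≤ 2
substitutions, the pigeonhole principle guarantees at least one exact seed,
so the matcher finds every true placement; a brute-force all-pairs recount
oracle verifies exact agreement in the tests. Filtering semantics: no match
within the mismatch budget → unassigned (the analog of dropping unmapped
records); two or more genes matching equally well → ambiguous, discarded
(the analog of a MAPQ cutoff on multi-mappers); ties are never broken
randomly. External count TSVs, or BAM files filtered to primary alignments
with MAPQ ≥ 30, can be imported instead.

FPKM uses the *post-filter* assigned-read total as denominator ("per million
mapped fragments" names mapped fragments); with single-end reads, fragments
equal reads. A zero denominator is an explicit error, never silent zeros.

## Interactor calling

Identified set: every gene with ≥ 1 assigned bait read. Accepted iff
log2((FPKM_b + 0.5)/(FPKM_e + 0.5)) > 1.5 **and** one-sided Fisher exact
p < 0.05 on [[c_b, M_b − c_b], [c_e, M_e − c_e]] — both strict. Design
choices where the procedure is under-determined, each switchable in
`CallingConfig`:

* **Test**: one-sided Fisher's exact on read counts. Counts are the
  primitive observable; the single-pool design has no replicates, ruling out
  variance-model tests.
* **Log base 2**, consistent with the proteome analysis.
* **Zero baseline**: pseudocount 0.5 FPKM rather than exclusion — keeps
  log fold changes finite and rankings intact.
* **No multiple-testing correction in the accept rule** (the rule filters on
  raw p); BH q is reported as an informational column.

**Known limitation — overdispersion.** Reads from one colony are correlated
(~90 reads per colony-insert at demo depth), so a read-level Fisher test is
anti-conservative whenever per-gene counts are dominated by few colonies.
Calibration of the test is therefore verified in the regime where
read-sampling noise dominates: the null experiment (bait and empty generated
under identical rules, 250 genes all self-activating, no interactors) uses
5000 colonies and 2500 reads per screen (~20 colonies and ~10 reads per
gene), where the measured false-positive rate at p < 0.05 stays within
3 Monte-Carlo standard errors of nominal. At high depth-per-colony the raw
p-values should be interpreted as enrichment scores, as they are in
practice.

## Transmembrane annotation

Kyte–Doolittle mean hydropathy over a 19-residue sliding window, threshold
1.6 (the authors' recommended setting for membrane-spanning segments). Runs
of consecutive above-threshold windows become segments spanning the
outermost window extents; runs whose extents overlap are merged — two
windows a few residues apart describe one physical helix. Non-standard
residues score 0 with a warning; sequences shorter than the window yield
zero segments. Prediction operates on the upper-cased, stripped sequence.
Precomputed annotations from any external predictor can be imported; the
downstream analysis consumes only the binary flag. The FPKM-bin table uses
half-open bins [e_i, e_{i+1}) with the last bin closed; default edges are
powers of 10 (the analysis is edge-agnostic and the edges are configurable);
empty bins report an undefined (NaN) fraction.

## Enrichment

One-sided hypergeometric upper tail per term, BH across tested terms. The
universe is the set of genes identified in the screen — the correct
background for a screening library — and terms with no gene in the universe
are skipped. Annotations come from two-column TSV or GMT files; the demo
pipeline generates synthetic GO-like annotations in which one
transporter-activity-style term is enriched among true interactors.

## Proteome integration

log2FC = mean(log2 mutant) − mean(log2 control); two-sided Welch *t* on log2
abundances (standard for n = 3 label-free designs; no variance shrinkage
dependency). UP/DOWN require |log2FC| > 1 and p < 0.05, strictly; everything
else is NS, so the three classes partition the quantified set. Proteins with
missing replicates are excluded and logged, never imputed; non-positive
abundances are an error. When both groups are exactly constant the t
statistic is undefined and p is reported as 1 (no evidence). BH q is an
informational column. The synthetic proteome plants lognormal base
abundances, 10% replicate CV and ±2 log2-unit shifts; at n = 3 this gives
≈ 17 standard errors of separation, so near-perfect recovery of planted
shifts and near-zero null mis-classification are the *expected* outcome —
the test verifies wiring and calibration, not statistical difficulty. In the
demo pipeline, true interactors are preferentially planted down-regulated
(cargo of the deleted receptor), making the Y2H × down-regulated overlap
informative at reduced scale.

## Pipeline, determinism and problem sizes

One `RunConfig` drives all stages; the global seed deterministically fixes
every stage seed (library, screens, annotations, proteome) via spawned seed
sequences, and identical config + seed reproduces every output byte for
byte. Stage wall-clock timings are written to a separate `timings.json` so
the report itself is deterministic. Machine outputs are plain-text
(FASTA/FASTQ/TSV/JSON/YAML) in a single run directory; any stage failure
aborts annotated with the stage name, preserving completed outputs.

Experiment sizes in the test suite and acceptance script — 500-gene demo
screen at 10⁵ reads/screen, 250-gene null calibration, 400-protein proteome
experiments, 300-gene membrane-abundance pattern check (median-split FPKM
bins on accepted genes) — were chosen so each experiment carries enough
genes for stable Monte-Carlo bounds while the whole suite runs in minutes on
one CPU. Scaling the screen up (e.g. toward a 6,000-gene library) changes
runtime roughly linearly in reads and genes but nothing in the code paths.

## Limitations

* Synthetic CDSs are collision-free by construction; real cDNA libraries
  contain homologous genes and shared domains, so real ambiguity rates will
  be higher and the ambiguous-read discard policy more consequential.
* The simulator emits substitution-only single-end reads; indels, adapter
  read-through and quality gradients are out of scope (an external aligner
  feeding the BAM import path covers real data).
* The read-level Fisher test's overdispersion at high depth per colony
  (above) is inherent to the published analysis style, not fixable by this
  implementation without changing the method (a colony-level or
  replicate-based model would be the alternative).
* Hydropathy-scan TM prediction is a classical stand-in; modern deep
  predictors are more accurate, and the import path exists for exactly that
  reason.
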