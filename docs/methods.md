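# Methods

## Problem setting

The package covers the downstream half of a bacterial bulk RNA-seq study on
a single circular chromosome. The input is a per-gene differential
expression table (log₂ fold change and BH-adjusted P, as DESeq2 emits),
plus genome resources: GFF3 annotation, genome FASTA, an operon table, a
TSS table, and GMT gene sets for regulons and curated functional lists.
Everything upstream of the DE table — alignment, counting, dispersion
estimation — is out of scope by design, as is motif discovery itself (MEME
and TomTom are external; the package writes MEME's input FASTA and parses
TomTom's output TSV).

## DE classification

A gene is *up* when log₂FC ≥ log₂(fc_min) and p_adj ≤ padj_max, *down* on
the mirrored condition, otherwise *not significant* — including when p_adj
is missing, which is how DESeq2's independent filtering marks genes it
declined to test. Defaults are fc_min = 1.5 and padj_max = 0.05, both
inclusive: the methods-style statement ("≥ 1.5", "≤ 0.05") is taken as the
operational rule, and exact-boundary genes are vanishingly rare in float
data anyway. log₂(1.5) is computed at run time; the 0.585 seen on plot
legends is only a rounded display value. Genes present in the annotation
but absent from the expression table are *unmeasured* — a distinct state
that breaks cluster runs like not-significant does, but is never counted in
enrichment universes.

## Cluster scan on the circular chromosome

Genes carry an ordinal 0..n−1 assigned by ascending start coordinate.
"Consecutive" means adjacent ordinals, irrespective of strand or intergenic
distance — the co-expression signal of interest is physical neighborhood,
and operons are handled separately at the promoter stage. A cluster is a
*maximal* run of ≥ min_run (default 5) genes with the same DE direction; a
not-significant, unmeasured, or oppositely-moving gene terminates a run,
and there is no gap tolerance. With `circular=true` (the default for a
bacterial chromosome) a run may wrap through the origin and is reported
once, un-split; the implementation rotates the scan to start at a run
boundary, so no maximal run is ever cut. The scan is checked against an
exhaustive brute-force window enumerator on every status vector of length
≤ 8 and on thousands of random vectors, in both circular and linear modes.
`sensitivity_sweep` recomputes cluster counts across a range of k with
identical run semantics; cluster count is non-increasing in k.

No significance model is attached to cluster counts — the cutoff is
descriptive, and the sweep is the tool for judging its stability. A
permutation null would be a natural extension.

## Promoter extraction

The motif-discovery front end reduces the DE list to one representative per
operon. Two readings of "first gene of the operon" are possible: the
operon's literal first gene (which may not be DE) or the most upstream *DE*
gene. The package keeps the first DE gene in transcription order, since the
alternative would inject non-DE genes into a DE-derived list; the choice is
recorded here and visible in the function contract.

Start resolution: a mapped TSS wins over the annotated start codon; among
multiple TSS records the one typed `primary` wins, otherwise the site
nearest the annotated start (a deterministic rule; sources rarely
disambiguate further). A TSS typed `antisense` lies on the strand opposite
the gene, so the gene's strand is switched before extraction and the region
is flagged `flipped`. Other TSS types (secondary, internal, ...) are used
as-is. Without any TSS, the start codon is used: the left coordinate for a
+ gene, the right for a − gene.

Extraction takes exactly `upstream_len` bases (default 250 bp) strand-5′ of
the resolved start, excluding the start base itself; windows wrap around
the origin on a circular genome and are never silently truncated on a
linear one. Extraction commutes with reverse-complementing the genome and
mirroring coordinates, which is property-tested.

## Enrichment

Each gene set is restricted to the stated universe (default: measured
genes; optionally all annotated genes — the choice matters and is logged),
a 2×2 table (in set × DE) is formed, and Fisher's exact test is applied via
`scipy.stats.fisher_exact`. The default alternative is two-sided — the
convention of the statistical environments these analyses are usually run
in — with one-sided `greater` available; the test suite verifies both
against full enumeration over all tables with the observed margins, with
the two-sided tie rule (sum all tables whose point probability does not
exceed the observed one) evaluated in exact rational arithmetic.
Benjamini–Hochberg correction (`statsmodels`' step-up implementation,
cross-checked against the direct formula) runs over one family per
submitted batch — regulons and curated lists are corrected separately, as
they are reported separately. Sets with no members in the universe are
flagged untestable and excluded from the family rather than diluting it.
Per-set output includes the up/down split and the dysregulated fraction
(n_DE-in-set / set size), plus a regulon-vs-regulon overlap report for
comparing database regulons against ChIP-seq-derived ones.

## Auxiliary statistics

* **percent CV** = sample (n−1) standard deviation / mean × 100 over
  per-cell fluorescence intensities; treats the cells as a sample from a
  population. Scale-invariant; zero iff constant.
* **2^−ΔΔCt** with ΔΔCt = (Ct_target − Ct_ref)_test − (Ct_target −
  Ct_ref)_control, assuming doubling-per-cycle efficiency; efficiency
  calibration is out of scope.
* **first_significant_timepoint**: paired one-sided (greater) t test of
  each later timepoint against the first, returning the 0-based index of
  the earliest timepoint with p < α. Zero-variance differences fall back on
  the sign of the mean shift.
* **fold_correlation**: squared Pearson correlation of two log₂
  fold-change vectors (log scale for up/down symmetry); callers wanting
  signed linear folds transform first.

## Synthetic studies

The generator emulates the statistical structure the pipeline assumes, not
the sequence biology: a circular chromosome of `n_genes` genes tiled at
fixed spacing (defaults 1,000 genes × 900 bp + 100 bp gaps ≈ a 1 Mb
desk-scale chromosome), i.i.d. uniform nucleotides, strands Bernoulli
(40% minus), operons formed by grouping contiguous same-strand stretches
(seed probability 0.5, geometric sizes of mean 3, truncated at strand
switches), TSS 10–80 bp upstream for 70% of genes with 10% of those
antisense, and ten regulons of 10–50 uniformly sampled genes. Expression:
background genes are DE with probability 0.1 (fair-coin direction),
planted-run genes are DE in their direction with probability 1, and
planted-regulon members are DE at an elevated rate (the recovery studies
use 0.5 = 5× background with set size 30 in a 1,000-gene universe). DE
genes draw |log₂FC| from N(2.0, 0.6) floored at log₂(1.5) + 0.1 and p_adj
uniform below 0.05; null genes draw p_adj uniform above 0.05. One seeded
`numpy` generator is threaded through the sub-generators in a fixed order,
so identical configs give byte-identical files.

Two deliberate idealizations: each planted run is flanked by one forced
non-DE gene so that it is exactly a maximal run (recovery can then be
scored on exact membership), and adjusted P values are drawn directly
rather than derived from simulated counts — the pipeline consumes results
tables, so simulating the DE test would only test DESeq2. Consequently,
passing recovery tests demonstrates the scan/enrichment machinery, not
robustness to count noise, batch structure, or correlated background DE,
none of which the generator emulates.

## Pipeline and numerical choices

`run_pipeline` chains the stages from one YAML config, writes plain-text
outputs and a JSON manifest of per-stage counts and warnings, and fails
fast with the failed stage recorded. A missing operon table degrades
gracefully (every DE gene keeps its own promoter, flagged in the manifest)
because operon predictions are an external resource; a missing TSS table
falls back to start codons. The Circos exporter writes karyotype and
log₂FC track text (red = significant up, green = significant down, grey
otherwise) and skips-with-warning expression rows absent from the
annotation; rendering is left to Circos.

Problem sizes in the shipped tests and in `scripts/acceptance.py` (20
studies of 1,000 genes; exhaustive vectors to length 8; 1,000 random
length-200 vectors; enumeration oracles at margins ≤ 12) were chosen so the
full suite completes in well under a minute on one core while still
exercising every wrap, flip, and tie case; all scale linearly if enlarged.

## Known limitations

Single-chromosome genomes only (no plasmids); no gap-tolerant cluster mode;
no PWM scanning or motif discovery; enrichment assumes a fixed,
user-stated universe and exchangeable genes (no gene-length or GC bias
correction); the locus-tag-ordering fallback presumes tags numbered along
the chromosome, which renamed or merged annotations can violate.
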