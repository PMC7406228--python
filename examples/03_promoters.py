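"""Extract promoter regions of DE genes for motif discovery.

The DE list is first reduced to one gene per operon (co-transcribed
genes share a promoter), each representative's transcription start is
resolved — mapped TSS where available, with antisense TSS switching the
strand, start codon otherwise — and the 250 bp upstream of that start
is written as FASTA, ready for a motif finder such as MEME.
"""

from declust import SimulationConfig, ThresholdConfig, generate_study
from declust.classify import classify_table
from declust.model import DEStatus
from declust.promoters import (
    build_promoter_regions,
    emit_promoter_fasta,
    first_in_operon_filter,
)

sim = SimulationConfig(seed=11, n_genes=300, gene_length=90, intergenic_gap=10,
                       tss_coverage=0.7, antisense_tss_fraction=0.1)
genome, annotations, operons, tss, *_, expression, _ = generate_study(sim)
cfg = ThresholdConfig()

statuses, _ = classify_table(expression, cfg)
by_locus = {a.locus_tag: a for a in annotations}
de_loci = [l for l, s in statuses.items() if s is not DEStatus.NOT_SIGNIFICANT]

reduced = first_in_operon_filter(de_loci, operons, by_locus)
print(f"{len(de_loci)} DE genes -> {len(reduced)} after operon filtering")

tss_map = {}
for t in tss:
    tss_map.setdefault(t.locus_tag, []).append(t)
regions = build_promoter_regions(reduced, genome, tss_map, by_locus, cfg)

n_tss = sum(r.source == "tss" for r in regions)
n_flipped = sum(r.flipped for r in regions)
print(f"{len(regions)} promoter windows of {cfg.upstream_len} bp: "
      f"{n_tss} anchored on a mapped TSS ({n_flipped} antisense, strand "
      f"switched), {len(regions) - n_tss} on the start codon")

emit_promoter_fasta(regions, "scratch/promoters.fasta",
                    "scratch/promoters.manifest.json")
print("FASTA written to scratch/promoters.fasta; submit it to MEME "
      "(up to 5 motifs, E <= 0.05) and feed the TomTom matches back "
      "into the enrichment stage.")
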