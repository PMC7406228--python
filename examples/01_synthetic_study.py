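"""Generate a seeded synthetic study and look at what was planted.

The generator emulates the inputs of a bacterial RNA-seq downstream
analysis: a circular genome, operons, TSS annotations, regulons and a
DESeq2-style DE table with planted same-direction gene runs and planted
enriched regulons.
"""

from declust import SimulationConfig, generate_study

cfg = SimulationConfig(
    seed=11,
    n_genes=300,
    gene_length=90,
    intergenic_gap=10,
    planted_runs=((40, 6, "up"), (297, 5, "down")),  # second run wraps the origin
    planted_regulons=((0, 0.6),),
)
genome, annotations, operons, tss, regulons, curated, expression, truth = (
    generate_study(cfg, out_dir="scratch/example_study")
)

print(f"genome: {genome.length:,} bp, circular={genome.circular}")
print(f"genes: {len(annotations)}, operons: {len(operons)}, TSS rows: {len(tss)}")
print(f"regulons: {len(regulons)}, planted enriched: {truth.planted_regulon_names}")
for pc in truth.planted_clusters:
    print(
        f"planted run: {pc['direction']} x{pc['length']} starting at "
        f"ordinal {pc['start_ordinal']} ({pc['members'][0]}..{pc['members'][-1]})"
    )
# The planted runs are what the cluster scan must find; the planted
# regulon is what the enrichment stage must flag. Files for the CLI were
# written under scratch/example_study/.
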