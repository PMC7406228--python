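"""Map motif matches to regulons and test them for enrichment.

TomTom matches (q <= 0.5) name candidate transcription factors; each
factor's regulon is then tested for over-representation of DE genes by
Fisher's exact test, with Benjamini-Hochberg correction across the batch
and a significance call at BH <= 0.05.
"""

import textwrap
from pathlib import Path

from declust import SimulationConfig, ThresholdConfig, generate_study
from declust.classify import classify_table
from declust.enrichment import compare_regulons, enrich_gene_sets, results_frame
from declust.io import read_tomtom
from declust.promoters import candidate_regulators

sim = SimulationConfig(seed=11, n_genes=300, gene_length=90, intergenic_gap=10,
                       planted_regulons=((0, 0.7), (3, 0.6)))
_, annotations, _, _, regulons, _, expression, truth = generate_study(sim)
cfg = ThresholdConfig()
statuses, _ = classify_table(expression, cfg)

# a TomTom output as the motif-comparison step would emit it
tomtom = Path("scratch/tomtom_example.tsv")
tomtom.parent.mkdir(exist_ok=True)
tomtom.write_text(textwrap.dedent("""\
    Query_ID\tTarget_ID\tOptimal_offset\tp-value\tE-value\tq-value
    MEME-1\tReg01\t0\t1e-5\t0.001\t0.02
    MEME-2\tReg04\t2\t1e-3\t0.04\t0.45
    MEME-3\tReg09\t1\t1e-2\t0.30\t0.80
"""))
matches = read_tomtom(tomtom, cfg.tomtom_q_max)
candidates, unmapped = candidate_regulators(matches, regulons)
print(f"TomTom matches kept at q <= {cfg.tomtom_q_max}: "
      f"{[s.name for s in candidates]} (dropped above threshold: Reg09)")

results = enrich_gene_sets(candidates, statuses, set(statuses), cfg)
print(results_frame(results).to_string(index=False))
print(f"planted enriched regulons were: {truth.planted_regulon_names}")

# overlap between two regulons, as when comparing a database regulon
# against a ChIP-seq one for the same factor
rep = compare_regulons(regulons[0], regulons[3], statuses)
print(f"{rep.set_a_name} vs {rep.set_b_name}: {rep.n_common_members} shared "
      f"genes; dysregulated fractions "
      f"{rep.fraction_dysregulated_a:.0%} / {rep.fraction_dysregulated_b:.0%}")
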