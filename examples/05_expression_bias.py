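"""Quantify homoeolog expression bias across a simulated tissue atlas.

Each homoeolog pair is tested per tissue with an NB Wald test on
median-of-ratios normalized counts; HEB > 0 means bias toward the A
subgenome.  The atlas is generated with a slight B-ward bias (56% of
biased pairs) and 86.9% cross-tissue consistency, which the analysis
should recover.
"""

from polysub import expression as ex
from polysub import simulate as sim

cfg = sim.SimConfig(seed=51, n_chromosome_pairs=2, genes_per_chromosome=1000,
                    codons_per_gene=100, t_divergence=0, t_merger=0,
                    fractionation_rate_A=0, fractionation_rate_B=0,
                    tandem_rate=0, inversion_count=0, intergenic_length=10)
genome = sim.simulate_progenitors(cfg)
sim.simulate_atlas(cfg, genome)

records = ex.heb_table(genome.atlas_counts,
                       genome.atlas_pair_truth[["pair_id", "gene_A", "gene_B"]],
                       genome.atlas_samples, alpha=0.05)
summary = ex.dominance_consistency(records)

n_pairs = genome.atlas_pair_truth.shape[0]
print(f"{n_pairs} homoeolog pairs x {cfg.atlas.n_tissues} tissues")
print(f"significant comparisons: {summary.extras['n_significant_comparisons']}")
print(f"B-ward share among significant: "
      f"{100 * summary.b_share_significant:.1f}% "
      f"(generator parameter {100 * cfg.atlas.prob_bias_toward_B:.0f}%)")
print(f"consistent dominance across tissues: "
      f"{100 * summary.consistent_share:.1f}% "
      f"(generator parameter {100 * cfg.atlas.frac_consistent_across_tissues:.1f}%)")
print(f"pairs: {summary.n_consistent} consistent, {summary.n_reversing} "
      f"reversing, {summary.n_never_biased} never biased")
# The B-ward share tracks the generator setting closely.  The recovered
# consistency share sits a few points above the generator parameter: a
# truly reversing pair whose flipped tissue never reaches significance is
# indistinguishable from a consistent one, so detection misses inflate
# consistency slightly.
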