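"""Generate a small synthetic allotetraploid bundle and look at its truth.

The generator evolves one diploid ancestor along two lineages for 5 Myr,
merges them 1.1 Mya into A/B subgenomes, and emits genes, TEs, satellite
arrays and an expression atlas with complete ground truth.
"""

from polysub import simulate as sim

cfg = sim.SimConfig(seed=11, n_chromosome_pairs=4, genes_per_chromosome=25,
                    codons_per_gene=150, satellite_copy_range=(50, 120))
genome = sim.simulate_all(cfg)
paths = sim.write_outputs(genome, "example_out/simulated")

genes = genome.genes
print(f"chromosomes: {len(genome.chrom_table)} "
      f"({cfg.n_chromosome_pairs} homoeologous pairs)")
print(f"genes placed: {(genes.status != 'lost').sum()} "
      f"(lost: {(genes.status == 'lost').sum()}, "
      f"pseudogenes: {(genes.status == 'pseudogene').sum()}, "
      f"tandem copies: {(genes.status == 'tandem_copy').sum()})")
print(f"surviving homoeolog pairs: {len(genome.homoeolog_truth_pairs())}")
print(f"LTR elements: {len(genome.ltr_elements)} in "
      f"{genome.ltr_elements.family.nunique()} families")
print(f"satellite arrays: {len(genome.satellite_arrays)} "
      f"({genome.satellite_arrays.copy_number.min()}-"
      f"{genome.satellite_arrays.copy_number.max()} copies of "
      f"{cfg.satellite_monomer_length} bp monomers)")
print(f"wrote {len(paths)} files to example_out/simulated/")
# The counts above recount the emitted truth tables: every downstream stage
# can be scored against them.
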