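"""Population-genetic summary table of the identified individuals.

Per locus: allele count A, individuals typed N, observed/expected
heterozygosity, polymorphic information content, probabilities of identity
(unrelated and sibling), the Chakraborty null-allele estimate, and a
Monte-Carlo exact Hardy-Weinberg test.  The across-loci row multiplies the
per-locus identity probabilities: it is the probability that two random
(unrelated / sibling) individuals share the whole multilocus genotype, the
quantity that decides whether the marker panel can separate individuals.
"""

from nigcmr import genotyping, identity, popgen
from nigcmr.simulate import (
    SimulationConfig,
    corrupt_to_replicates,
    simulate_population,
)

# misidentification off so that every identified genotype is a real animal
# (ghost genotypes would otherwise inflate the allele counts)
cfg = SimulationConfig(seed=42, alpha=1.0, n_females=40, n_males=50)
truth = simulate_population(cfg)
replicates, samples = corrupt_to_replicates(truth)
patterns = samples[["sample_id"] + cfg.pattern_loci]
cons = genotyping.consensus_table(replicates, loci=cfg.loci, patterns=patterns)
individuals = identity.cluster_individuals(cons, cfg.loci, cfg.pattern_loci)
table = identity.individuals_table(individuals, cfg.loci)
print(f"{int(cons['accepted'].sum())} accepted samples -> {len(table)} individuals\n")

summary = popgen.locus_table(table, cfg.loci, hwe=True, seed=1)
print(summary.round(4).to_string(index=False))

across = summary.iloc[-1]
print()
print(f"P_ID(across)    = {across['P_ID']:.2g}  "
      "(two random unrelated individuals sharing one genotype)")
print(f"P_IDsib(across) = {across['P_IDsib']:.2g}  "
      "(same, for full siblings - the conservative criterion)")
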