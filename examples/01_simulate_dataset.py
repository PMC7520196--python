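"""Simulate a noninvasive monitoring dataset and inspect its ground truth.

Generates a two-sex population followed over ten sessions (spring/fall), runs
the capture and misidentification process forward, and expands every capture
into a three-replicate microsatellite genotype table with realistic error
processes (allelic dropout, false alleles, missing replicates, sex-marker
dropout).
"""

from nigcmr.simulate import (
    SimulationConfig,
    corrupt_to_replicates,
    simulate_population,
)

cfg = SimulationConfig(seed=42)
truth = simulate_population(cfg)
replicates, samples = corrupt_to_replicates(truth)

print(f"individuals ever alive : {truth.n_individuals}")
print(f"capture events         : {len(truth.capture_events)}")
print(f"ghost records          : {len(truth.ghost_records)}")
print(f"samples                : {samples.shape[0]}")
print(f"replicate-table rows   : {replicates.shape[0]}")
print()
print("first replicate rows (one sample, one locus, three PCR replicates):")
print(replicates.head(3).to_string(index=False))

# Each capture event became one sample; a ghost record is a capture whose
# genotyping error fabricated a unique (never recurring) genotype.  The ghost
# share should be close to 1 - alpha for the season/sex mix.
print()
print(f"ghost share of samples : {samples['is_ghost'].mean():.3f}")
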