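"""Detect and correct a planted reciprocal translocation.

A tail-tail exchange between two chromosomes is planted in the simulation;
junction-spanning contacts of the derivative chromosomes appear as dense
opposite corner blocks in the reference-frame inter-chromosomal matrix.
"""

import contactscape as cs
from contactscape.matrix import bin_contacts

spec = cs.TranslocationSpec("chrA", 3_210_000, "chrB", 2_140_000)
params = cs.SimulationParams(chrom_lengths={"chrA": 8_000_000, "chrB": 6_000_000},
                             n_pairs=40_000, translocation=spec, seed=4)
sg = cs.simulate_genome(params)
records = cs.simulate_pairs(sg, params)
contacts, _ = cs.filter_pair_stream(records, cs.FilterPolicy(), sg.genome)

model = cs.detect_translocation(contacts, sg.genome, "chrA", "chrB")
print(f"planted breakpoints:  chrA:{spec.breakpoint_a}  chrB:{spec.breakpoint_b}")
print(f"detected breakpoints: {model.chrom_a}:{model.breakpoint_a}  "
      f"{model.chrom_b}:{model.breakpoint_b}  "
      f"(enrichment score {model.score:.1f}, resolution {model.resolution} bp)")
print("-> the multi-resolution scan (1 Mb -> 100 kb -> 10 kb) localizes both "
      "breakpoints to a 10 kb bin")

ga = sg.genome.grid("chrA", 1_000_000)
gb = sg.genome.grid("chrB", 1_000_000)
inter = bin_contacts(contacts, ga, gb)
part = cs.partition_regions(model, ga, gb)
corrected = cs.reconstruct_corrected_matrix(inter, part)
print(f"\njunction-region mean before correction: {inter.values[part.C].mean():.1f}")
print(f"junction-region mean after correction:  {corrected.values[part.C].mean():.1f}")
print(f"background region mean (halved):        {corrected.values[part.A].mean():.1f}")
print("-> the corrected matrix estimates the true inter-chromosomal contacts "
      "of the derivative chromosomes")
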