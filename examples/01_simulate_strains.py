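"""Generate the two-strain synthetic dataset and inspect its truth table.

Builds an inducer strain ("160") carrying a recent burst of 20
near-identical copies of a TIR transposon plus shared ancient degraded
relics, and a non-inducer strain ("9") with the relics only, then
simulates 100-bp single-end reads from both genomes.
"""

from te_strain_scan import presets

ds = presets.strain_contrast_dataset(seed=1)

for strain, genome in sorted(ds.genomes.items()):
    active = sum(1 for i in genome.insertions if i.is_active_clade)
    degraded = len(genome.insertions) - active
    reads = ds.readsets[strain]
    print(f"strain {strain}: genome {len(genome.sequence):,} bp, "
          f"{active} active + {degraded} degraded insertions, "
          f"{len(reads.reads):,} reads "
          f"({ds.denominators[strain]:,} wholly from background)")

# The active/degraded asymmetry between strains is the planted signal the
# enrichment screen (example 02) is expected to recover.
poly = ds.families["POLY"]
print(f"\nPOLY consensus: {len(poly.consensus)} bp, "
      f"TIR {poly.spec.tir_length} bp, "
      f"active clade divergence {poly.spec.active_divergence:.0%}")
for copy in poly.degraded[:3]:
    print(f"  degraded relic {copy.copy_id}: {len(copy.sequence)} bp, "
          f"{copy.divergence:.0%} diverged")
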