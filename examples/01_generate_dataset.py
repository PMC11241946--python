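"""Generate a small synthetic dataset and write it as plain-text files.

The generator emulates a two-ecotype chromatin study: gene models, per-mark
peak sets, expression/dN/dS tables, two-population genotypes, fragment
samples and ecotype coverage tracks, plus truth tables for every planted
effect.  Everything downstream in examples 02-06 can be driven either from
these files or from the in-memory objects.
"""

from regmark import SimulationConfig, generate

cfg = SimulationConfig(seed=1)
ds = generate(cfg)
ds.write("example_data")

print(f"genome: {cfg.n_chroms} chromosomes x {cfg.chrom_len:,} bp, "
      f"{len(ds.genes)} genes")
for mark, peaks in ds.peaks.items():
    print(f"  {mark:9s} {len(peaks):4d} peaks")
print(f"genotypes: {ds.genotypes.n_sites:,} SNPs, "
      f"{len(ds.genotypes.samples)} samples in 2 populations")
print(f"screen truth: {len(ds.screen.truth['marine_specific'])} planted "
      f"marine-specific genes, of which "
      f"{len(ds.screen.truth['deletions'])} carry a stream deletion")
print("files written to example_data/ (GFF3, BED, TSV, VCF, bedGraph, JSON)")
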