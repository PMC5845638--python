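"""Simulate an eight-founder MAGIC RIL population with ground truth.

Builds a tomato-scale genetic map, draws founder haplotypes, pushes them
through the funnel (4 two-way F1s -> 2 four-way -> 1 eight-way hybrid)
plus three selfing generations, and inspects the resulting mosaics.
"""

import numpy as np

import magicqtl as mq

gmap = mq.default_map(n_markers=240, n_chromosomes=4, total_cM=720, seed=1)
founders, variants, genes = mq.simulate_founders(gmap, diversity=1.0, seed=2)
genotypes, mosaic = mq.simulate_magic_lines(founders, gmap, n_lines=200, seed=3)

shares = mosaic.genome_shares()
bkpts = np.mean([mosaic.n_breakpoints(l, c)
                 for l in mosaic.lines for c in mosaic.chromosomes])

print(f"map: {gmap.n_markers} markers, {len(gmap.chromosomes)} chromosomes, "
      f"{gmap.total_length_cM:.0f} cM")
print(f"lines: {len(mosaic.lines)} homozygous RILs")
print("founder genome shares (expected 0.125 each):")
for name, s in zip(founders.founders, shares):
    print(f"  {name:10s} {s:.3f}")
print(f"mean ancestral breakpoints per chromosome: {bkpts:.2f}")
print(f"annotation: {len(genes.table)} genes, {len(variants.table)} polymorphisms")
# Each line's genome is a mosaic of the eight founders; shares near 1/8 and
# a few breakpoints per 180-cM chromosome are what the funnel + SSD design
# predicts.
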