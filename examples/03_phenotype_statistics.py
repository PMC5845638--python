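"""Phenotype statistics: ANOVA partition, heritability, plasticity, MV.

Simulates a trait with a genotype-by-treatment interaction, then runs the
replicate-level statistics a two-treatment trial would use.
"""

import magicqtl as mq

gmap = mq.default_map(n_markers=120, n_chromosomes=3, total_cM=300, seed=1)
founders, _, _ = mq.simulate_founders(gmap, seed=2)
_, mosaic = mq.simulate_magic_lines(founders, gmap, n_lines=150, seed=3)

qtl = mq.QtlSpec(chrom="chr02", position_cM=40.0,
                 effects=(2.0, 2.0, -0.5, -0.5, -0.5, -0.5, -1.0, -1.0),
                 treatment_scale={"stress": 0.3})   # weaker effect under stress
arch = mq.TraitArchitecture(trait="FW", qtls=(qtl,), mu=30.0,
                            treatment_offsets={"stress": -5.0},
                            target_h2=0.7, n_replicates=2)
df = mq.simulate_phenotypes(mosaic, gmap, arch,
                            treatments=["control", "stress"], seed=4)
table = mq.PhenotypeTable(data=df)

aov = mq.two_way_anova(table, "FW", "Exp1")
print("two-way ANOVA, % of total SSq:")
print(aov.terms["ss_pct"].round(2).to_string())

for tr in ("control", "stress"):
    h = mq.heritability(table, "FW", "Exp1", tr)
    print(f"h2 ({tr}): {h.h2:.3f}  (s2G={h.sigma2_g:.2f}, s2E={h.sigma2_e:.2f}, r={h.r:.0f})")

pp = mq.plasticity(table, "FW", "Exp1", "control", "stress")
mv = mq.mean_relative_variation(table, "FW", ("Exp1", "control"), ("Exp1", "stress"))
print(f"mean plasticity PP: {pp['pp'].mean():.3f}")
print(f"mean relative variation: {mv:+.2f}%")
# The GxT SSq share reflects the treatment-specific QTL scaling; MV is the
# population-level percent change of the trait mean under stress.
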