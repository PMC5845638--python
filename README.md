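# magicqtl

QTL mapping in multi-parent (MAGIC) populations under contrasting
treatments: founder-origin inference, phenotype and plasticity statistics,
multi-founder interval mapping with QTL classification, and
founder-effect-guided candidate-gene filtering — together with a synthetic
MAGIC-population generator so every stage can be validated against a known
ground truth.

## Who this is for

Quantitative geneticists and breeders working with multi-parent RIL panels
(the motivating case is an eight-founder cultivated-tomato MAGIC population
of ~250 lines genotyped at 1,345 SNPs across 12 chromosomes, phenotyped
under control vs. water-deficit and control vs. salinity treatments) who
need a tested, scriptable implementation of the full analysis chain, or a
simulation test bed for methods work on such panels.

## The models at the core

**Founder-origin HMM.** Each line's genome is a homozygous mosaic of the
eight founders. Per chromosome, the founder origin is a hidden Markov chain
over 8 states evaluated at every marker plus a 2-cM lattice. Transitions
over a gap of *d* Morgans follow the Haldane model with ancestry switch
rate ρ (the effective number of recombining meioses, default from the
funnel + selfing design): with probability 1 − e^(−ρd) the chain jumps to a
uniformly random founder. Emissions at markers are 1 − ε on an allele match
and ε otherwise. Forward–backward yields posterior founder probabilities;
positions are assigned to the argmax founder only when its posterior
exceeds 0.5, otherwise left unassigned.

**Phenotype statistics.** Two-way ANOVA *Y = μ + G + T + G×T + ε* with
sequential (Type I) sums of squares and per-term share of total SSq;
broad-sense heritability h² = σ²G/(σ²G + σ²E/r) from the one-way genotype
ANOVA with r the average replicate count; per-genotype plasticity
PP = (Stress − Control)/Control; population-level mean relative variation
MV (%); Pearson correlations within and between treatments.

**Interval mapping.** At each evaluation position the per-line trait value
is regressed on the eight founder probabilities (drop-one parameterization;
effects reported mean-centered across all eight founders), with
LOD = (n/2)·log₁₀(1/(1 − R²)). Peaks at LOD ≥ 3 become QTL with 1-LOD
support intervals, projected to bp through the genetic map. Same-trait QTL
with overlapping intervals across contexts merge and are classified
constitutive / treatment-specific / interactive (plasticity-mapped).

**Candidate filtering.** Within a QTL's physical interval, a polymorphism
is kept iff the founders in the high-effect group share one allele, the
founders in the low-effect group share the other, and the two differ
(pattern language: `Cerv # all`, `(Cerv = Stup) # (LA14 = LA0)`); candidate
genes are those retaining at least one passing polymorphism.

## Worked example

```python
import magicqtl as mq

gmap = mq.default_map(n_markers=450, n_chromosomes=4, total_cM=720, seed=1)
founders, _, _ = mq.simulate_founders(gmap, diversity=1.0, seed=2)
genotypes, mosaic = mq.simulate_magic_lines(founders, gmap, n_lines=100, seed=3)
observed = mq.add_genotyping_error(genotypes, 0.005, seed=4)

grid = mq.infer_founder_probabilities(observed, founders, gmap,
                                      error_rate=0.005, grid_step_cM=2.0)
assignment = mq.assign_founder(grid, threshold=0.5)
s = mq.assignment_summary(grid, assignment, truth=mosaic)
print(f"evaluated marker positions : {s['n_positions']}")
print(f"assigned fraction          : {s['assigned_fraction']:.3f}")
print(f"unassigned fraction        : {s['unassigned_fraction']:.3f}")
print(f"accuracy (vs truth)        : {s['accuracy']:.3f}")
print(f"accuracy among assigned    : {s['accuracy_assigned']:.3f}")
```

prints (seed-exact):

```
evaluated marker positions : 45000
assigned fraction          : 0.983
unassigned fraction        : 0.017
accuracy (vs truth)        : 0.941
accuracy among assigned    : 0.957
```

i.e. with 0.5% genotyping error, 94.1% of (line, marker) positions are
assigned to the true founder and only 1.7% are left unassigned at the 0.5
posterior threshold. The `examples/` directory walks through every
capability the same way: simulation (`01`), founder inference (`02`),
phenotype statistics (`03`), scanning and classification (`04`), candidate
filtering (`05`) and the full configured pipeline (`06`).

A thin CLI mirrors the stages:

```bash
magicqtl simulate --config examples/demo_config.yaml --out run/
magicqtl infer-founders --map run/map.tsv --genotypes run/genotypes.vcf --out run/
magicqtl run --config examples/demo_config.yaml --out run/
```

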