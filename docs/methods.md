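# Methods

This note documents the models, the simulator's assumptions, the numerical
choices, and the known limitations of `magicqtl`.

## Population model and simulator

The package targets eight-founder MAGIC RIL panels. The simulator derives
each line through the canonical funnel — four two-way F1s, two four-way
hybrids, one eight-way hybrid — followed by single-seed descent. Defaults:

* **Map**: 1,345 markers on 12 chromosomes totalling 2,156 cM (the scale of
  the tomato MAGIC panel the package is modelled on); markers placed
  uniformly at random, physical positions follow genetic positions at
  ~420 kb/cM (tomato genome ÷ map length) with mild monotone jitter, so
  cM↔bp projection is exercised on a non-linear bridge.
* **Recombination**: Haldane model — crossovers are a Poisson process on
  the genetic scale with no interference. This is the simplest model
  consistent with standard MAGIC analyses; no interference parameter is
  exposed.
* **Funnel order**: randomized per line (the real population pools many
  funnels); a fixed-funnel debug mode exists.
* **Selfing depth**: 3 generations by default (configurable; real MAGIC
  panels undergo "several" recombination generations and rarely publish
  the exact depth). After the last selfing, the line is one random gamete
  doubled, so lines are exactly homozygous — residual heterozygosity is
  not modelled.
* **Founder alleles**: independent Bernoulli(f) per founder per marker with
  f = diversity/2. `diversity = 0` gives monomorphic founders;
  `diversity = 1` gives the fair-coin case used by the assignment
  benchmark. The expected founder-pair difference rate is 2f(1 − f).
* **Annotation track**: non-overlapping gene intervals per chromosome with
  polymorphisms placed in gene regions ± flank; effect classes use the
  standard HIGH/MODERATE/LOW/MODIFIER vocabulary, with intergenic
  polymorphisms always MODIFIER and associated to their gene region.

Phenotypes follow the two-way decomposition Y = μ + G + T + G×T + ε: a
line's genetic value per treatment is μ + treatment offset + Σ over QTL of
(treatment scale × effect of the founder carried at the QTL). Residual
noise is i.i.d. normal per replicate; when a target h² is given, σ²E is
calibrated per treatment as r·σ²G·(1 − h²)/h² from the realized genetic
variance, so the expected estimated heritability matches the target.
Traits flagged `log` are simulated on the log scale and exponentiated
(guaranteeing positivity, as for fruit weight or fruit number).

What the generator deliberately does **not** emulate: epistasis, dominance,
cytoplasmic effects, selection during line derivation, genotype-call
heterozygosity, linkage disequilibrium among founder alleles, spatial field
structure, or non-normal residuals. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every artefact of real field data.

## Founder-origin inference

Per chromosome an order-1 HMM over the eight founders, evaluated at all
marker positions plus an even 2-cM lattice (duplicates removed by exact cM
equality). Transitions over distance d Morgans: jump with probability
1 − e^(−ρd) to a uniform founder. ρ ("effective meioses per Morgan")
defaults to `expected_meioses(n_selfing)` = 3 + Σ_{t=1..g} 2^{−(t−1)}:
three funnel meioses plus selfing contributions discounted by the halving
of founder-origin heterozygosity. This slightly overstates the realized
junction density (junctions are also lost through lineage averaging;
empirically ~3.8/Morgan at g = 3 versus the formula's 4.75), but posterior
accuracy is insensitive to this level of misspecification and ρ is
configurable everywhere.

Emissions: match 1 − ε, mismatch ε (default ε = 0.01; set it to the
genotyping error rate when known); missing founder or line calls emit
uniformly; lattice positions carry no emission and receive posteriors
through the chain. Heterozygous line calls are recoded missing on VCF
read — lines are assumed inbred. Posteriors come from scaled
forward–backward; an exhaustive path-enumeration oracle checks them to
1e-10 on small instances.

Assignment uses strictly-greater-than 0.5 ("above" the majority
threshold); exact ties are unassigned. The summary reports accuracy
(correct over all evaluated positions, unassigned counting as errors) and
accuracy-among-assigned separately, because published "accurately
predicted" percentages do not always say which denominator they use.

## Phenotype statistics

* Two-way ANOVA uses sequential (Type I) sums of squares in the fixed
  order G, T, G×T — the default of the R environment such analyses are
  usually run in; statsmodels' `anova_lm` does the decomposition. An
  all-constant response returns zero SSq with F and p reported NaN.
* Heritability: σ²E = residual mean square, σ²G = (MS_G − σ²E)/r truncated
  at 0; r is the arithmetic mean replicate count (harmonic available via
  `r_mode`). With a single replicate everywhere the components are
  confounded; all variance is then reported as genetic.
* Plasticity PP is computed on untransformed replicate means. For
  log-flagged traits, the value mapped as the plasticity trait is
  log(stress mean) − log(control mean): a relative change can be negative,
  so "log-transforming PP" cannot apply literally, and the log-mean
  difference is the monotone equivalent that stays defined. Zero control
  means yield NaN with a counted warning.
* Mean relative variation is computed on raw trait means over the line set
  common to both conditions by default (`paired=False` uses all lines per
  condition — the two options bracket small reporting ambiguities in
  published tables).

## QTL mapping

The founder-probability design at a position sums to one, so the fit drops
the eighth founder column (absorbed in the intercept) and re-expresses
effects as all-eight mean-centered values for reporting. LOD is the
regression identity (n/2)·log₁₀(1/(1 − R²)); R² is clipped to [0, 1).

Peak calling: local maxima at LOD ≥ 3 (the conventional fixed threshold;
permutation thresholds are out of scope). The confidence interval is the
1-LOD *support interval* — walk outward until the profile drops one LOD
unit below the *peak*. The alternative reading "one below the threshold"
coincides for peaks near LOD 4; the support-interval reading is the field
convention and is used throughout. Same-chromosome peaks with overlapping
support intervals merge, keeping the higher peak. PVE is R² × 100 at the
peak (single-position, not drop-term); `joint_pve` gives the multi-QTL R²
of all peak blocks fitted jointly, via a rank-revealing solve so duplicate
blocks are harmless.

Classification merges same-trait, same-chromosome records whose genetic
CIs overlap (connected components of the overlap graph; a union-find
equivalent is oracle-tested). Labels: constitutive (≥ 2 treatments),
treatment-specific, interactive-specific (plasticity contexts only),
interactive-shared (plasticity + mean-trait members). Venn-style counts
per context combination are emitted for reporting.

## Candidate filtering

Intervals are 0-based half-open bp internally (BED-native; GFF3 converted
on read). Genes count on any overlap with the CI, polymorphisms on
containment. A gene is a candidate iff it retains ≥ 1 passing
polymorphism — gene-level and polymorphism-level filtering are one joint
operation, since retained candidates are defined by their polymorphisms.
Missing founder calls in a grouped founder fail the polymorphism by
default (`permissive_missing=True` ignores them while at least one call
remains per group); both modes exist because published filters are
ambiguous about intermediate or missing parents. `suggest_grouping` is
advisory only (largest-gap split of mean-centered effects, founders within
a margin of 25% of the gap left ungrouped): groupings in practice are
chosen by inspecting the founder-effect profile, and the API keeps that
human step explicit.

## Determinism and problem sizes

All randomness flows from one integer seed through numpy `SeedSequence`
spawning; no global state. Two pipeline runs from the same configuration
are checksum-identical (text outputs by byte hash; the probability-grid
container by the digest of its arrays, which is invariant to archive
metadata).

Test-bed problem sizes are chosen to exercise each property at the scale
that makes it informative while keeping the suite quick: the assignment
benchmark runs at full study scale (1,345 markers / 250 lines / 5 seeds);
heritability recovery uses 200 phenotype draws over 10 independent genome
populations of 250 lines on a 2-chromosome map; QTL recovery uses 100
replicates of 250 lines on a 3-chromosome, 300-cM map with a planted
20%-PVE locus; posterior exactness uses 1,000 random ≤ 4-marker chains
against full path enumeration.

## Known limitations

* The HMM treats lines independently; no joint pedigree likelihood, no
  genotype imputation, no sex chromosomes or ploidy handling.
* Interval mapping is single-QTL per position: no composite interval
  mapping, no multi-QTL model search, no epistasis scan.
* No mixed-model REML, spatial correction, or outlier rejection beyond
  missing-value handling.
* The candidate filter reasons over biallelic founder patterns only and
  does not predict variant effects; effect classes are taken from the
  annotation as given.
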