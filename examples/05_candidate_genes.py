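"""Candidate-gene filtering by founder allelic-effect grouping.

Builds a QTL whose founder effects single out one parent, parses the
corresponding filter pattern, and reduces the genes/polymorphisms inside
the QTL's physical confidence interval.
"""

import magicqtl as mq

gmap = mq.default_map(n_markers=120, n_chromosomes=3, total_cM=300, seed=1)
founders, variants, genes = mq.simulate_founders(
    gmap, seed=2, n_genes_per_chrom=40, n_variants_per_gene_region=12
)

# plant a handful of Cervil-private polymorphisms: the causal pattern the
# founder-effect filter is meant to recover
vt = variants.table
private = vt.index[vt["chrom"] == "chr01"][::60][:6]
for f in founders.founders:
    vt.loc[private, f] = 0
vt.loc[private, "Cervil"] = 1

# A QTL where Cervil diverges strongly from the other seven parents
record = mq.QtlRecord(
    trait="Firm", context="Exp2:salt", chrom="chr01",
    peak_cM=50.0, peak_lod=8.2, ci_low_cM=45.0, ci_high_cM=55.0,
    ci_low_bp=int(gmap.project_bp("chr01", 45.0)),
    ci_high_bp=int(gmap.project_bp("chr01", 55.0)),
    effects=(4.3, -0.65, -0.28, -2.17, -0.82, -0.44, -0.33, 0.38),
    pve=28.0, n=250,
)

suggested, note = mq.suggest_grouping(record.effects_centered, founders.founders)
print(f"suggested grouping: {suggested.pattern()}")
print(f"  ({note})")

grouping = mq.parse_grouping("Cerv # all", founders.founders)
summary, listing = mq.cg_report(record, grouping, variants, genes)
print(f"\nQTL {summary['trait']} on {summary['chrom']}, "
      f"CI {summary['ci_size_bp'] / 1e6:.2f} Mb")
print(f"genes in CI          : {summary['n_genes']}")
print(f"polymorphisms in CI  : {summary['n_polymorphisms']}")
print(f"filter               : {summary['filter']}")
print(f"candidate genes      : {summary['n_candidate_genes']}")
print(f"candidate polymorphs : {summary['n_candidate_polymorphisms']}")
if not listing.empty:
    print("\nfirst candidates:")
    print(listing.head(5).to_string(index=False))
# Only polymorphisms where Cervil carries one allele and the other seven
# parents uniformly carry the other survive; genes keep their candidacy
# through at least one surviving polymorphism.
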