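import numpy as np
import pandas as pd
import pytest

import magicqtl as mq


@pytest.fixture(scope="session")
def small_map() -> mq.GeneticMap:
    """Three 100-cM chromosomes, 40 markers each."""
    return mq.default_map(n_markers=120, n_chromosomes=3, total_cM=300.0, seed=7)


@pytest.fixture(scope="session")
def small_population(small_map):
    """Founders + 60 MAGIC lines on the small map, fully distinct haplotypes."""
    founders, variants, genes = mq.simulate_founders(
        small_map, diversity=1.0, n_genes_per_chrom=12,
        n_variants_per_gene_region=6, seed=11,
    )
    genotypes, mosaic = mq.simulate_magic_lines(founders, small_map, n_lines=60, seed=13)
    return {
        "map": small_map,
        "founders": founders,
        "variants": variants,
        "genes": genes,
        "genotypes": genotypes,
        "mosaic": mosaic,
    }


@pytest.fixture(scope="session")
def small_grid(small_population):
    return mq.infer_founder_probabilities(
        small_population["genotypes"],
        small_population["founders"],
        small_population["map"],
        error_rate=0.01,
    )


def balanced_table(values: dict, trait="y", experiment="Exp1") -> mq.PhenotypeTable:
    """Build a PhenotypeTable from {(line, treatment): [replicate values]}."""
    rows = []
    for (line, tr), vals in values.items():
        for i, v in enumerate(vals):
            rows.append((line, experiment, tr, i + 1, trait, float(v)))
    return mq.PhenotypeTable(
        data=pd.DataFrame(
            rows, columns=["line", "experiment", "treatment", "replicate", "trait", "value"]
        )
    )


def random_pheno_table(rng, n_lines=10, n_reps=2, trait="y", experiment="Exp1"):
    values = {}
    for i in range(n_lines):
        for tr in ("control", "stress"):
            values[(f"L{i:03d}", tr)] = rng.normal(10, 2, n_reps)
    return balanced_table(values, trait=trait, experiment=experiment)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
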