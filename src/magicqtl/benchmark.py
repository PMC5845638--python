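"""Standard synthetic benchmark for founder-origin assignment.

The benchmark reproduces the geometry of the tomato MAGIC study: 1,345
biallelic markers on 12 chromosomes totalling ~2,156 cM, eight founders
with independent alleles at frequency 0.5, 250 RILs derived through the
funnel plus three selfing generations, and 0.5% genotyping error.  HMM
inference with the 0.5 posterior threshold is then scored against the
simulated truth at marker positions.
"""

from __future__ import annotations

import numpy as np

from . import infer as inf
from . import simulate as sim

__all__ = ["founder_assignment_benchmark", "run_benchmark_seeds"]


def founder_assignment_benchmark(
    seed: int,
    n_lines: int = 250,
    n_markers: int = 1345,
    n_chromosomes: int = 12,
    total_cM: float = 2156.0,
    genotyping_error: float = 0.005,
    n_selfing: int = 3,
    threshold: float = 0.5,
) -> dict:
    """One benchmark replicate; returns the assignment summary vs truth."""
    ss = np.random.SeedSequence(seed)
    s_map, s_founders, s_lines, s_err = (int(s) % 2**31 for s in ss.generate_state(4))
    gmap = sim.default_map(
        n_markers=n_markers, n_chromosomes=n_chromosomes, total_cM=total_cM, seed=s_map
    )
    founders, _, _ = sim.simulate_founders(
        gmap, diversity=1.0, n_genes_per_chrom=2, n_variants_per_gene_region=1,
        seed=s_founders,
    )
    genotypes, mosaic = sim.simulate_magic_lines(
        founders, gmap, n_lines=n_lines, n_selfing_generations=n_selfing, seed=s_lines
    )
    observed = sim.add_genotyping_error(genotypes, genotyping_error, seed=s_err)
    grid = inf.infer_founder_probabilities(
        observed, founders, gmap,
        error_rate=genotyping_error,
        n_meioses=sim.expected_meioses(n_selfing),
    )
    assignment = inf.assign_founder(grid, threshold=threshold)
    return inf.assignment_summary(grid, assignment, truth=mosaic, markers_only=True)


def run_benchmark_seeds(seeds) -> dict:
    """Average accuracy and unassigned fraction (percent) over seeds."""
    acc, unas, n = [], [], 0
    for s in seeds:
        summary = founder_assignment_benchmark(int(s))
        acc.append(summary["accuracy"])
        unas.append(summary["unassigned_fraction"])
        n += summary["n_positions"]
    return {
        "accuracy_pct": float(np.mean(acc)) * 100.0,
        "unassigned_pct": float(np.mean(unas)) * 100.0,
        "per_seed_accuracy_pct": [a * 100.0 for a in acc],
        "per_seed_unassigned_pct": [u * 100.0 for u in unas],
        "n_positions": n,
    }
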