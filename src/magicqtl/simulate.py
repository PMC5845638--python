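"""Synthetic MAGIC populations with ground-truth tracks.

Emulates an eight-founder MAGIC RIL population of the kind used in tomato:
a funnel of crosses (four two-way F1s, two four-way hybrids, one eight-way
hybrid) followed by single-seed descent, producing homozygous lines whose
genomes are mosaics of the eight founder genomes.  Everything downstream
(founder-origin inference, phenotype statistics, QTL scans, candidate-gene
filtering) can be validated against the recorded truth.

Recombination uses the Haldane model (crossovers are a Poisson process on
the genetic scale, no interference).  All randomness flows from one integer
seed through numpy Generators; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap, MapError

__all__ = [
    "FOUNDER_NAMES",
    "EFFECT_CLASSES",
    "FounderGenotypes",
    "FounderMosaic",
    "GeneSet",
    "VariantTable",
    "QtlSpec",
    "TraitArchitecture",
    "SimulationError",
    "default_map",
    "simulate_founders",
    "simulate_magic_lines",
    "simulate_phenotypes",
    "add_genotyping_error",
]

# Default founder panel mirrors the cultivated-tomato MAGIC parents: four
# cherry-type (cerasiforme) and four large-fruited lines.
FOUNDER_NAMES = (
    "Cervil",
    "Levovil",
    "Criollo",
    "Stupicke",
    "Plovdiv",
    "LA1420",
    "Ferum",
    "LA0147",
)

EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

MISSING = -1  # allele code for missing genotype


class SimulationError(ValueError):
    """Invalid simulation input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderGenotypes:
    """Allele matrix of the (exactly eight) founders.

    ``alleles`` has shape (8, n_markers), entries in {0, 1} or -1 for
    missing; markers follow the order of the associated :class:`GeneticMap`.
    """

    founders: tuple[str, ...]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        if len(self.founders) != 8:
            raise SimulationError(f"expected exactly 8 founders, got {len(self.founders)}")
        a = np.asarray(self.alleles, dtype=np.int8)
        if a.ndim != 2 or a.shape[0] != 8:
            raise SimulationError("allele matrix must be 8 x n_markers")
        valid = np.isin(a, (MISSING, 0, 1))
        if not valid.all():
            j = int(np.argwhere(~valid)[0, 1])
            raise SimulationError(f"marker column {j} is not biallelic 0/1/missing")
        object.__setattr__(self, "alleles", a)

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]


@dataclass
class FounderMosaic:
    """Ground-truth founder ancestry of each line.

    ``segments[line][chrom]`` is a pair of arrays ``(ends, founders)``:
    segment ``k`` covers the genetic interval ``[ends[k-1], ends[k])``
    (with an implicit 0 start) and descends from founder index
    ``founders[k]``; ``ends[-1]`` equals the chromosome length in cM.
    """

    chromosomes: tuple[str, ...]
    lines: list[str]
    segments: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]

    def founder_at(self, line: str, chrom: str, position_cM) -> np.ndarray:
        """True founder index at genetic position(s) on a chromosome."""
        ends, fnd = self.segments[line][chrom]
        pos = np.atleast_1d(np.asarray(position_cM, dtype=float))
        idx = np.minimum(np.searchsorted(ends, pos, side="right"), len(fnd) - 1)
        return fnd[idx]

    def n_breakpoints(self, line: str, chrom: str) -> int:
        _, fnd = self.segments[line][chrom]
        return int(np.sum(fnd[1:] != fnd[:-1]))

    def genome_shares(self) -> np.ndarray:
        """Fraction of total genetic length inherited from each founder."""
        total = np.zeros(8)
        for line in self.lines:
            for chrom in self.chromosomes:
                ends, fnd = self.segments[line][chrom]
                lengths = np.diff(np.concatenate([[0.0], ends]))
                np.add.at(total, fnd, lengths)
        s = total.sum()
        return total / s if s > 0 else total


@dataclass(frozen=True)
class GeneSet:
    """Gene intervals per chromosome; 0-based half-open bp coordinates."""

    table: pd.DataFrame  # columns: gene, chrom, start, end, annotation

    def __post_init__(self) -> None:
        t = self.table
        if t["gene"].duplicated().any():
            raise SimulationError("duplicate gene ids")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene"].iloc[0]
            raise SimulationError(f"gene {bad!r} has start >= end")


@dataclass(frozen=True)
class VariantTable:
    """Polymorphisms with per-founder alleles, gene association, effect class.

    ``table`` columns: chrom, pos (bp), then one column per founder name
    (alleles 0/1, -1 missing), then gene, effect.
    """

    table: pd.DataFrame
    founders: tuple[str, ...] = FOUNDER_NAMES

    def __post_init__(self) -> None:
        for f in self.founders:
            if f not in self.table.columns:
                raise SimulationError(f"variant table missing founder column {f!r}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise SimulationError(f"variant positions unsorted on {chrom!r}")

    def allele_matrix(self) -> np.ndarray:
        """(n_variants, 8) founder allele matrix."""
        return self.table[list(self.founders)].to_numpy(dtype=np.int8)


@dataclass(frozen=True)
class QtlSpec:
    """A simulated causal locus with per-founder additive effects."""

    chrom: str
    position_cM: float
    effects: tuple[float, ...]  # length 8, one additive effect per founder
    treatment_scale: dict[str, float] = field(default_factory=dict)  # default 1.0

    def __post_init__(self) -> None:
        if len(self.effects) != 8:
            raise SimulationError("QTL effect vector must have length 8")

    def scale(self, treatment: str) -> float:
        return float(self.treatment_scale.get(treatment, 1.0))


@dataclass(frozen=True)
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    The generative model mirrors the two-way ANOVA decomposition
    Y = mu + G + T + GxT + error: founder effects at the QTL produce G,
    per-treatment offsets produce T, and treatment-specific effect scaling
    produces GxT.  Residual noise is either given per treatment
    (``residual_var``) or calibrated so the realized broad-sense
    heritability h2 = s2G / (s2G + s2E / r) matches ``target_h2``.
    """

    trait: str
    qtls: tuple[QtlSpec, ...]
    mu: float = 0.0
    treatment_offsets: dict[str, float] = field(default_factory=dict)
    target_h2: float | None = None
    residual_var: dict[str, float] | float | None = None
    n_replicates: int = 2
    transform: str = "identity"  # identity | log (simulated on the log scale)

    def __post_init__(self) -> None:
        if self.target_h2 is not None and not (0 < self.target_h2 <= 1):
            raise SimulationError("target_h2 must be in (0, 1]")
        if self.target_h2 is None and self.residual_var is None:
            raise SimulationError("give target_h2 or residual_var")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.transform not in ("identity", "log"):
            raise SimulationError(f"unknown transform {self.transform!r}")


# ---------------------------------------------------------------------------
# default map
# ---------------------------------------------------------------------------


def default_map(
    n_markers: int = 1345,
    n_chromosomes: int = 12,
    total_cM: float = 2156.0,
    bp_per_cM: float = 420_000.0,
    seed: int = 0,
) -> GeneticMap:
    """Tomato-scale default map: 1,345 markers on 12 chromosomes, ~2,156 cM.

    Markers are placed uniformly at random along each chromosome (sorted),
    and physical positions follow the genetic positions with mild jitter so
    the cM->bp relation is monotone but not exactly linear.
    """
    rng = np.random.default_rng(seed)
    base, extra = divmod(n_markers, n_chromosomes)
    counts = [base + (1 if i < extra else 0) for i in range(n_chromosomes)]
    length = total_cM / n_chromosomes
    rows = []
    for i, cnt in enumerate(counts):
        chrom = f"chr{i + 1:02d}"
        if cnt < 2:
            raise SimulationError("need >=2 markers per chromosome")
        cm = np.sort(rng.uniform(0.0, length, cnt - 2))
        cm = np.concatenate([[0.0], cm, [length]])  # anchor both ends
        jitter = rng.uniform(0.8, 1.2, cnt)
        bp = np.cumsum(np.diff(np.concatenate([[0.0], cm])) * bp_per_cM * jitter)
        bp = np.maximum(np.round(bp).astype(np.int64), 1)
        bp = np.maximum.accumulate(bp)
        for j in range(cnt):
            rows.append((f"{chrom}_m{j + 1:04d}", chrom, round(float(cm[j]), 4), int(bp[j])))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


# ---------------------------------------------------------------------------
# founders, variants, genes
# ---------------------------------------------------------------------------


def simulate_founders(
    gmap: GeneticMap,
    diversity: float = 1.0,
    n_genes_per_chrom: int = 40,
    n_variants_per_gene_region: int = 10,
    gene_flank_bp: int = 2_000,
    seed: int = 0,
    founders: tuple[str, ...] = FOUNDER_NAMES,
) -> tuple[FounderGenotypes, VariantTable, GeneSet]:
    """Draw founder haplotypes plus a resequencing-style annotation set.

    Marker (and variant) alleles are drawn independently per founder as
    Bernoulli(f) with f = diversity / 2: at ``diversity=0`` every marker is
    monomorphic across founders, at ``diversity=1`` founder alleles are
    independent fair coin flips, the maximally informative case.  The
    expected fraction of markers at which a given founder pair differs is
    2 f (1 - f).

    Gene intervals are non-overlapping within each chromosome; each gene
    region carries ``n_variants_per_gene_region`` polymorphisms placed in
    [start - flank, end + flank), classed MODIFIER when intergenic and
    HIGH/MODERATE/LOW/MODIFIER by severity weights when genic.
    """
    if not (0.0 <= diversity <= 1.0):
        raise SimulationError("diversity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    f = diversity / 2.0
    alleles = (rng.random((8, gmap.n_markers)) < f).astype(np.int8)
    fg = FounderGenotypes(founders=tuple(founders), alleles=alleles)

    gene_rows, var_rows = [], []
    severity = np.array([0.05, 0.15, 0.30, 0.50])  # HIGH..MODIFIER for genic
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        lo, hi = int(sub["bp"].min()), int(sub["bp"].max())
        span = max(hi - lo, n_genes_per_chrom * 10)
        slot = span / n_genes_per_chrom
        for g in range(n_genes_per_chrom):
            s0 = lo + g * slot
            glen = rng.uniform(0.1, 0.6) * slot
            start = int(s0 + rng.uniform(0.0, slot - glen))
            end = int(start + max(glen, 200))
            gene = f"{chrom}_g{g + 1:03d}"
            gene_rows.append((gene, chrom, start, end, f"synthetic annotation {gene}"))
            pos = np.sort(
                rng.integers(
                    max(start - gene_flank_bp, lo),
                    end + gene_flank_bp,
                    n_variants_per_gene_region,
                )
            )
            fa = (rng.random((n_variants_per_gene_region, 8)) < f).astype(np.int8)
            for k in range(n_variants_per_gene_region):
                inside = start <= pos[k] < end
                eff = (
                    EFFECT_CLASSES[rng.choice(4, p=severity)] if inside else "MODIFIER"
                )
                var_rows.append((chrom, int(pos[k]), *fa[k].tolist(), gene, eff))
    genes = GeneSet(
        pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end", "annotation"])
    )
    vt = pd.DataFrame(
        var_rows, columns=["chrom", "pos", *founders, "gene", "effect"]
    ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    variants = VariantTable(table=vt, founders=tuple(founders))
    return fg, variants, genes


# ---------------------------------------------------------------------------
# meiosis and the funnel
# ---------------------------------------------------------------------------

Haplotype = tuple[np.ndarray, np.ndarray]  # (segment end positions cM, founder idx)


def _compress(ends: np.ndarray, fnd: np.ndarray) -> Haplotype:
    """Drop zero-length segments and merge adjacent identical founders."""
    starts = np.concatenate([[0.0], ends[:-1]])
    keep = ends > starts
    ends, fnd = ends[keep], fnd[keep]
    if len(fnd) > 1:
        keep = np.concatenate([fnd[:-1] != fnd[1:], [True]])
        # merging keeps the END of each run, so drop ends where next founder equal
        ends, fnd = ends[keep], fnd[keep]
    return ends, fnd


def _slice_hap(h: Haplotype, a: float, b: float) -> tuple[list, list]:
    """Segments of haplotype ``h`` restricted to [a, b)."""
    ends, fnd = h
    i0 = int(np.searchsorted(ends, a, side="right"))
    j = int(np.searchsorted(ends, b, side="left"))
    j = min(j, len(ends) - 1)
    seg_ends = np.minimum(ends[i0 : j + 1], b).tolist()
    if seg_ends:
        seg_ends[-1] = b
    return seg_ends, fnd[i0 : j + 1].tolist()


def _meiosis(h1: Haplotype, h2: Haplotype, length_cM: float, rng) -> Haplotype:
    """One gamete under the Haldane model (Poisson crossovers, no interference)."""
    n_x = rng.poisson(length_cM / 100.0) if length_cM > 0 else 0
    start = int(rng.integers(2))
    if n_x == 0:
        return (h1, h2)[start]
    cuts = np.sort(rng.uniform(0.0, length_cM, n_x))
    bounds = np.concatenate([[0.0], cuts, [length_cM]])
    haps = (h1, h2)
    ends_out: list = []
    fnd_out: list = []
    cur = start
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a:
            e, fr = _slice_hap(haps[cur], a, b)
            ends_out.extend(e)
            fnd_out.extend(fr)
        cur ^= 1
    return _compress(np.asarray(ends_out, dtype=float), np.asarray(fnd_out, dtype=np.int64))


def _founder_hap(idx: int, length_cM: float) -> Haplotype:
    return np.asarray([length_cM], dtype=float), np.asarray([idx], dtype=np.int64)


def _derive_line_chrom(order: np.ndarray, length_cM: float, n_selfing: int, rng) -> Haplotype:
    """Run one chromosome through the funnel and single-seed descent.

    Funnel: four two-way F1s in the (randomized) founder order, two
    four-way hybrids, one eight-way hybrid; then ``n_selfing`` selfing
    meioses; the emitted line is one random gamete of the last generation,
    doubled (fully homozygous).
    """
    haps = [_founder_hap(int(i), length_cM) for i in order]
    f1 = [(haps[2 * k], haps[2 * k + 1]) for k in range(4)]
    fw1 = (_meiosis(*f1[0], length_cM, rng), _meiosis(*f1[1], length_cM, rng))
    fw2 = (_meiosis(*f1[2], length_cM, rng), _meiosis(*f1[3], length_cM, rng))
    ind = (_meiosis(*fw1, length_cM, rng), _meiosis(*fw2, length_cM, rng))
    for _ in range(n_selfing):
        ind = (_meiosis(*ind, length_cM, rng), _meiosis(*ind, length_cM, rng))
    return ind[int(rng.integers(2))]


def expected_meioses(n_selfing: int = 3) -> float:
    """Effective number of recombining meioses per lineage.

    Three funnel meioses always separate a line from its founders.  Each
    selfing generation adds crossovers only where the individual is still
    heterozygous for founder origin; heterozygosity halves each generation,
    so the selfing chain contributes about sum over generations of 2^-(t-1)
    relative to the first selfing meiosis.  This gives the default ancestry
    switch rate (per Morgan) used by the founder-inference HMM.
    """
    return 3.0 + sum(2.0 ** -(t - 1) for t in range(1, n_selfing + 1))


def simulate_magic_lines(
    founders: FounderGenotypes,
    gmap: GeneticMap,
    n_lines: int,
    n_selfing_generations: int = 3,
    fixed_funnel: bool = False,
    seed: int = 0,
    line_prefix: str = "L",
) -> tuple[pd.DataFrame, FounderMosaic]:
    """Derive homozygous MAGIC RILs and their ground-truth mosaics.

    Returns a (n_lines x n_markers) genotype DataFrame (rows = line ids,
    columns = marker ids, alleles 0/1) and the :class:`FounderMosaic`.
    The funnel founder order is randomized per line unless ``fixed_funnel``.
    """
    if n_lines < 1:
        raise SimulationError("n_lines must be >= 1")
    if n_selfing_generations < 1:
        raise SimulationError("n_selfing_generations must be >= 1")
    if len(founders.founders) != 8:
        raise SimulationError("need exactly 8 founders")
    rng = np.random.default_rng(seed)
    lines = [f"{line_prefix}{i + 1:04d}" for i in range(n_lines)]
    segments: dict[str, dict[str, Haplotype]] = {}
    geno = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    marker_pos = {c: gmap.chrom_table(c)["cM"].to_numpy(float) for c in gmap.chromosomes}
    marker_idx = {c: gmap.chrom_table(c).index.to_numpy() for c in gmap.chromosomes}
    for li, line in enumerate(lines):
        order = np.arange(8) if fixed_funnel else rng.permutation(8)
        segments[line] = {}
        for chrom in gmap.chromosomes:
            length = gmap.chrom_length_cM(chrom)
            hap = _derive_line_chrom(order, length, n_selfing_generations, rng)
            segments[line][chrom] = hap
            ends, fnd = hap
            idx = np.minimum(
                np.searchsorted(ends, marker_pos[chrom], side="right"), len(fnd) - 1
            )
            geno[li, marker_idx[chrom]] = founders.alleles[fnd[idx], marker_idx[chrom]]
    mosaic = FounderMosaic(
        chromosomes=gmap.chromosomes, lines=lines, segments=segments
    )
    gdf = pd.DataFrame(geno, index=pd.Index(lines, name="line"), columns=gmap.markers)
    return gdf, mosaic


def add_genotyping_error(
    genotypes: pd.DataFrame, error_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Flip each biallelic call to the other allele with the given rate."""
    if not (0.0 <= error_rate < 1.0):
        raise SimulationError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g = genotypes.to_numpy(np.int8).copy()
    flip = (rng.random(g.shape) < error_rate) & (g != MISSING)
    g[flip] = 1 - g[flip]
    return pd.DataFrame(g, index=genotypes.index, columns=genotypes.columns)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    mosaic: FounderMosaic,
    gmap: GeneticMap,
    arch: TraitArchitecture,
    treatments: list[str],
    experiment: str = "Exp1",
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level phenotypes from a trait architecture.

    A line's genetic value under a treatment is mu + the treatment offset +
    the sum over QTL of (treatment scale x effect of the founder carried at
    the QTL position).  Residual noise is i.i.d. normal; its variance is
    either given per treatment or calibrated per treatment so that the
    realized h2 = s2G / (s2G + s2E / r) equals the architecture's target.
    Traits flagged ``log`` are simulated on the log scale and exponentiated.

    Returns a long-format table: line, experiment, treatment, replicate,
    trait, value.
    """
    for q in arch.qtls:
        if q.chrom not in mosaic.chromosomes:
            raise SimulationError(f"QTL on unknown chromosome {q.chrom!r}")
        if not (0.0 <= q.position_cM <= gmap.chrom_length_cM(q.chrom)):
            raise SimulationError(
                f"QTL at {q.position_cM} cM off chromosome {q.chrom!r}"
            )
    rng = np.random.default_rng(seed)
    lines = mosaic.lines
    n = len(lines)
    r = arch.n_replicates
    # founder index per line per QTL
    fidx = np.empty((len(arch.qtls), n), dtype=np.int64)
    for qi, q in enumerate(arch.qtls):
        for li, line in enumerate(lines):
            fidx[qi, li] = mosaic.founder_at(line, q.chrom, q.position_cM)[0]
    rows = []
    for tr in treatments:
        g = np.full(n, arch.mu + arch.treatment_offsets.get(tr, 0.0))
        for qi, q in enumerate(arch.qtls):
            g += q.scale(tr) * np.asarray(q.effects)[fidx[qi]]
        if arch.target_h2 is not None:
            s2g = float(np.var(g))
            s2e = r * s2g * (1.0 - arch.target_h2) / arch.target_h2
        else:
            rv = arch.residual_var
            s2e = float(rv[tr] if isinstance(rv, dict) else rv)
        noise = rng.normal(0.0, np.sqrt(s2e), size=(n, r)) if s2e > 0 else np.zeros((n, r))
        values = g[:, None] + noise
        if arch.transform == "log":
            values = np.exp(values)
        for li, line in enumerate(lines):
            for rep in range(r):
                rows.append((line, experiment, tr, rep + 1, arch.trait, float(values[li, rep])))
    return pd.DataFrame(
        rows, columns=["line", "experiment", "treatment", "replicate", "trait", "value"]
    )
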