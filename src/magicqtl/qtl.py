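"""Multi-founder interval mapping by regression on founder probabilities.

At every evaluation position the per-line trait value is regressed on the
eight founder-origin probabilities.  Because the probabilities sum to one,
the design is rank-deficient with an intercept; fitting drops the last
founder column (its effect is absorbed into the intercept) and reported
effects are re-expressed as all-eight mean-centered values.  Evidence is
summarized as LOD = (n/2) log10(1 / (1 - R2)), the likelihood-ratio form of
the regression F test under normal errors.

Peaks above the LOD threshold (default 3) become QTL; the confidence
interval is the 1-LOD support interval, found by walking outward from the
peak until the profile drops one LOD unit below the peak.  QTL for the same
trait whose genetic CIs overlap across treatments are merged and classified
as constitutive, treatment-specific, or interactive (plasticity-mapped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gmap import GeneticMap
from .infer import FounderProbabilityGrid

__all__ = [
    "LodProfile",
    "QtlRecord",
    "QtlClassification",
    "QtlError",
    "PLASTICITY_PREFIX",
    "scan",
    "call_peaks",
    "classify_qtl",
    "joint_pve",
]

PLASTICITY_PREFIX = "PLASTICITY:"


class QtlError(ValueError):
    """Invalid QTL-mapping input."""


@dataclass(frozen=True)
class LodProfile:
    """Genome scan for one trait in one context (treatment or plasticity)."""

    trait: str
    context: str
    table: pd.DataFrame  # columns: chrom, cM, lod, r2, n

    def chrom_profile(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom].reset_index(drop=True)


@dataclass(frozen=True)
class QtlRecord:
    """One detected QTL with its support interval and founder effects."""

    trait: str
    context: str
    chrom: str
    peak_cM: float
    peak_lod: float
    ci_low_cM: float
    ci_high_cM: float
    ci_low_bp: int
    ci_high_bp: int
    effects: tuple[float, ...]  # raw fitted effects, last founder = 0 reference
    effects_centered: tuple[float, ...] = field(init=False)
    pve: float = 0.0
    n: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low_cM <= self.peak_cM <= self.ci_high_cM):
            raise QtlError("confidence interval does not contain the peak")
        e = np.asarray(self.effects, dtype=float)
        if len(e) != 8:
            raise QtlError("expected 8 founder effects")
        object.__setattr__(self, "effects_centered", tuple(e - e.mean()))

    @property
    def is_plasticity(self) -> bool:
        return self.context.startswith(PLASTICITY_PREFIX)

    def to_row(self, founders: tuple[str, ...]) -> dict:
        row = {
            "trait": self.trait,
            "context": self.context,
            "chrom": self.chrom,
            "peak_cM": self.peak_cM,
            "peak_lod": self.peak_lod,
            "ci_low_cM": self.ci_low_cM,
            "ci_high_cM": self.ci_high_cM,
            "ci_low_bp": self.ci_low_bp,
            "ci_high_bp": self.ci_high_bp,
            "pve": self.pve,
            "n": self.n,
        }
        for f, e, ec in zip(founders, self.effects, self.effects_centered):
            row[f"eff_{f}"] = e
            row[f"eff_centered_{f}"] = ec
        return row


def _design(probs: np.ndarray) -> np.ndarray:
    """Intercept + first seven founder-probability columns (drop-one)."""
    n = probs.shape[0]
    return np.column_stack([np.ones(n), probs[:, :7]])


def _fit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares R2 (vs intercept-only) and coefficients."""
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0, coef
    r2 = 1.0 - float(np.sum(resid**2)) / tss
    return max(r2, 0.0), coef


def lod_from_r2(r2: float | np.ndarray, n: int) -> np.ndarray:
    """LOD = (n/2) log10(1 / (1 - R2))."""
    r2 = np.clip(np.asarray(r2, dtype=float), 0.0, 1.0 - 1e-15)
    return n / 2.0 * np.log10(1.0 / (1.0 - r2))


def scan(
    grid: FounderProbabilityGrid,
    phenotype: pd.Series,
    trait: str,
    context: str,
) -> LodProfile:
    """Genome scan of one per-line trait vector on the probability grid.

    ``phenotype`` is indexed by line id (replicate means, transformed
    upstream).  Lines missing either genotype probabilities or phenotype
    are dropped; at least 10 lines are required (8 founder effects + 2).
    A constant phenotype yields an all-zero profile with a warning.
    """
    pheno = phenotype.dropna()
    line_index = {line: i for i, line in enumerate(grid.lines)}
    common = [l for l in pheno.index if l in line_index]
    if len(common) < 10:
        raise QtlError(f"only {len(common)} usable lines; need >= 10")
    rows_idx = np.asarray([line_index[l] for l in common])
    y = pheno[common].to_numpy(float)
    constant = np.all(y == y[0])
    if constant:
        warnings.warn(f"constant phenotype for {trait!r}/{context!r}; LOD = 0", stacklevel=2)
    n = len(y)
    recs = []
    for chrom in grid.chromosomes:
        pos = grid.positions[chrom]
        p = grid.probs[chrom][rows_idx]
        for j, cm in enumerate(pos):
            if constant:
                r2 = 0.0
            else:
                r2, _ = _fit_r2(_design(p[:, j, :]), y)
            recs.append((chrom, float(cm), r2, n))
    t = pd.DataFrame(recs, columns=["chrom", "cM", "r2", "n"])
    t["lod"] = lod_from_r2(t["r2"].to_numpy(), n)
    return LodProfile(trait=trait, context=context, table=t[["chrom", "cM", "lod", "r2", "n"]])


def _support_interval(cm: np.ndarray, lod: np.ndarray, peak_idx: int) -> tuple[float, float]:
    """1-LOD support interval: walk outward until LOD <= peak - 1."""
    target = lod[peak_idx] - 1.0
    lo = peak_idx
    while lo > 0 and lod[lo] > target:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi] > target:
        hi += 1
    return float(cm[lo]), float(cm[hi])


def _peak_effects(
    grid: FounderProbabilityGrid,
    chrom: str,
    cm: float,
    rows_idx: np.ndarray,
    y: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Founder effects (all 8, reference-founder raw form) and R2 at a position."""
    p = grid.block(chrom, cm)[rows_idx]
    r2, coef = _fit_r2(_design(p), y)
    effects = np.concatenate([coef[1:8], [0.0]])  # dropped founder as reference 0
    return effects, r2


def call_peaks(
    profile: LodProfile,
    grid: FounderProbabilityGrid,
    phenotype: pd.Series,
    gmap: GeneticMap,
    lod_threshold: float = 3.0,
) -> list[QtlRecord]:
    """Call QTL from a LOD profile.

    Local maxima at or above the threshold seed 1-LOD support intervals;
    peaks on a chromosome whose intervals overlap are merged, keeping the
    higher peak.  Each record carries founder effects, PVE (R2 x 100 at the
    peak) and the bp projection of its interval.
    """
    pheno = phenotype.dropna()
    line_index = {line: i for i, line in enumerate(grid.lines)}
    common = [l for l in pheno.index if l in line_index]
    rows_idx = np.asarray([line_index[l] for l in common])
    y = pheno[common].to_numpy(float)
    records: list[QtlRecord] = []
    for chrom in profile.table["chrom"].unique():
        sub = profile.chrom_profile(chrom)
        cm = sub["cM"].to_numpy(float)
        lod = sub["lod"].to_numpy(float)
        n = int(sub["n"].iloc[0])
        # local maxima >= threshold (plateaus: keep leftmost point)
        cand = [
            i
            for i in range(len(lod))
            if lod[i] >= lod_threshold
            and (i == 0 or lod[i] > lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        chrom_recs: list[tuple[int, tuple[float, float]]] = []
        for i in cand:
            ci = _support_interval(cm, lod, i)
            chrom_recs.append((i, ci))
        # merge overlapping support intervals, keep the higher peak
        merged: list[tuple[int, tuple[float, float]]] = []
        for i, ci in sorted(chrom_recs, key=lambda t: t[1][0]):
            if merged and ci[0] <= merged[-1][1][1]:
                pi, pci = merged[-1]
                keep = i if lod[i] > lod[pi] else pi
                merged[-1] = (keep, (min(ci[0], pci[0]), max(ci[1], pci[1])))
            else:
                merged.append((i, ci))
        for i, ci in merged:
            effects, r2 = _peak_effects(grid, chrom, cm[i], rows_idx, y)
            lo_bp, hi_bp = gmap.project_bp(chrom, np.asarray(ci))
            records.append(
                QtlRecord(
                    trait=profile.trait,
                    context=profile.context,
                    chrom=str(chrom),
                    peak_cM=float(cm[i]),
                    peak_lod=float(lod[i]),
                    ci_low_cM=ci[0],
                    ci_high_cM=ci[1],
                    ci_low_bp=int(lo_bp),
                    ci_high_bp=int(hi_bp),
                    effects=tuple(effects),
                    pve=r2 * 100.0,
                    n=n,
                )
            )
    return records


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

LABELS = ("constitutive", "treatment-specific", "interactive-specific", "interactive-shared")


@dataclass(frozen=True)
class QtlClassification:
    """Merged same-trait QTL with their expression-pattern label."""

    groups: tuple[tuple[QtlRecord, ...], ...]
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, (grp, lab) in enumerate(zip(self.groups, self.labels)):
            rep = max(grp, key=lambda r: r.peak_lod)
            rows.append(
                {
                    "qtl_id": f"{rep.trait}_{rep.chrom}_{gi + 1}",
                    "trait": rep.trait,
                    "chrom": rep.chrom,
                    "label": lab,
                    "n_members": len(grp),
                    "contexts": ";".join(sorted(r.context for r in grp)),
                    "peak_cM": rep.peak_cM,
                    "peak_lod": rep.peak_lod,
                }
            )
        return pd.DataFrame(rows)

    def venn_counts(self) -> pd.DataFrame:
        """Count merged QTL per combination of mean-trait contexts (Venn cells)."""
        cells: dict[str, int] = {}
        for grp in self.groups:
            contexts = sorted({r.context for r in grp if not r.is_plasticity})
            if not contexts:
                contexts = sorted({r.context for r in grp})
            key = "&".join(contexts)
            cells[key] = cells.get(key, 0) + 1
        return pd.DataFrame(
            sorted(cells.items()), columns=["contexts", "n_qtl"]
        )


def _overlap(a: QtlRecord, b: QtlRecord) -> bool:
    return a.ci_low_cM <= b.ci_high_cM and b.ci_low_cM <= a.ci_high_cM


def classify_qtl(records: list[QtlRecord]) -> QtlClassification:
    """Merge same-trait, same-chromosome QTL with overlapping genetic CIs.

    Connected components of the overlap graph become single QTL, labelled:

    * ``constitutive`` — members from two or more treatments (no plasticity
      member): one locus expressed in several conditions;
    * ``treatment-specific`` — a single treatment context;
    * ``interactive-specific`` — only plasticity contexts (a pure QTLxE);
    * ``interactive-shared`` — plasticity plus mean-trait members (allelic
      sensitivity: the locus moves the mean and its response).
    """
    groups: list[list[QtlRecord]] = []
    by_key: dict[tuple[str, str], list[int]] = {}
    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for (key), idxs in _group_indices(records).items():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if _overlap(records[i], records[j]):
                    union(i, j)
    comp: dict[int, list[QtlRecord]] = {}
    for i, rec in enumerate(records):
        comp.setdefault(find(i), []).append(rec)
    groups = list(comp.values())
    labels = []
    for grp in groups:
        mean_contexts = {r.context for r in grp if not r.is_plasticity}
        has_plast = any(r.is_plasticity for r in grp)
        if has_plast:
            labels.append("interactive-shared" if mean_contexts else "interactive-specific")
        elif len(mean_contexts) >= 2:
            labels.append("constitutive")
        else:
            labels.append("treatment-specific")
    return QtlClassification(groups=tuple(tuple(g) for g in groups), labels=tuple(labels))


def _group_indices(records: list[QtlRecord]) -> dict[tuple[str, str], list[int]]:
    out: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(records):
        out.setdefault((r.trait, r.chrom), []).append(i)
    return out


def joint_pve(
    records: list[QtlRecord],
    grid: FounderProbabilityGrid,
    phenotype: pd.Series,
) -> float:
    """R2 x 100 of the joint regression on all peak probability blocks.

    Duplicate peaks contribute collinear columns; the rank-revealing
    least-squares solve leaves the fit (and hence the joint PVE) unchanged.
    """
    if not records:
        raise QtlError("need at least one QTL record")
    pheno = phenotype.dropna()
    line_index = {line: i for i, line in enumerate(grid.lines)}
    common = [l for l in pheno.index if l in line_index]
    rows_idx = np.asarray([line_index[l] for l in common])
    y = pheno[common].to_numpy(float)
    blocks = [np.ones((len(y), 1))]
    seen = set()
    dup = False
    for rec in records:
        key = (rec.chrom, rec.peak_cM)
        if key in seen:
            dup = True
        seen.add(key)
        blocks.append(grid.block(rec.chrom, rec.peak_cM)[rows_idx][:, :7])
    if dup:
        warnings.warn("duplicate/collinear QTL blocks in joint fit", stacklevel=2)
    x = np.hstack(blocks)
    r2, _ = _fit_r2(x, y)
    return r2 * 100.0
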