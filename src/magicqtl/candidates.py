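"""Candidate-gene reduction inside a QTL's physical confidence interval.

The eight founders of a MAGIC population carry known alleles at every
resequenced polymorphism.  When the founder allelic effects at a QTL split
the founders into a high group and a low group, the causal polymorphism
should follow that split: all founders on one side share an allele, all
founders on the other side share the other.  Filtering the interval's
polymorphisms by that pattern, and keeping genes associated with at least
one passing polymorphism, typically reduces hundreds of positional
candidates to a short list.

Groupings are written in a small pattern language: founder names (unique
prefixes accepted) joined by ``=`` within a group, groups separated by
``#``, and ``all`` standing for every founder not named on the other side,
e.g. ``Cerv # all`` or ``(Cerv = Stup) # (LA14 = LA0)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl import QtlRecord
from .simulate import GeneSet, VariantTable, MISSING

__all__ = [
    "FounderGrouping",
    "GroupingParseError",
    "CandidateError",
    "interval_content",
    "parse_grouping",
    "suggest_grouping",
    "filter_candidates",
    "cg_report",
]


class CandidateError(ValueError):
    """Invalid candidate-filter input."""


class GroupingParseError(CandidateError):
    """Malformed grouping pattern; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


@dataclass(frozen=True)
class FounderGrouping:
    """Disjoint founder subsets varying in opposite directions at a QTL."""

    group_a: frozenset[str]
    group_b: frozenset[str]
    founders: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise CandidateError("both groups must be nonempty")
        if self.group_a & self.group_b:
            raise CandidateError(
                f"groups overlap: {sorted(self.group_a & self.group_b)}"
            )
        unknown = (self.group_a | self.group_b) - set(self.founders)
        if unknown:
            raise CandidateError(f"unknown founders: {sorted(unknown)}")

    @property
    def ungrouped(self) -> frozenset[str]:
        return frozenset(self.founders) - self.group_a - self.group_b

    def pattern(self) -> str:
        def side(s: frozenset[str]) -> str:
            names = sorted(s, key=self.founders.index)
            return names[0] if len(names) == 1 else "(" + " = ".join(names) + ")"

        return f"{side(self.group_a)} # {side(self.group_b)}"


# ---------------------------------------------------------------------------
# interval content
# ---------------------------------------------------------------------------


def interval_content(
    ci_bp: tuple[int, int],
    chrom: str,
    variants: VariantTable,
    genes: GeneSet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes and polymorphisms inside a physical confidence interval.

    The interval is half-open [low, high).  Genes count when they overlap
    the interval at all (not containment); polymorphisms when their
    position lies inside it.
    """
    low, high = ci_bp
    if low > high:
        raise CandidateError(f"invalid interval [{low}, {high})")
    known = set(variants.table["chrom"]) | set(genes.table["chrom"])
    if chrom not in known:
        raise CandidateError(f"unknown chromosome {chrom!r}")
    g = genes.table
    if low == high:  # empty interval overlaps nothing
        return g.iloc[0:0], variants.table.iloc[0:0]
    g_hit = g[(g["chrom"] == chrom) & (g["start"] < high) & (g["end"] > low)]
    v = variants.table
    v_hit = v[(v["chrom"] == chrom) & (v["pos"] >= low) & (v["pos"] < high)]
    return g_hit.reset_index(drop=True), v_hit.reset_index(drop=True)


# ---------------------------------------------------------------------------
# grouping patterns
# ---------------------------------------------------------------------------


def _resolve_name(token: str, founders: tuple[str, ...], position: int) -> str:
    matches = [f for f in founders if f.lower().startswith(token.lower())]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise GroupingParseError(f"unknown founder name {token!r}", position)
    raise GroupingParseError(
        f"ambiguous founder prefix {token!r} (matches {matches})", position
    )


def parse_grouping(pattern: str, founders: tuple[str, ...]) -> FounderGrouping:
    """Parse a Table-style filter pattern into a :class:`FounderGrouping`.

    Grammar: ``side '#' side`` where a side is ``all`` or one or more
    founder names joined by ``=``, optionally parenthesized.  ``all`` on
    one side means the complement of the other side.
    """
    if pattern.count("#") != 1:
        raise GroupingParseError("pattern must contain exactly one '#'", pattern.find("#"))
    left_txt, right_txt = pattern.split("#")

    def parse_side(txt: str, offset: int) -> frozenset[str] | None:
        s = txt.strip()
        if s.startswith("(") and s.endswith(")"):
            s = s[1:-1]
        if not s.strip():
            raise GroupingParseError("empty group", offset)
        if s.strip().lower() == "all":
            return None
        names = []
        for tok in s.split("="):
            tok = tok.strip()
            if not tok:
                raise GroupingParseError("empty founder name", offset + txt.find("="))
            if not re.fullmatch(r"[A-Za-z0-9_.-]+", tok):
                raise GroupingParseError(f"bad token {tok!r}", offset + txt.find(tok))
            names.append(_resolve_name(tok, founders, offset + txt.find(tok)))
        return frozenset(names)

    a = parse_side(left_txt, 0)
    b = parse_side(right_txt, len(left_txt) + 1)
    if a is None and b is None:
        raise GroupingParseError("'all' cannot appear on both sides", 0)
    if a is None:
        a = frozenset(founders) - b
    if b is None:
        b = frozenset(founders) - a
    try:
        return FounderGrouping(group_a=a, group_b=b, founders=founders)
    except CandidateError as exc:
        raise GroupingParseError(str(exc), 0) from exc


def suggest_grouping(
    founder_effects,
    founders: tuple[str, ...],
    margin_fraction: float = 0.25,
    min_gap: float = 1e-9,
) -> tuple[FounderGrouping | None, str]:
    """Heuristic grouping from the eight founder effects at a QTL.

    Effects are mean-centered and sorted; the split is placed at the
    largest gap, group A being the high-effect side.  Founders whose
    centered effect falls within ``margin_fraction`` of the gap around its
    midpoint are left ungrouped.  Returns (grouping or None, note); the
    note flags the result as a suggestion requiring inspection, mirroring
    how such groupings are chosen by eye in practice.
    """
    e = np.asarray(founder_effects, dtype=float)
    if len(e) != len(founders):
        raise CandidateError("effect vector length must match founders")
    if not np.all(np.isfinite(e)):
        raise CandidateError("effects must be finite")
    e = e - e.mean()
    order = np.argsort(e)
    gaps = np.diff(e[order])
    if gaps.max() <= min_gap:
        return None, "no divergence among founder effects; no grouping suggested"
    split = int(np.argmax(gaps))
    gap = float(gaps[split])
    mid = (e[order][split] + e[order][split + 1]) / 2.0
    margin = margin_fraction * gap
    low = {founders[i] for i in order[: split + 1] if e[i] < mid - margin}
    high = {founders[i] for i in order[split + 1 :] if e[i] > mid + margin}
    if not low or not high:
        return None, "largest gap leaves an empty side after margin; no grouping"
    grouping = FounderGrouping(
        group_a=frozenset(high), group_b=frozenset(low), founders=founders
    )
    note = (
        f"heuristic suggestion (largest-gap split, margin {margin_fraction:.2f} of gap "
        f"{gap:.3g}); confirm against the founder-effect plot before filtering"
    )
    return grouping, note


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_candidates(
    polymorphisms: pd.DataFrame,
    genes: pd.DataFrame,
    grouping: FounderGrouping,
    permissive_missing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep polymorphisms whose founder alleles follow the grouping.

    A polymorphism passes when every group-A founder carries one allele,
    every group-B founder carries one allele, and the two alleles differ;
    ungrouped founders are unconstrained.  A missing allele in a grouped
    founder fails the polymorphism (conservative default) or is ignored
    with ``permissive_missing`` as long as at least one call remains per
    group.  Candidate genes are those associated with a passing
    polymorphism.
    """
    a_cols = [f for f in grouping.founders if f in grouping.group_a]
    b_cols = [f for f in grouping.founders if f in grouping.group_b]
    if polymorphisms.empty:
        return genes.iloc[0:0], polymorphisms.iloc[0:0]
    a = polymorphisms[a_cols].to_numpy(dtype=float)
    b = polymorphisms[b_cols].to_numpy(dtype=float)
    a = np.where(a == MISSING, np.nan, a)
    b = np.where(b == MISSING, np.nan, b)

    def uniform(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        any_missing = np.isnan(m).any(axis=1)
        all_missing = np.isnan(m).all(axis=1)
        first = np.nanmax(m, axis=1, initial=-np.inf)
        last = np.nanmin(m, axis=1, initial=np.inf)
        consistent = first == last  # all non-missing calls equal
        if permissive_missing:
            ok = consistent & ~all_missing
        else:
            ok = consistent & ~any_missing
        allele = np.where(ok, first, np.nan)
        return ok, allele

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ok_a, allele_a = uniform(a)
        ok_b, allele_b = uniform(b)
    passing = ok_a & ok_b & (allele_a != allele_b)
    kept_poly = polymorphisms[passing].reset_index(drop=True)
    kept_genes = genes[genes["gene"].isin(set(kept_poly["gene"]))].reset_index(drop=True)
    return kept_genes, kept_poly


def cg_report(
    record: QtlRecord,
    grouping: FounderGrouping,
    variants: VariantTable,
    genes: GeneSet,
    permissive_missing: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-QTL candidate-gene summary plus the per-candidate listing.

    The summary row carries the interval size, the total gene/polymorphism
    counts in the interval, the filter pattern and the filtered counts
    (Nb.CG, Nb.CP); the listing has one row per candidate polymorphism with
    its effect class and the gene annotation.
    """
    ci = (record.ci_low_bp, record.ci_high_bp)
    g_all, v_all = interval_content(ci, record.chrom, variants, genes)
    g_kept, v_kept = filter_candidates(v_all, g_all, grouping, permissive_missing)
    summary = pd.Series(
        {
            "trait": record.trait,
            "context": record.context,
            "chrom": record.chrom,
            "peak_cM": record.peak_cM,
            "ci_low_bp": ci[0],
            "ci_high_bp": ci[1],
            "ci_size_bp": ci[1] - ci[0],
            "filter": grouping.pattern(),
            "n_genes": len(g_all),
            "n_polymorphisms": len(v_all),
            "n_candidate_genes": len(g_kept),
            "n_candidate_polymorphisms": len(v_kept),
        }
    )
    if v_kept.empty:
        listing = pd.DataFrame(
            columns=["chrom", "pos", "gene", "effect", "annotation"]
        )
    else:
        ann = genes.table.set_index("gene")["annotation"]
        listing = v_kept[["chrom", "pos", "gene", "effect"]].copy()
        listing["annotation"] = listing["gene"].map(ann)
    return summary, listing
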