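"""Genetic maps: markers with genetic (cM) and physical (bp) coordinates.

The map is the bridge between the genetic scale on which recombination,
founder inference and QTL scanning operate, and the physical scale on which
genes and polymorphisms live.  Within each chromosome the cM and bp orders
must agree, which is what makes piecewise-linear projection between the two
scales well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "MapError"]


class MapError(ValueError):
    """A genetic map violated one of its structural invariants."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map over a set of chromosomes.

    Parameters
    ----------
    table:
        One row per marker with columns ``marker``, ``chrom``, ``cM``, ``bp``.
        Markers are sorted by (chromosome, cM); chromosome order follows first
        appearance in the input.
    """

    table: pd.DataFrame
    chromosomes: tuple[str, ...] = field(init=False)

    REQUIRED = ("marker", "chrom", "cM", "bp")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise MapError(f"map table missing columns: {missing}")
        t = t.copy()
        t["chrom"] = t["chrom"].astype(str)
        chrom_order = list(dict.fromkeys(t["chrom"]))
        t["_c"] = pd.Categorical(t["chrom"], categories=chrom_order, ordered=True)
        t = t.sort_values(["_c", "cM"], kind="stable").drop(columns="_c")
        t = t.reset_index(drop=True)
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise MapError(f"duplicate marker id: {dup!r}")
        for chrom, sub in t.groupby("chrom", sort=False):
            if len(sub) < 2:
                raise MapError(f"chromosome {chrom!r} has <2 markers")
            cm = sub["cM"].to_numpy(float)
            bp = sub["bp"].to_numpy()
            if (cm < 0).any():
                bad = sub["marker"].iloc[int(np.argmax(cm < 0))]
                raise MapError(f"negative cM at marker {bad!r}")
            if (bp <= 0).any():
                bad = sub["marker"].iloc[int(np.argmax(bp <= 0))]
                raise MapError(f"non-positive bp at marker {bad!r}")
            if (np.diff(bp) < 0).any():
                i = int(np.argmax(np.diff(bp) < 0)) + 1
                raise MapError(
                    f"bp order disagrees with cM order at marker "
                    f"{sub['marker'].iloc[i]!r} on {chrom!r}"
                )
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "chromosomes", tuple(chrom_order))

    # -- accessors ---------------------------------------------------------

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.table["marker"])

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        if chrom not in self.chromosomes:
            raise MapError(f"unknown chromosome {chrom!r}")
        return self.table[self.table["chrom"] == chrom]

    def chrom_length_cM(self, chrom: str) -> float:
        return float(self.chrom_table(chrom)["cM"].max())

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chrom_length_cM(c) for c in self.chromosomes))

    # -- projection --------------------------------------------------------

    def project_bp(self, chrom: str, position_cM: float | np.ndarray) -> np.ndarray:
        """Project genetic position(s) to physical bp.

        Piecewise-linear interpolation between flanking markers; positions
        outside the marker span are clamped to the terminal markers.
        """
        sub = self.chrom_table(chrom)
        cm = sub["cM"].to_numpy(float)
        bp = sub["bp"].to_numpy(float)
        out = np.interp(np.asarray(position_cM, dtype=float), cm, bp)
        return np.round(out).astype(np.int64)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
        return cls(t)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneticMap):
            return NotImplemented
        return self.table.equals(other.table)
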