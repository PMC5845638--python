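"""Founder-origin inference for MAGIC lines.

For every line and every evaluation position (all marker positions plus an
even lattice, by default every 2 cM), computes the posterior probability
that each of the eight founders is the origin of the local genome, by
forward-backward over an order-1 hidden Markov chain per chromosome:

* hidden states: the eight founders;
* transitions between consecutive evaluation positions follow from their
  genetic distance via the Haldane model with an ancestry switch rate
  ``n_meioses`` per Morgan (the effective number of recombining meioses
  separating a line from its founders): over distance d Morgans the chain
  jumps with probability 1 - exp(-n_meioses * d) to a uniformly random
  founder (possibly the same one);
* emissions at marker positions: probability 1 - error_rate when the line
  allele matches that founder's allele, error_rate otherwise; a missing
  line or founder call emits uniformly; grid-only positions carry no
  emission and receive their posterior purely through the chain.

Assignment follows the strict majority rule: a position is labelled with
the argmax founder only when its posterior exceeds the threshold
(default 0.5); ties and sub-threshold maxima are left UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmap import GeneticMap
from .simulate import FounderGenotypes, FounderMosaic, MISSING, expected_meioses

__all__ = [
    "UNASSIGNED",
    "FounderProbabilityGrid",
    "InferenceError",
    "infer_founder_probabilities",
    "assign_founder",
    "assignment_summary",
]

UNASSIGNED = -1


class InferenceError(ValueError):
    """Invalid input to founder inference."""


@dataclass(frozen=True)
class FounderProbabilityGrid:
    """Posterior founder probabilities per line x evaluation position.

    ``positions`` maps chromosome -> (cM array, is_marker mask, marker column
    indices into the genotype matrix); ``probs`` maps chromosome -> array of
    shape (n_lines, n_positions, 8).  Probability vectors sum to 1.
    """

    lines: tuple[str, ...]
    founders: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions: dict[str, np.ndarray]  # cM per chromosome
    is_marker: dict[str, np.ndarray]  # bool mask aligned with positions
    probs: dict[str, np.ndarray]  # (n_lines, n_pos, 8)

    def validate(self) -> None:
        for chrom in self.chromosomes:
            p = self.probs[chrom]
            if not np.all((p >= 0) & (p <= 1)):
                raise InferenceError(f"probabilities outside [0,1] on {chrom}")
            if not np.allclose(p.sum(axis=2), 1.0, atol=1e-9):
                raise InferenceError(f"posterior does not sum to 1 on {chrom}")

    def block(self, chrom: str, position_cM: float) -> np.ndarray:
        """(n_lines, 8) probabilities at the evaluation position nearest to cM."""
        pos = self.positions[chrom]
        j = int(np.argmin(np.abs(pos - position_cM)))
        return self.probs[chrom][:, j, :]

    def to_frame(self) -> pd.DataFrame:
        """Long TSV-ready export: line, chrom, position_cM, is_marker, p1..p8."""
        frames = []
        for chrom in self.chromosomes:
            p = self.probs[chrom]
            n_lines, n_pos, _ = p.shape
            df = pd.DataFrame(
                p.reshape(n_lines * n_pos, 8),
                columns=[f"p_{f}" for f in self.founders],
            )
            df.insert(0, "is_marker", np.tile(self.is_marker[chrom], n_lines))
            df.insert(0, "position_cM", np.tile(self.positions[chrom], n_lines))
            df.insert(0, "chrom", chrom)
            df.insert(0, "line", np.repeat(list(self.lines), n_pos))
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def save_npz(self, path) -> None:
        payload = {
            "lines": np.asarray(self.lines),
            "founders": np.asarray(self.founders),
            "chromosomes": np.asarray(self.chromosomes),
        }
        for chrom in self.chromosomes:
            payload[f"pos_{chrom}"] = self.positions[chrom]
            payload[f"mask_{chrom}"] = self.is_marker[chrom]
            payload[f"probs_{chrom}"] = self.probs[chrom]
        np.savez_compressed(path, **payload)

    @classmethod
    def load_npz(cls, path) -> "FounderProbabilityGrid":
        z = np.load(path, allow_pickle=False)
        chroms = tuple(str(c) for c in z["chromosomes"])
        return cls(
            lines=tuple(str(x) for x in z["lines"]),
            founders=tuple(str(x) for x in z["founders"]),
            chromosomes=chroms,
            positions={c: z[f"pos_{c}"] for c in chroms},
            is_marker={c: z[f"mask_{c}"] for c in chroms},
            probs={c: z[f"probs_{c}"] for c in chroms},
        )


def _evaluation_positions(
    gmap: GeneticMap, chrom: str, grid_step_cM: float
) -> tuple[np.ndarray, np.ndarray]:
    """Union of marker positions and an even lattice; exact-cM duplicates dropped."""
    marker_cm = gmap.chrom_table(chrom)["cM"].to_numpy(float)
    length = gmap.chrom_length_cM(chrom)
    if grid_step_cM and grid_step_cM > 0:
        lattice = np.arange(0.0, length + 1e-9, grid_step_cM)
    else:
        lattice = np.empty(0)
    pos = np.unique(np.concatenate([marker_cm, lattice]))
    is_marker = np.isin(pos, marker_cm)
    return pos, is_marker


def _transition_terms(dist_cM: np.ndarray, n_meioses: float) -> np.ndarray:
    """Probability of at least one ancestry jump over each inter-position gap."""
    return 1.0 - np.exp(-n_meioses * np.asarray(dist_cM, dtype=float) / 100.0)


def _emission_tensor(
    line_alleles: np.ndarray, founder_alleles: np.ndarray, error_rate: float
) -> np.ndarray:
    """(n_lines, n_markers, 8) emission likelihoods.

    Match -> 1 - error_rate, mismatch -> error_rate, missing on either
    side -> 1 (uninformative).
    """
    la = line_alleles[:, :, None]  # (L, M, 1)
    fa = founder_alleles.T[None, :, :]  # (1, M, 8)
    em = np.where(la == fa, 1.0 - error_rate, error_rate)
    uninformative = (la == MISSING) | (fa == MISSING)
    return np.where(uninformative, 1.0, em)


def infer_founder_probabilities(
    line_genotypes: pd.DataFrame,
    founders: FounderGenotypes,
    gmap: GeneticMap,
    error_rate: float = 0.01,
    grid_step_cM: float = 2.0,
    n_meioses: float | None = None,
) -> FounderProbabilityGrid:
    """Posterior founder-origin probabilities by forward-backward.

    Parameters
    ----------
    line_genotypes:
        (n_lines x n_markers) allele matrix, columns = marker ids matching
        the map; alleles 0/1, -1 missing (heterozygous calls should be
        recoded missing upstream; lines are assumed inbred).
    error_rate:
        Genotyping/emission error, in [0, 0.5).
    grid_step_cM:
        Spacing of the no-emission lattice added between markers (0 to
        evaluate at markers only).
    n_meioses:
        Ancestry switch rate per Morgan; defaults to the funnel +
        three-selfing expectation of the simulator's design.
    """
    if not (0.0 <= error_rate < 0.5):
        raise InferenceError("error_rate must be in [0, 0.5)")
    if n_meioses is None:
        n_meioses = expected_meioses()
    shared = [m for m in gmap.markers if m in line_genotypes.columns]
    if len(shared) != gmap.n_markers:
        missing = set(gmap.markers) - set(line_genotypes.columns)
        raise InferenceError(
            f"genotypes missing {len(missing)} mapped markers, e.g. {sorted(missing)[:3]}"
        )
    geno = line_genotypes[list(gmap.markers)].to_numpy(np.int8)
    lines = tuple(line_genotypes.index.astype(str))
    n_lines = geno.shape[0]

    positions: dict[str, np.ndarray] = {}
    marker_mask: dict[str, np.ndarray] = {}
    probs: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_table(chrom)
        col_idx = sub.index.to_numpy()
        if len(col_idx) == 0:
            raise InferenceError(f"no shared markers on chromosome {chrom!r}")
        pos, is_marker = _evaluation_positions(gmap, chrom, grid_step_cM)
        n_pos = len(pos)
        # emissions: ones at grid-only positions
        em = np.ones((n_lines, n_pos, 8))
        marker_cm = sub["cM"].to_numpy(float)
        # marker columns may share a cM position; multiply emissions in place
        em_markers = _emission_tensor(geno[:, col_idx], founders.alleles[:, col_idx], error_rate)
        pos_of_marker = np.searchsorted(pos, marker_cm)
        for k in range(len(col_idx)):
            em[:, pos_of_marker[k], :] *= em_markers[:, k, :]
        jump = _transition_terms(np.diff(pos), n_meioses)  # (n_pos-1,)
        probs[chrom] = _forward_backward(em, jump)
        positions[chrom] = pos
        marker_mask[chrom] = is_marker
    grid = FounderProbabilityGrid(
        lines=lines,
        founders=founders.founders,
        chromosomes=gmap.chromosomes,
        positions=positions,
        is_marker=marker_mask,
        probs=probs,
    )
    grid.validate()
    return grid


def _forward_backward(em: np.ndarray, jump: np.ndarray) -> np.ndarray:
    """Scaled forward-backward over the 8-state uniform-jump chain.

    ``em``: (n_lines, n_pos, 8) emissions; ``jump``: (n_pos-1,) probability
    of an ancestry jump in each gap.  The transition matrix over a gap is
    (1 - j) I + (j / 8) J, which lets both recursions run as vector ops.
    """
    n_lines, n_pos, k = em.shape
    alpha = np.empty_like(em)
    scale = np.empty((n_lines, n_pos))
    a = em[:, 0, :] / k
    scale[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / scale[:, 0][:, None]
    for t in range(1, n_pos):
        j = jump[t - 1]
        pred = (1.0 - j) * alpha[:, t - 1] + j / k * alpha[:, t - 1].sum(axis=1, keepdims=True)
        a = pred * em[:, t, :]
        s = a.sum(axis=1)
        s[s == 0] = 1.0
        scale[:, t] = s
        alpha[:, t] = a / s[:, None]
    beta = np.empty_like(em)
    beta[:, -1] = 1.0
    for t in range(n_pos - 2, -1, -1):
        j = jump[t]
        w = beta[:, t + 1] * em[:, t + 1, :]
        beta[:, t] = ((1.0 - j) * w + j / k * w.sum(axis=1, keepdims=True)) / scale[
            :, t + 1
        ][:, None]
    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    return post


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def assign_founder(grid: FounderProbabilityGrid, threshold: float = 0.5) -> dict[str, np.ndarray]:
    """Label each line x position with its argmax founder, strictly above threshold.

    Returns chromosome -> (n_lines, n_pos) int array of founder indices,
    ``UNASSIGNED`` (-1) where the maximum posterior does not exceed the
    threshold or is shared exactly between founders.
    """
    out = {}
    for chrom in grid.chromosomes:
        p = grid.probs[chrom]
        best = p.argmax(axis=2)
        pmax = p.max(axis=2)
        tied = (np.isclose(p, pmax[:, :, None], rtol=0.0, atol=0.0)).sum(axis=2) > 1
        lab = np.where((pmax > threshold) & ~tied, best, UNASSIGNED)
        out[chrom] = lab.astype(np.int64)
    return out


def assignment_summary(
    grid: FounderProbabilityGrid,
    assignment: dict[str, np.ndarray],
    truth: FounderMosaic | None = None,
    markers_only: bool = True,
) -> dict:
    """Assignment statistics, optionally against the simulated truth.

    Reports the assigned and unassigned fractions and the per-founder genome
    share among assigned positions; with a truth mosaic, also the accuracy
    (fraction of evaluated positions where the assigned founder equals the
    true founder — unassigned positions count as errors) and the accuracy
    among assigned positions only.
    """
    n_total = 0
    n_assigned = 0
    shares = np.zeros(len(grid.founders))
    n_correct = 0
    for chrom in grid.chromosomes:
        lab = assignment[chrom]
        mask = grid.is_marker[chrom] if markers_only else np.ones(lab.shape[1], bool)
        lab = lab[:, mask]
        n_total += lab.size
        assigned = lab != UNASSIGNED
        n_assigned += int(assigned.sum())
        np.add.at(shares, lab[assigned], 1)
        if truth is not None:
            pos = grid.positions[chrom][mask]
            true_lab = np.stack(
                [truth.founder_at(line, chrom, pos) for line in grid.lines]
            )
            if true_lab.shape != lab.shape:
                raise InferenceError("truth mosaic does not align with assignment")
            n_correct += int(np.sum(assigned & (lab == true_lab)))
    out = {
        "n_positions": n_total,
        "assigned_fraction": n_assigned / n_total if n_total else 0.0,
        "unassigned_fraction": 1.0 - (n_assigned / n_total) if n_total else 0.0,
        "founder_shares": (shares / n_assigned).tolist() if n_assigned else shares.tolist(),
    }
    if truth is not None:
        out["accuracy"] = n_correct / n_total if n_total else 0.0
        out["accuracy_assigned"] = n_correct / n_assigned if n_assigned else 0.0
    return out
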