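"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles (explicit
enumeration, explicit design matrices, plain loops) and shares no code
path with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- founder-origin posterior by exhaustive path enumeration ----------------


def posterior_by_enumeration(
    line_alleles: np.ndarray,
    founder_alleles: np.ndarray,
    dist_cM: np.ndarray,
    error_rate: float,
    n_meioses: float,
    n_states: int = 8,
) -> np.ndarray:
    """Posterior over founders at each marker, summing over all state paths.

    Builds the full joint probability tensor over the n_states**m founder
    paths and marginalizes; feasible for m <= 4 markers.
    """
    m = len(line_alleles)
    em = np.ones((m, n_states))
    for t in range(m):
        for s in range(n_states):
            la, fa = line_alleles[t], founder_alleles[s, t]
            if la < 0 or fa < 0:
                em[t, s] = 1.0
            else:
                em[t, s] = 1.0 - error_rate if la == fa else error_rate
    trans = []
    for d in dist_cM:
        j = 1.0 - np.exp(-n_meioses * d / 100.0)
        T = np.full((n_states, n_states), j / n_states)
        T[np.diag_indices(n_states)] += 1.0 - j
        trans.append(T)
    post = np.zeros((m, n_states))
    total = 0.0
    for path in itertools.product(range(n_states), repeat=m):
        w = em[0, path[0]] / n_states
        for t in range(1, m):
            w *= trans[t - 1][path[t - 1], path[t]] * em[t, path[t]]
        total += w
        for t in range(m):
            post[t, path[t]] += w
    return post / total


# -- sequential (Type I) ANOVA by explicit design matrices ------------------


def _dummies(labels) -> np.ndarray:
    levels = sorted(set(labels))
    return np.column_stack([[1.0 if l == lv else 0.0 for l in labels] for lv in levels])


def type1_anova(y, genotype, treatment) -> dict:
    """Sequential SSq for G, T, GxT via nested least-squares comparisons."""
    y = np.asarray(y, dtype=float)
    n = len(y)

    def rss(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return float(np.sum((y - x @ beta) ** 2))

    ones = np.ones((n, 1))
    xg = np.hstack([ones, _dummies(genotype)])
    xt = np.hstack([xg, _dummies(treatment)])
    inter = [f"{g}||{t}" for g, t in zip(genotype, treatment)]
    xf = np.hstack([xt, _dummies(inter)])
    r0, rg, rt, rf = rss(ones), rss(xg), rss(xt), rss(xf)
    return {"G": r0 - rg, "T": rg - rt, "GxT": rt - rf, "residual": rf}


def variance_components(values, genotypes, r) -> tuple[float, float]:
    """One-way mean squares -> (sigma2_g, sigma2_e), truncated at zero."""
    values = np.asarray(values, dtype=float)
    groups = sorted(set(genotypes))
    grand = values.mean()
    ss_g = sum(
        len([v for v, g in zip(values, genotypes) if g == grp])
        * (np.mean([v for v, g in zip(values, genotypes) if g == grp]) - grand) ** 2
        for grp in groups
    )
    ss_e = sum(
        (v - np.mean([w for w, h in zip(values, genotypes) if h == g])) ** 2
        for v, g in zip(values, genotypes)
    )
    ms_g = ss_g / (len(groups) - 1)
    ms_e = ss_e / (len(values) - len(groups))
    return max((ms_g - ms_e) / r, 0.0), ms_e


# -- scan oracle: normal equations ------------------------------------------


def lod_by_normal_equations(probs: np.ndarray, y: np.ndarray) -> float:
    """LOD at one position from the explicit normal-equations solve."""
    n = len(y)
    x = np.column_stack([np.ones(n), probs[:, :7]])
    xtx = x.T @ x
    beta = np.linalg.pinv(xtx) @ x.T @ y
    rss = float(np.sum((y - x @ beta) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else max(1.0 - rss / tss, 0.0)
    return n / 2.0 * np.log10(1.0 / (1.0 - min(r2, 1 - 1e-15)))


# -- interval content by linear scan ----------------------------------------


def genes_in_interval(genes_df, chrom, low, high) -> set:
    out = set()
    for row in genes_df.itertuples(index=False):
        if row.chrom == chrom and row.start < high and row.end > low:
            out.add(row.gene)
    return out


def variants_in_interval(var_df, chrom, low, high) -> set:
    out = set()
    for row in var_df.itertuples(index=False):
        if row.chrom == chrom and low <= row.pos < high:
            out.add((row.chrom, row.pos))
    return out


# -- candidate filter: per-polymorphism check -------------------------------


def passes_filter(alleles_by_founder: dict, group_a, group_b) -> bool:
    a_vals = [alleles_by_founder[f] for f in group_a]
    b_vals = [alleles_by_founder[f] for f in group_b]
    if any(v < 0 for v in a_vals + b_vals):
        return False
    return len(set(a_vals)) == 1 and len(set(b_vals)) == 1 and a_vals[0] != b_vals[0]


# -- best bipartition by between/within variance ----------------------------


def best_bipartition(effects) -> frozenset:
    """Exhaustive search over bipartitions minimizing within-group variance."""
    e = np.asarray(effects, dtype=float)
    n = len(e)
    best, best_score = None, np.inf
    for mask in range(1, 2 ** n - 1):
        a = [i for i in range(n) if mask >> i & 1]
        b = [i for i in range(n) if not mask >> i & 1]
        score = np.var(e[a]) * len(a) + np.var(e[b]) * len(b)
        if score < best_score - 1e-12:
            best_score = score
            best = frozenset(a)
    other = frozenset(range(n)) - best
    return best if min(best) < min(other) else other


# -- overlap components by breadth-first search -----------------------------


def overlap_component_count(intervals: list[tuple[float, float]]) -> int:
    n = len(intervals)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a[0] <= b[1] and b[0] <= a[1]:
                adj[i].append(j)
                adj[j].append(i)
    seen = [False] * n
    comps = 0
    for i in range(n):
        if seen[i]:
            continue
        comps += 1
        stack = [i]
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            stack.extend(adj[v])
    return comps


# -- minimal independent pedigree Monte-Carlo -------------------------------


def pedigree_breakpoints_mc(
    length_cM: float, n_selfing: int, n_lines: int, rng
) -> float:
    """Mean ancestral breakpoints per line for the funnel + SSD design.

    Plain-Python re-simulation of the mating design: haplotypes are lists
    of (end_cM, founder) segments, gametes recombine with Poisson
    crossovers and a random start haplotype.
    """

    def extract(h, a, b):
        segs = []
        start = 0.0
        for end, f in h:
            if end > a and start < b:
                segs.append((min(end, b), f))
            start = end
            if start >= b:
                break
        return segs

    def gamete(h1, h2):
        nx = rng.poisson(length_cM / 100.0)
        cur = int(rng.integers(2))
        if nx == 0:
            return list((h1, h2)[cur])
        cuts = sorted(rng.uniform(0, length_cM, nx).tolist()) + [length_cM]
        haps = (h1, h2)
        out = []
        prev = 0.0
        for cut in cuts:
            if cut > prev:
                out.extend(extract(haps[cur], prev, cut))
            prev = cut
            cur ^= 1
        # merge adjacent identical founders
        merged = []
        for end, f in out:
            if merged and merged[-1][1] == f:
                merged[-1] = (end, f)
            else:
                merged.append((end, f))
        merged[-1] = (length_cM, merged[-1][1])
        return merged

    counts = []
    for _ in range(n_lines):
        order = rng.permutation(8)
        h = [[(length_cM, int(f))] for f in order]
        f1 = [(h[0], h[1]), (h[2], h[3]), (h[4], h[5]), (h[6], h[7])]
        fw1 = (gamete(*f1[0]), gamete(*f1[1]))
        fw2 = (gamete(*f1[2]), gamete(*f1[3]))
        ind = (gamete(*fw1), gamete(*fw2))
        for _ in range(n_selfing):
            ind = (gamete(*ind), gamete(*ind))
        final = ind[int(rng.integers(2))]
        counts.append(len(final) - 1)
    return float(np.mean(counts))
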