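import numpy as np
import pandas as pd
import pytest

import magicqtl as mq
from magicqtl.candidates import CandidateError, GroupingParseError

from _oracles import (
    best_bipartition,
    genes_in_interval,
    passes_filter,
    variants_in_interval,
)

F = mq.FOUNDER_NAMES


def make_tables(gene_rows, var_rows):
    genes = mq.GeneSet(table=pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "annotation"]))
    variants = mq.VariantTable(table=pd.DataFrame(
        var_rows, columns=["chrom", "pos", *F, "gene", "effect"]))
    return genes, variants


class TestIntervalContent:
    def test_empty_interval(self):
        genes, variants = make_tables(
            [("g1", "c1", 100, 200, "")],
            [("c1", 150, *[0] * 8, "g1", "MODIFIER")],
        )
        g, v = mq.interval_content((150, 150), "c1", variants, genes)
        assert len(g) == 0 and len(v) == 0

    def test_overlap_not_containment(self):
        genes, variants = make_tables(
            [("g1", "c1", 100, 200, "")],
            [("c1", 155, *[0] * 8, "g1", "MODIFIER")],
        )
        g, v = mq.interval_content((150, 160), "c1", variants, genes)
        assert list(g["gene"]) == ["g1"]
        assert len(v) == 1

    def test_half_open_convention(self):
        genes, variants = make_tables(
            [("g1", "c1", 100, 200, "")],
            [("c1", 100, *[0] * 8, "g1", "LOW"), ("c1", 200, *[0] * 8, "g1", "LOW")],
        )
        _, v = mq.interval_content((100, 200), "c1", variants, genes)
        assert list(v["pos"]) == [100]

    def test_unknown_chromosome_errors(self):
        genes, variants = make_tables(
            [("g1", "c1", 100, 200, "")], [("c1", 150, *[0] * 8, "g1", "LOW")]
        )
        with pytest.raises(CandidateError, match="unknown chromosome"):
            mq.interval_content((0, 10), "c9", variants, genes)

    def test_random_intervals_match_linear_scan(self, rng):
        gene_rows, var_rows = [], []
        for i in range(200):
            start = int(rng.integers(0, 10**6))
            gene_rows.append((f"g{i}", "c1", start, start + int(rng.integers(1, 5000)), ""))
        for i in range(2000):
            var_rows.append(("c1", int(rng.integers(0, 10**6)), *[0] * 8, f"g{i % 200}", "LOW"))
        var_rows.sort(key=lambda r: r[1])
        genes, variants = make_tables(gene_rows, var_rows)
        for _ in range(50):
            lo = int(rng.integers(0, 10**6))
            hi = lo + int(rng.integers(0, 10**5))
            g, v = mq.interval_content((lo, hi), "c1", variants, genes)
            assert set(g["gene"]) == genes_in_interval(genes.table, "c1", lo, hi)
            assert {(r.chrom, r.pos) for r in v.itertuples()} == variants_in_interval(
                variants.table, "c1", lo, hi
            )


class TestParseGrouping:
    def test_one_versus_all(self):
        g = mq.parse_grouping("Cerv # all", F)
        assert g.group_a == {"Cervil"}
        assert g.group_b == set(F) - {"Cervil"}
        assert not g.ungrouped

    def test_two_versus_two(self):
        g = mq.parse_grouping("(Cerv = Stup) # (LA14 = LA0)", F)
        assert g.group_a == {"Cervil", "Stupicke"}
        assert g.group_b == {"LA1420", "LA0147"}
        assert len(g.ungrouped) == 4

    def test_overlapping_groups_rejected(self):
        with pytest.raises(GroupingParseError):
            mq.parse_grouping("Cerv # Cerv", F)

    def test_unknown_name_positions(self):
        with pytest.raises(GroupingParseError, match="unknown founder"):
            mq.parse_grouping("Cerv # Nothing", F)

    def test_empty_side_rejected(self):
        with pytest.raises(GroupingParseError, match="empty"):
            mq.parse_grouping("Cerv # ", F)

    def test_ambiguous_prefix_rejected(self):
        with pytest.raises(GroupingParseError, match="ambiguous"):
            mq.parse_grouping("L # Cerv", F)  # LA1420 / LA0147 / Levovil

    def test_pattern_round_trip(self):
        g = mq.parse_grouping("(Cervil = Plovdiv) # Criollo", F)
        assert mq.parse_grouping(g.pattern(), F) == g


class TestSuggestGrouping:
    def test_single_divergent_founder(self):
        effects = (4.3, -0.65, -0.28, -2.17, -0.82, -0.44, -0.33, 0.38)
        g, note = mq.suggest_grouping(effects, F)
        assert g is not None
        assert g.group_a == {"Cervil"}
        assert g.group_b == set(F) - {"Cervil"}
        assert "suggestion" in note

    def test_all_equal_no_grouping(self):
        g, note = mq.suggest_grouping((0.0,) * 8, F)
        assert g is None
        assert "no divergence" in note

    def test_balanced_split_matches_bipartition_oracle(self):
        effects = (1.0, 1.1, 0.9, 1.05, -1.0, -0.95, -1.1, -1.02)
        g, _ = mq.suggest_grouping(effects, F)
        assert g is not None
        idx_a = frozenset(F.index(f) for f in g.group_a)
        idx_b = frozenset(F.index(f) for f in g.group_b)
        oracle = best_bipartition(effects)
        assert oracle in (idx_a, idx_b)
        assert not g.ungrouped


class TestFilterCandidates:
    def grouping(self, pattern="Cerv # all"):
        return mq.parse_grouping(pattern, F)

    def test_private_allele_kept(self):
        genes, variants = make_tables(
            [("g1", "c1", 0, 1000, "")],
            [("c1", 10, 1, 0, 0, 0, 0, 0, 0, 0, "g1", "HIGH")],
        )
        kept_g, kept_v = mq.filter_candidates(variants.table, genes.table, self.grouping())
        assert len(kept_v) == 1
        assert list(kept_g["gene"]) == ["g1"]

    def test_non_uniform_group_b_discarded(self):
        genes, variants = make_tables(
            [("g1", "c1", 0, 1000, "")],
            [("c1", 10, 1, 1, 0, 0, 0, 0, 0, 0, "g1", "HIGH")],
        )
        _, kept_v = mq.filter_candidates(variants.table, genes.table, self.grouping())
        assert len(kept_v) == 0

    def test_missing_in_grouped_founder_fails_conservatively(self):
        genes, variants = make_tables(
            [("g1", "c1", 0, 1000, "")],
            [("c1", 10, 1, -1, 0, 0, 0, 0, 0, 0, "g1", "HIGH")],
        )
        _, strict = mq.filter_candidates(variants.table, genes.table, self.grouping())
        assert len(strict) == 0
        _, permissive = mq.filter_candidates(
            variants.table, genes.table, self.grouping(), permissive_missing=True
        )
        assert len(permissive) == 1

    def test_ungrouped_founders_unconstrained(self):
        g = self.grouping("(Cerv = Stup) # (LA14 = LA0)")
        # Cervil/Stupicke = 1, LA1420/LA0147 = 0, others arbitrary
        row = {"Cervil": 1, "Stupicke": 1, "LA1420": 0, "LA0147": 0,
               "Levovil": 1, "Criollo": 0, "Plovdiv": 1, "Ferum": 0}
        genes, variants = make_tables(
            [("g1", "c1", 0, 1000, "")],
            [("c1", 10, *[row[f] for f in F], "g1", "LOW")],
        )
        _, kept = mq.filter_candidates(variants.table, genes.table, g)
        assert len(kept) == 1

    def test_random_fixtures_match_per_polymorphism_oracle(self, rng):
        for _ in range(20):
            n_var = 60
            var_rows = []
            for i in range(n_var):
                alleles = rng.integers(0, 2, 8).tolist()
                if rng.random() < 0.15:
                    alleles[int(rng.integers(8))] = -1
                var_rows.append(("c1", i * 10, *alleles, f"g{i % 7}", "LOW"))
            gene_rows = [(f"g{i}", "c1", i * 100, i * 100 + 50, "") for i in range(7)]
            genes, variants = make_tables(gene_rows, var_rows)
            sizes = [1, 2, 3]
            a_n, b_n = int(rng.choice(sizes)), int(rng.choice(sizes))
            perm = rng.permutation(8)
            ga = frozenset(F[i] for i in perm[:a_n])
            gb = frozenset(F[i] for i in perm[a_n:a_n + b_n])
            grouping = mq.FounderGrouping(group_a=ga, group_b=gb, founders=F)
            _, kept = mq.filter_candidates(variants.table, genes.table, grouping)
            expected = {
                row[1]
                for row in var_rows
                if passes_filter(dict(zip(F, row[2:10])), ga, gb)
            }
            assert set(kept["pos"]) == expected

    def test_monotone_in_added_constraints(self):
        # moving a founder from ungrouped into a group never adds candidates
        rng = np.random.default_rng(4)
        var_rows = []
        for i in range(200):
            var_rows.append(("c1", i * 5, *rng.integers(0, 2, 8).tolist(), "g0", "LOW"))
        gene_rows = [("g0", "c1", 0, 10_000, "")]
        genes, variants = make_tables(gene_rows, var_rows)
        loose = mq.FounderGrouping(group_a=frozenset({F[0]}),
                                   group_b=frozenset({F[1]}), founders=F)
        tight = mq.FounderGrouping(group_a=frozenset({F[0], F[2]}),
                                   group_b=frozenset({F[1], F[3]}), founders=F)
        _, kept_loose = mq.filter_candidates(variants.table, genes.table, loose)
        _, kept_tight = mq.filter_candidates(variants.table, genes.table, tight)
        assert set(kept_tight["pos"]) <= set(kept_loose["pos"])


class TestCgReport:
    def make_record(self, lo, hi):
        return mq.QtlRecord(
            trait="Firm", context="Exp2:salt", chrom="c1",
            peak_cM=(lo + hi) / 2e5, peak_lod=6.0,
            ci_low_cM=lo / 1e5, ci_high_cM=hi / 1e5,
            ci_low_bp=lo, ci_high_bp=hi,
            effects=(4.3, -0.65, -0.28, -2.17, -0.82, -0.44, -0.33, 0.38),
            pve=25.0, n=200,
        )

    def test_planted_candidates_counted_exactly(self, rng):
        grouping = mq.parse_grouping("Cerv # all", F)
        var_rows = []
        planted = []
        pos = 0
        for i in range(500):
            pos += int(rng.integers(10, 50))
            if i % 50 == 0:  # plant 10 group-consistent polymorphisms
                alleles = [1, 0, 0, 0, 0, 0, 0, 0]
                planted.append(pos)
            else:
                alleles = rng.integers(0, 2, 8).tolist()
                if len(set(alleles[1:])) == 1 and alleles[0] != alleles[1]:
                    alleles[1] = 1 - alleles[1]  # keep the plant set exact
            var_rows.append(("c1", pos, *alleles, f"g{i % 20}", "MODIFIER"))
        gene_rows = [(f"g{i}", "c1", i * 1000, i * 1000 + 400, f"ann {i}")
                     for i in range(20)]
        genes, variants = make_tables(gene_rows, var_rows)
        rec = self.make_record(0, pos + 100)
        summary, listing = mq.cg_report(rec, grouping, variants, genes)
        assert summary["n_polymorphisms"] == 500
        assert summary["n_candidate_polymorphisms"] == len(planted)
        assert sorted(listing["pos"]) == planted
        assert summary["filter"].startswith("Cervil # (")
        assert summary["n_candidate_genes"] == len(set(listing["gene"]))

    def test_empty_interval_zero_counts(self):
        genes, variants = make_tables(
            [("g1", "c1", 5000, 6000, "")],
            [("c1", 5500, *[0] * 8, "g1", "LOW")],
        )
        rec = self.make_record(0, 100)
        grouping = mq.parse_grouping("Cerv # all", F)
        summary, listing = mq.cg_report(rec, grouping, variants, genes)
        assert summary["n_candidate_genes"] == 0
        assert summary["n_candidate_polymorphisms"] == 0
        assert listing.empty

    def test_filter_matching_nothing_keeps_totals(self):
        var_rows = [("c1", 10 + i, *[i % 2] * 8, "g1", "LOW") for i in range(5)]
        genes, variants = make_tables([("g1", "c1", 0, 100, "")], var_rows)
        rec = self.make_record(0, 100)
        grouping = mq.parse_grouping("Cerv # all", F)
        summary, _ = mq.cg_report(rec, grouping, variants, genes)
        assert summary["n_polymorphisms"] == 5
        assert summary["n_candidate_polymorphisms"] == 0
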