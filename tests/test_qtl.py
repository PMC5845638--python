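import numpy as np
import pandas as pd
import pytest

import magicqtl as mq
from magicqtl.qtl import QtlError

from _oracles import lod_by_normal_equations, overlap_component_count


def truth_grid(mosaic, gmap, step=2.0):
    """One-hot founder 'probabilities' built directly from the truth mosaic."""
    positions, is_marker, probs = {}, {}, {}
    for chrom in gmap.chromosomes:
        marker_cm = gmap.chrom_table(chrom)["cM"].to_numpy(float)
        lattice = np.arange(0.0, gmap.chrom_length_cM(chrom) + 1e-9, step)
        pos = np.unique(np.concatenate([marker_cm, lattice]))
        p = np.zeros((len(mosaic.lines), len(pos), 8))
        for li, line in enumerate(mosaic.lines):
            f = mosaic.founder_at(line, chrom, pos)
            p[li, np.arange(len(pos)), f] = 1.0
        positions[chrom] = pos
        is_marker[chrom] = np.isin(pos, marker_cm)
        probs[chrom] = p
    return mq.FounderProbabilityGrid(
        lines=tuple(mosaic.lines), founders=mq.FOUNDER_NAMES,
        chromosomes=gmap.chromosomes, positions=positions,
        is_marker=is_marker, probs=probs,
    )


@pytest.fixture(scope="module")
def scan_setup(small_population):
    pop = small_population
    grid = truth_grid(pop["mosaic"], pop["map"])
    q = mq.QtlSpec(chrom="chr02", position_cM=40.0,
                   effects=(3.0, 3.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0))
    arch = mq.TraitArchitecture(trait="t", qtls=(q,), target_h2=0.6, n_replicates=2)
    df = mq.simulate_phenotypes(pop["mosaic"], pop["map"], arch,
                                treatments=["control"], seed=99)
    y = mq.PhenotypeTable(data=df).line_means("t", "Exp1", "control")
    return {"grid": grid, "y": y, "qtl_cm": 40.0, "map": pop["map"]}


class TestScan:
    def test_constant_phenotype_gives_zero_lod(self, scan_setup):
        y = pd.Series(1.0, index=scan_setup["y"].index)
        with pytest.warns(UserWarning, match="constant"):
            profile = mq.scan(scan_setup["grid"], y, "t", "ctx")
        assert (profile.table["lod"] == 0.0).all()

    def test_self_regression_peaks_at_position(self, scan_setup):
        # phenotype equal to founder-1 probability at a position: that
        # position carries the profile maximum
        grid = scan_setup["grid"]
        pos = grid.positions["chr01"]
        j = len(pos) // 2
        y = pd.Series(grid.probs["chr01"][:, j, 0], index=list(grid.lines))
        profile = mq.scan(grid, y, "t", "ctx")
        sub = profile.chrom_profile("chr01")
        best = sub.loc[sub["lod"].idxmax(), "cM"]
        assert best == pytest.approx(pos[j])

    def test_lod_matches_normal_equations_oracle(self, scan_setup):
        grid, y = scan_setup["grid"], scan_setup["y"]
        profile = mq.scan(grid, y, "t", "ctx")
        yv = y[list(grid.lines)].to_numpy(float)
        for chrom in ("chr01", "chr02"):
            sub = profile.chrom_profile(chrom)
            for j in range(0, len(sub), 7):
                p = grid.probs[chrom][:, j, :]
                expected = lod_by_normal_equations(p, yv)
                assert sub["lod"].iloc[j] == pytest.approx(expected, abs=1e-8)

    def test_lod_r2_identity(self, scan_setup):
        profile = mq.scan(scan_setup["grid"], scan_setup["y"], "t", "ctx")
        t = profile.table
        n = t["n"].iloc[0]
        expected = n / 2.0 * np.log10(1.0 / (1.0 - t["r2"]))
        np.testing.assert_allclose(t["lod"], expected, atol=1e-10)

    def test_too_few_lines_errors(self, scan_setup):
        y = scan_setup["y"].iloc[:5]
        with pytest.raises(QtlError, match="usable lines"):
            mq.scan(scan_setup["grid"], y, "t", "ctx")


class TestCallPeaks:
    def make_profile(self, cm, lod, trait="t", context="c", chrom="chr01"):
        t = pd.DataFrame({"chrom": chrom, "cM": cm, "lod": lod,
                          "r2": 1 - 10 ** (-2 * np.asarray(lod) / 20), "n": 20})
        return mq.LodProfile(trait=trait, context=context, table=t)

    def test_below_threshold_yields_nothing(self, scan_setup):
        profile = self.make_profile(np.arange(0, 100, 10.0), [2.9] * 10)
        recs = mq.call_peaks(profile, scan_setup["grid"], scan_setup["y"],
                             scan_setup["map"])
        assert recs == []

    def test_triangular_peak_interval_geometry(self, scan_setup):
        cm = np.array([20.0, 30.0, 40.0, 50.0, 60.0])
        lod = np.array([1.0, 5.0, 6.0, 5.0, 1.0])
        profile = self.make_profile(cm, lod)
        recs = mq.call_peaks(profile, scan_setup["grid"], scan_setup["y"],
                             scan_setup["map"])
        assert len(recs) == 1
        rec = recs[0]
        assert rec.peak_cM == 40.0
        assert (rec.ci_low_cM, rec.ci_high_cM) == (30.0, 50.0)

    def test_planted_qtl_recovered_with_ci_coverage(self, scan_setup):
        grid, y = scan_setup["grid"], scan_setup["y"]
        profile = mq.scan(grid, y, "t", "ctx")
        recs = mq.call_peaks(profile, grid, y, scan_setup["map"])
        hits = [r for r in recs if r.chrom == "chr02"
                and r.ci_low_cM <= scan_setup["qtl_cm"] <= r.ci_high_cM]
        assert hits, "planted QTL not covered by any called interval"
        rec = max(hits, key=lambda r: r.peak_lod)
        assert rec.peak_lod >= 3.0
        assert rec.pve > 10.0
        # founders 1+2 carry the high allele: their centered effects top the list
        top2 = np.argsort(rec.effects_centered)[-2:]
        assert set(top2) == {0, 1}

    def test_centered_effects_sum_to_zero(self, scan_setup):
        profile = mq.scan(scan_setup["grid"], scan_setup["y"], "t", "ctx")
        for rec in mq.call_peaks(profile, scan_setup["grid"], scan_setup["y"],
                                 scan_setup["map"]):
            assert sum(rec.effects_centered) == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_peaks_merge_keeping_higher(self, scan_setup):
        cm = np.arange(0.0, 110.0, 10.0)
        lod = np.array([0, 4.0, 3.5, 4.5, 0.5, 0, 0, 0, 0, 0, 0.0])
        profile = self.make_profile(cm, lod)
        recs = mq.call_peaks(profile, scan_setup["grid"], scan_setup["y"],
                             scan_setup["map"])
        assert len(recs) == 1
        assert recs[0].peak_cM == 30.0


class TestClassification:
    def rec(self, trait, context, chrom, lo, hi, lod=5.0):
        return mq.QtlRecord(
            trait=trait, context=context, chrom=chrom,
            peak_cM=(lo + hi) / 2, peak_lod=lod,
            ci_low_cM=lo, ci_high_cM=hi, ci_low_bp=int(lo * 1e5),
            ci_high_bp=int(hi * 1e5), effects=(0.0,) * 8, pve=10.0, n=100,
        )

    def test_overlapping_treatments_constitutive(self):
        recs = [self.rec("FW", "Exp1:control", "c1", 10, 30),
                self.rec("FW", "Exp1:stress", "c1", 25, 45)]
        cl = mq.classify_qtl(recs)
        assert cl.labels == ("constitutive",)
        assert len(cl.groups[0]) == 2

    def test_disjoint_intervals_stay_separate(self):
        recs = [self.rec("FW", "Exp1:control", "c1", 10, 20),
                self.rec("FW", "Exp1:stress", "c1", 30, 40)]
        cl = mq.classify_qtl(recs)
        assert sorted(cl.labels) == ["treatment-specific", "treatment-specific"]

    def test_different_traits_never_merge(self):
        recs = [self.rec("FW", "Exp1:control", "c1", 10, 30),
                self.rec("SSC", "Exp1:stress", "c1", 20, 40)]
        cl = mq.classify_qtl(recs)
        assert len(cl.groups) == 2

    def test_plasticity_labels(self):
        recs = [
            self.rec("FW", "PLASTICITY:Exp1", "c1", 10, 30),
            self.rec("FW", "PLASTICITY:Exp1", "c2", 10, 30),
            self.rec("FW", "Exp1:control", "c2", 20, 40),
        ]
        cl = mq.classify_qtl(recs)
        by_chrom = {g[0].chrom: lab for g, lab in zip(cl.groups, cl.labels)}
        assert by_chrom["c1"] == "interactive-specific"
        assert by_chrom["c2"] == "interactive-shared"

    def test_component_count_matches_bfs_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 12))
            intervals = []
            recs = []
            for i in range(n):
                lo = float(rng.uniform(0, 80))
                hi = lo + float(rng.uniform(1, 25))
                intervals.append((lo, hi))
                recs.append(self.rec("t", f"Exp1:c{i}", "c1", lo, hi))
            cl = mq.classify_qtl(recs)
            assert len(cl.groups) == overlap_component_count(intervals)

    def test_venn_counts_total(self):
        recs = [self.rec("FW", "Exp1:control", "c1", 10, 30),
                self.rec("FW", "Exp1:stress", "c1", 25, 45),
                self.rec("SSC", "Exp1:stress", "c2", 5, 15)]
        cl = mq.classify_qtl(recs)
        venn = cl.venn_counts()
        assert venn["n_qtl"].sum() == len(cl.groups)


class TestJointPve:
    def test_single_record_equals_own_pve(self, scan_setup):
        grid, y = scan_setup["grid"], scan_setup["y"]
        profile = mq.scan(grid, y, "t", "ctx")
        recs = mq.call_peaks(profile, grid, y, scan_setup["map"])
        rec = max(recs, key=lambda r: r.peak_lod)
        jp = mq.joint_pve([rec], grid, y)
        assert jp == pytest.approx(rec.pve, abs=1e-8)

    def test_duplicated_record_idempotent(self, scan_setup):
        grid, y = scan_setup["grid"], scan_setup["y"]
        profile = mq.scan(grid, y, "t", "ctx")
        rec = max(mq.call_peaks(profile, grid, y, scan_setup["map"]),
                  key=lambda r: r.peak_lod)
        with pytest.warns(UserWarning, match="collinear"):
            jp2 = mq.joint_pve([rec, rec], grid, y)
        assert jp2 == pytest.approx(mq.joint_pve([rec], grid, y), abs=1e-8)

    def test_two_orthogonal_qtl_pves_add(self, small_population):
        pop = small_population
        gmap = mq.default_map(n_markers=40, n_chromosomes=2, total_cM=200, seed=31)
        fg, _, _ = mq.simulate_founders(gmap, seed=32, n_genes_per_chrom=2,
                                        n_variants_per_gene_region=1)
        _, mosaic = mq.simulate_magic_lines(fg, gmap, n_lines=400, seed=33)
        grid = truth_grid(mosaic, gmap)
        qa = mq.QtlSpec(chrom="chr01", position_cM=50.0,
                        effects=(2.0, 2.0, 2.0, 2.0, -2.0, -2.0, -2.0, -2.0))
        qb = mq.QtlSpec(chrom="chr02", position_cM=50.0,
                        effects=(2.0, -2.0, 2.0, -2.0, 2.0, -2.0, 2.0, -2.0))
        arch = mq.TraitArchitecture(trait="t2", qtls=(qa, qb), target_h2=0.5,
                                    n_replicates=1)
        df = mq.simulate_phenotypes(mosaic, gmap, arch, treatments=["c"], seed=5)
        y = mq.PhenotypeTable(data=df).line_means("t2", "Exp1", "c")
        profile = mq.scan(grid, y, "t2", "c")
        recs = mq.call_peaks(profile, grid, y, gmap)
        assert len(recs) >= 2
        best = sorted(recs, key=lambda r: -r.peak_lod)[:2]
        jp = mq.joint_pve(best, grid, y)
        assert jp == pytest.approx(best[0].pve + best[1].pve, abs=6.0)
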