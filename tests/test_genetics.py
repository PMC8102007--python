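"""QTL scans, permutation thresholds, support intervals, epistasis, F_ST."""

import numpy as np
import pandas as pd
import pytest

import stripespot as ss
from stripespot.genetics import _lod_columns

MAP = ss.make_marker_map(n_chromosomes=5, markers_per_chromosome=10)


def planted_family(pct_var=15.0, n=158, seed=0, marker="chr3_m4", origin="hybrid"):
    """Additive QTL built to explain the stated percent of phenotypic variance."""
    a = 1.0
    frac = pct_var / 100.0
    sd = np.sqrt((a**2 / 4.0) * (1.0 - frac) / frac)
    qtl = ss.QTLModel(residual_sd=sd, loci=[ss.QTLLocus(marker, origin, a)])
    return ss.gen_backcross(n, MAP, qtl, seed=seed)


class TestLodScan:
    def test_constant_phenotype_all_zero_with_flag(self):
        fam = planted_family(seed=1)
        fam.phenotypes["trait"] = 1.0
        scan = ss.lod_scan(fam, "trait")
        assert scan.constant_phenotype
        assert np.all(scan.table["lod"] == 0.0)

    def test_degenerate_fit_capped_and_flagged(self):
        qtl = ss.QTLModel(residual_sd=0.0, loci=[ss.QTLLocus("chr2_m5", "hybrid", 1)])
        fam = ss.gen_backcross(100, MAP, qtl, seed=2)
        scan = ss.lod_scan(fam, "trait")
        row = scan.table[scan.table["marker"] == "chr2_m5"].iloc[0]
        assert row["lod"] == 300.0 and row["degenerate"]
        off = scan.table[scan.table["chrom"] != 2]
        assert np.all(np.isfinite(off["lod"])) and np.all(~off["degenerate"])

    def test_matches_per_marker_least_squares_oracle(self):
        fam = planted_family(seed=3)
        scan = ss.lod_scan(fam, "trait")
        y = fam.phenotypes["trait"].to_numpy()
        n = len(y)
        rss0 = np.sum((y - y.mean()) ** 2)
        for j in [0, 17, 34, 49]:
            x = fam.genotypes["hybrid"][:, j].astype(float)
            A = np.column_stack([np.ones(n), x])
            rss1 = np.sum((y - A @ np.linalg.lstsq(A, y, rcond=None)[0]) ** 2)
            lod_o = (n / 2.0) * np.log10(rss0 / rss1)
            assert scan.table["lod"].iloc[j] == pytest.approx(lod_o, abs=1e-8)

    def test_expected_lod_at_planted_qtl(self):
        """Mean observed peak LOD tracks the closed form (n/2)log10(1/(1-r2))."""
        n, frac = 158, 0.15
        expected = (n / 2.0) * np.log10(1.0 / (1.0 - frac))
        lods = [ss.lod_scan(planted_family(seed=s), "trait").lod("chr3_m4")
                for s in range(50)]
        assert abs(np.mean(lods) - expected) < 2.0

    def test_small_family_rejected(self):
        fam = planted_family(n=10, seed=4)
        with pytest.raises(ValueError):
            ss.lod_scan(fam, "trait")

    def test_missing_genotypes_imputed_from_flanks(self):
        qtl = ss.QTLModel(residual_sd=0.5, loci=[ss.QTLLocus("chr1_m5", "hybrid", 1)])
        fam = ss.gen_backcross(200, MAP, qtl, seed=5, missing_rate=0.2)
        X = ss.expected_genotypes(fam, "hybrid")
        assert np.all((X >= 0) & (X <= 1))
        miss = fam.genotypes["hybrid"] == -1
        assert np.all(X[~miss] == fam.genotypes["hybrid"][~miss])
        # imputation recovers signal: scan still peaks on the right chromosome
        scan = ss.lod_scan(fam, "trait")
        peak = scan.table.loc[scan.table["lod"].idxmax()]
        assert peak["chrom"] == 1

    def test_drop_missing_mode_excludes_markers(self):
        fam = ss.gen_backcross(100, MAP, ss.QTLModel(), seed=6, missing_rate=0.05)
        scan = ss.lod_scan(fam, "trait", drop_missing=True)
        n_clean = np.sum(~np.any(fam.genotypes["hybrid"] < 0, axis=0))
        assert len(scan.table) == n_clean


class TestPermutationThreshold:
    def test_alpha_one_is_minimum_of_maxima(self):
        fam = planted_family(seed=7)
        rng_thr = ss.permutation_threshold(fam, "trait", n_perm=100, alpha=1.0,
                                           seed=8)
        y = fam.phenotypes["trait"].to_numpy()
        rng = np.random.default_rng(8)
        X = ss.expected_genotypes(fam, "hybrid")
        maxima = []
        for _ in range(100):
            maxima.append(_lod_columns(X, y[rng.permutation(len(y))][:, None]).max())
        assert rng_thr == pytest.approx(min(maxima), abs=1e-12)

    def test_fixed_seed_reproducible(self):
        fam = planted_family(seed=9)
        t1 = ss.permutation_threshold(fam, "trait", n_perm=150, seed=10)
        t2 = ss.permutation_threshold(fam, "trait", n_perm=150, seed=10)
        assert t1 == t2

    def test_minimum_permutations_enforced(self):
        fam = planted_family(seed=11)
        with pytest.raises(ValueError):
            ss.permutation_threshold(fam, "trait", n_perm=50)


class TestLodInterval:
    def scan_with_profile(self, lods):
        table = pd.DataFrame({
            "marker": [f"chr1_m{j}" for j in range(len(lods))],
            "chrom": 1, "pos": np.arange(len(lods)) * 10.0,
            "lod": lods, "degenerate": False,
        })
        return ss.QTLScanResult(table, "trait", "hybrid")

    def test_unimodal_profile_brackets_drop(self):
        scan = self.scan_with_profile([0.5, 1.0, 3.0, 5.0, 3.8, 2.0, 0.5])
        lo, hi = ss.lod_interval(scan, "chr1_m3")
        # contiguous run >= 3.5: markers 3..4; extended one beyond each side
        assert (lo, hi) == ("chr1_m2", "chr1_m5")

    def test_single_marker_chromosome(self):
        table = pd.DataFrame({"marker": ["only"], "chrom": [7], "pos": [0.0],
                              "lod": [4.0], "degenerate": [False]})
        scan = ss.QTLScanResult(table, "trait", "hybrid")
        assert ss.lod_interval(scan, "only") == ("only", "only")

    def test_peak_at_chromosome_end_one_sided(self):
        scan = self.scan_with_profile([6.0, 4.0, 1.0, 0.5])
        lo, hi = ss.lod_interval(scan, "chr1_m0")
        # run above peak-1.5 is the peak alone; one conservative marker beyond
        assert lo == "chr1_m0" and hi == "chr1_m1"

    def test_interval_covers_true_locus(self):
        hits = 0
        detections = 0
        for s in range(30):
            fam = planted_family(seed=100 + s)
            scan = ss.lod_scan(fam, "trait")
            peak = scan.table.loc[scan.table["lod"].idxmax()]
            if peak["chrom"] != 3:
                continue
            detections += 1
            lo, hi = ss.lod_interval(scan, str(peak["marker"]))
            idx = scan.table["marker"].tolist()
            if idx.index(lo) <= idx.index("chr3_m4") <= idx.index(hi):
                hits += 1
        assert detections > 0
        assert hits / detections >= 0.9


class TestVarianceExplained:
    def test_noiseless_marker_explains_everything(self):
        qtl = ss.QTLModel(residual_sd=0.0, loci=[ss.QTLLocus("chr4_m2", "pure", 2)])
        fam = ss.gen_backcross(100, MAP, qtl, seed=12)
        assert ss.variance_explained(fam, "trait", "chr4_m2", "pure") == \
            pytest.approx(100.0, abs=1e-9)

    def test_independent_marker_explains_nothing(self):
        fam = ss.gen_backcross(10000, MAP, ss.QTLModel(residual_sd=1.0), seed=13)
        assert ss.variance_explained(fam, "trait", "chr2_m0", "hybrid") <= 2.0

    def test_planted_fifteen_percent_recovered(self):
        vals = [ss.variance_explained(planted_family(seed=200 + s), "trait",
                                      "chr3_m4", "hybrid") for s in range(50)]
        assert abs(np.mean(vals) - 15.0) < 4.0


class TestTwoLocus:
    def fig_style_family(self, seed, delta=-2.7, sd=2.7):
        qtl = ss.QTLModel(mean=5.5, residual_sd=sd, epistatic_pairs=[
            ss.EpistaticInteraction("chr1_m5", "chr2_m5", (1, 1), delta,
                                    "hybrid", "pure")])
        return ss.gen_backcross(158, MAP, qtl, seed=seed, phenotype_name="elements")

    def test_null_classes_share_letters(self):
        fam = ss.gen_backcross(10000, MAP, ss.QTLModel(residual_sd=1.0), seed=14)
        res = ss.two_locus_analysis(fam, "trait", "chr1_m5", "chr2_m5")
        assert abs(res.interaction_contrast) < 3 * res.contrast_se
        letters = set(res.letters.values())
        assert len(letters) == 1

    def test_additive_model_has_no_interaction(self):
        qtl = ss.QTLModel(residual_sd=1.0,
                          loci=[ss.QTLLocus("chr1_m5", "hybrid", 1.0),
                                ss.QTLLocus("chr2_m5", "pure", 0.8)])
        contrasts, ses, fs = [], [], []
        for s in range(10):
            fam = ss.gen_backcross(2000, MAP, qtl, seed=300 + s)
            res = ss.two_locus_analysis(fam, "trait", "chr1_m5", "chr2_m5")
            contrasts.append(res.interaction_contrast)
            ses.append(res.contrast_se)
            fs.append(res.f_stat)
        # interaction null while the overall group effect is strong
        assert np.mean(np.abs(contrasts) < 3 * np.array(ses)) >= 0.9
        assert min(fs) > 50

    def test_epistatic_class_gets_distinct_letter(self):
        fam = self.fig_style_family(seed=15)
        res = ss.two_locus_analysis(fam, "elements", "chr1_m5", "chr2_m5")
        others = {res.letters[c] for c in [(0, 0), (0, 1), (1, 0)]}
        shifted = set(res.letters[(1, 1)])
        assert not shifted & set("".join(others))
        assert res.class_table["n"].sum() == 158

    def test_class_means_near_truth(self):
        fam = self.fig_style_family(seed=16)
        res = ss.two_locus_analysis(fam, "elements", "chr1_m5", "chr2_m5")
        tbl = res.class_table.set_index("genotype")
        assert tbl.loc[[(0, 0), (0, 1), (1, 0)], "mean"].mean() == \
            pytest.approx(5.5, abs=1.0)
        assert tbl.loc[[(1, 1)], "mean"].iloc[0] == pytest.approx(2.8, abs=1.5)


class TestSelectExtremes:
    def test_full_sibship_scale_tail_sizes(self):
        v = np.linspace(0, 1, 457)
        lo, hi = ss.select_extremes(v, 0.035)
        assert len(lo) == len(hi) == 16  # ceil(457 * 0.035) = 16

    def test_small_n_ceiling(self):
        lo, hi = ss.select_extremes(np.arange(100, dtype=float), 0.035)
        assert len(lo) == len(hi) == 4
        assert list(lo) == [0, 1, 2, 3]
        assert list(hi) == [96, 97, 98, 99]

    def test_disjoint_and_tie_break_by_index(self):
        v = np.zeros(20)
        lo, hi = ss.select_extremes(v, 0.2)
        assert len(np.intersect1d(lo, hi)) == 0
        assert list(lo) == [0, 1, 2, 3]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            ss.select_extremes(np.arange(10.0), 0.5)


def oracle_fst(a1, a2):
    """Independent haploid Weir–Cockerham transcription via ANOVA sums of squares."""
    x = np.concatenate([a1, a2])
    n1, n2 = len(a1), len(a2)
    ssb = n1 * (a1.mean() - x.mean()) ** 2 + n2 * (a2.mean() - x.mean()) ** 2
    ssw = np.sum((a1 - a1.mean()) ** 2) + np.sum((a2 - a2.mean()) ** 2)
    msp, msg = ssb / 1.0, ssw / (n1 + n2 - 2)
    nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
    return (msp - msg) / (msp + (nc - 1) * msg)


class TestFst:
    def test_identical_groups_at_most_zero(self, rng):
        g = rng.integers(0, 2, size=(10, 4)).astype(np.int8)
        fst = ss.weir_cockerham_fst(g, g.copy())
        assert np.all(fst[~np.isnan(fst)] <= 1e-12)

    def test_fixed_difference_is_one(self):
        g1 = np.zeros((8, 3), dtype=np.int8)
        g2 = np.ones((8, 3), dtype=np.int8)
        assert np.allclose(ss.weir_cockerham_fst(g1, g2), 1.0)

    def test_matches_independent_transcription(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(4, 30, size=2)
            a1 = (rng.random(n1) < rng.random()).astype(float)
            a2 = (rng.random(n2) < rng.random()).astype(float)
            if a1.mean() == a2.mean() and a1.mean() in (0.0, 1.0):
                continue
            ours = ss.weir_cockerham_fst(a1[:, None], a2[:, None])[0]
            if np.isnan(ours):
                continue
            assert ours == pytest.approx(oracle_fst(a1, a2), abs=1e-12)

    def test_monomorphic_marker_missing(self):
        g1 = np.zeros((5, 1), dtype=np.int8)
        g2 = np.zeros((5, 1), dtype=np.int8)
        assert np.isnan(ss.weir_cockerham_fst(g1, g2)[0])

    def test_scan_flags_planted_major_locus(self):
        qtl = ss.QTLModel(residual_sd=0.5,
                          loci=[ss.QTLLocus("chr4_m5", "hybrid", 1.0)])
        fam = ss.gen_backcross(457, MAP, qtl, seed=17)
        lo, hi = ss.select_extremes(fam.phenotypes["trait"])
        res = ss.fst_scan(fam, (lo, hi), n_perm=2000, seed=18)
        assert res.max_marker == "chr4_m5"
        row = res.table[res.table["marker"] == "chr4_m5"].iloc[0]
        assert row["significant"]

    def test_overlapping_groups_rejected(self):
        fam = ss.gen_backcross(50, MAP, ss.QTLModel(), seed=19)
        with pytest.raises(ValueError):
            ss.fst_scan(fam, (np.array([0, 1, 2]), np.array([2, 3, 4])))
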