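"""Map a simulated backcross: LOD scan, epistasis, extreme-phenotype F_ST.

Simulates a backcross family (n = 158) segregating an additive QTL that
explains 15% of phenotypic variance, scans it by Haley-Knott regression with a
permutation threshold and 1.5-LOD support interval, tests a planted epistatic
pair, then runs an extreme-phenotype F_ST scan on a second, larger family
(n = 457, 3.5% tails) segregating a major-effect locus.
"""

import math

import stripespot as ss

marker_map = ss.make_marker_map()  # 25 chromosomes x 10 markers, 10 cM apart

# --- single-QTL scan -------------------------------------------------------
a, frac = 1.0, 0.15
sd = math.sqrt((a**2 / 4) * (1 - frac) / frac)
qtl = ss.QTLModel(residual_sd=sd, loci=[ss.QTLLocus("chr15_m4", "hybrid", a)])
family = ss.gen_backcross(158, marker_map, qtl, seed=2)

scan = ss.lod_scan(family, "trait", origin="hybrid")
threshold = ss.permutation_threshold(family, "trait", origin="hybrid",
                                     n_perm=1000, seed=3)
peaks = ss.find_peaks(scan, threshold, family)
print(f"genome-wide max LOD = {scan.max_lod:.2f}, "
      f"5% permutation threshold = {threshold:.2f}")
for p in peaks:
    print(f"  peak {p['marker']} (chr{p['chrom']}): LOD {p['lod']:.2f}, "
          f"1.5-LOD interval {p['interval'][0]}..{p['interval'][1]}, "
          f"%var = {p['pct_var']:.1f}")

# --- two-locus epistasis ---------------------------------------------------
ep = ss.QTLModel(mean=5.5, residual_sd=2.7, epistatic_pairs=[
    ss.EpistaticInteraction("chr18_m5", "chr20_m5", (1, 1), -2.7,
                            "hybrid", "pure")])
fam_ep = ss.gen_backcross(158, marker_map, ep, seed=4, phenotype_name="elements")
res = ss.two_locus_analysis(fam_ep, "elements", "chr18_m5", "chr20_m5")
print(f"\nepistasis ANOVA: F = {res.f_stat:.2f}, P = {res.p_value:.2g}")
print(f"interaction contrast = {res.interaction_contrast:.2f} "
      f"+- {res.contrast_se:.2f}")
print(res.class_table.to_string(index=False))

# --- extreme-phenotype F_ST scan ------------------------------------------
major = ss.QTLModel(residual_sd=0.5, loci=[ss.QTLLocus("chr7_m3", "hybrid", 1.0)])
fam_big = ss.gen_backcross(457, marker_map, major, seed=6)
low, high = ss.select_extremes(fam_big.phenotypes["trait"], fraction=0.035)
fst = ss.fst_scan(fam_big, (low, high), origin="hybrid", n_perm=2000, seed=7)
row = fst.table.loc[fst.table["fst"].idxmax()]
print(f"\nF_ST scan of {len(low)}+{len(high)} phenotypic extremes:")
print(f"  top marker {row['marker']} F_ST = {row['fst']:.3f} "
      f"(BH-adjusted P = {row['p_adj']:.3g})")
print("\nLOD compares single-QTL vs null fits; F_ST measures allele-frequency")
print("differentiation between the striped-most and spotted-most siblings.")
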