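"""Joint-linkage mapping: permutation thresholds, stepwise search, pruning,
re-scan, support intervals, allelic effects and PVE."""

import numpy as np
import pandas as pd
import pytest

from namqtl import linkage as jl

from conftest import qtl_phenotype


def independent_marker_data(n=400, m=30, n_fam=4, seed=0):
    """Markers drawn independently (no linkage): sharp, LD-free signals."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 2, size=(n, m)).astype(float)
    fam_idx = np.repeat(np.arange(n_fam), n // n_fam)
    markers = pd.DataFrame({
        "marker": [f"m{j}" for j in range(m)],
        "chrom": 1, "cM": np.arange(m, dtype=float),
        "bp": np.arange(m) * 1_000_000,
    })
    return jl.MarkerData(geno, fam_idx, [f"F{k}" for k in range(n_fam)],
                         [f"L{i:04d}" for i in range(n)], markers)


# ---------------------------------------------------------------------------
# Permutation threshold
# ---------------------------------------------------------------------------

def test_threshold_monotone_in_alpha_and_deterministic(md10):
    y = pd.Series(np.random.default_rng(0).normal(0, 1, md10.n_lines),
                  index=md10.line_ids)
    t05 = jl.jl_permutation_threshold(y, md10, n_perm=100, alpha=0.05, seed=1)
    t05b = jl.jl_permutation_threshold(y, md10, n_perm=100, alpha=0.05, seed=1)
    t01 = jl.jl_permutation_threshold(y, md10, n_perm=100, alpha=0.01, seed=1)
    t_all = jl.jl_permutation_threshold(y, md10, n_perm=100, alpha=1.0, seed=1)
    assert t05 == t05b
    assert t01 <= t05 <= t_all
    assert 0 < t05 < 1


def test_threshold_preconditions(md10):
    y = pd.Series(np.zeros(md10.n_lines), index=md10.line_ids)
    with pytest.raises(ValueError):
        jl.jl_permutation_threshold(y, md10, n_perm=10, alpha=0.05)
    with pytest.raises(ValueError):
        jl.jl_permutation_threshold(y, md10, n_perm=50, alpha=0.01)


def test_threshold_is_alpha_order_statistic():
    # with alpha = 1 the threshold is the largest permutation minimum, so a
    # fresh scan of any within-family permutation cannot beat it
    md = independent_marker_data(n=200, m=15, seed=3)
    rng = np.random.default_rng(4)
    y = pd.Series(rng.normal(0, 1, md.n_lines), index=md.line_ids)
    t_max = jl.jl_permutation_threshold(y, md, n_perm=50, alpha=1.0, seed=5)
    t_min = jl.jl_permutation_threshold(y, md, n_perm=50, alpha=1 / 50,
                                        seed=5)
    scan = jl.NestedScan(md)
    _, p, _ = scan.stats(y.to_numpy())
    assert t_min <= t_max
    assert t_min > 0


# ---------------------------------------------------------------------------
# Stepwise search
# ---------------------------------------------------------------------------

def test_stepwise_recovers_qtl_within_5cm(md10):
    hits = 0
    for s in range(5):
        y, _ = qtl_phenotype(md10, "c2_m50", pve_target=0.20, seed=s)
        model = jl.stepwise_jl(y, md10, entry_p=1e-5)
        pos = [abs(md10.markers.at[m, "cM"] - 50.0)
               for m in model.peaks
               if md10.markers.at[m, "chrom"] == 2]
        hits += bool(pos) and min(pos) <= 5.0
    assert hits >= 4


def test_identical_traits_give_identical_models(md10):
    y, _ = qtl_phenotype(md10, "c1_m30", pve_target=0.2, seed=3)
    m1 = jl.stepwise_jl(y, md10, entry_p=1e-5)
    m2 = jl.stepwise_jl(y.copy(), md10, entry_p=1e-5)
    assert m1.peaks == m2.peaks


def test_mostly_empty_models_on_null_traits(md10):
    y0 = pd.Series(np.random.default_rng(0).normal(0, 1, md10.n_lines),
                   index=md10.line_ids)
    thr = jl.jl_permutation_threshold(y0, md10, n_perm=200, alpha=0.05,
                                      seed=2)
    empties = 0
    for s in range(20):
        y = pd.Series(np.random.default_rng(500 + s).normal(
            0, 1, md10.n_lines), index=md10.line_ids)
        model = jl.stepwise_jl(y, md10, entry_p=thr)
        empties += not model.peaks
    assert empties >= 16


def test_exit_threshold_validated(md10):
    y = pd.Series(np.zeros(md10.n_lines) + np.random.default_rng(1).normal(
        0, 1, md10.n_lines), index=md10.line_ids)
    with pytest.raises(ValueError):
        jl.stepwise_jl(y, md10, entry_p=1e-3, exit_p=1e-4)


def test_stepwise_matches_best_subset_on_small_instances():
    # exhaustive oracle: stable states (every member passes drop-one entry,
    # no addition passes) ranked by model SS
    from itertools import combinations
    agree = 0
    for s in range(8):
        md = independent_marker_data(n=300, m=8, seed=s)
        y, _ = qtl_phenotype(md, "m3", pve_target=0.15, seed=s + 100,
                             effects=np.full(4, 1.0))
        entry = 1e-4
        model = jl.stepwise_jl(y, md, entry_p=entry)
        sub, yv = jl.align_phenotype(md, y)

        def model_ss(peaks):
            Q = jl._ortho_basis(jl._design(sub, list(peaks)))
            c = yv - yv.mean()
            return float(np.sum((Q.T @ c) ** 2))

        best, best_ss = (), -np.inf
        for k in range(0, 3):
            for peaks in combinations(range(md.n_markers), k):
                stats = jl._drop_one_pvalues(sub, yv, list(peaks))
                if any(p > entry for p, _ in stats.values()):
                    continue
                scan = jl.NestedScan(sub, model=list(peaks))
                others = np.setdiff1d(np.arange(md.n_markers), peaks)
                if others.size:
                    _, pv, _ = jl.NestedScan(
                        sub, model=list(peaks), candidates=others).stats(yv)
                    if np.nanmin(pv) <= entry:
                        continue
                ss = model_ss(peaks)
                if ss > best_ss:
                    best, best_ss = tuple(sorted(peaks)), ss
        agree += tuple(model.peaks) == best
    assert agree >= 7


# ---------------------------------------------------------------------------
# Multicollinearity pruning
# ---------------------------------------------------------------------------

def duplicated_marker_data(seed=0, r_noise=0.0):
    md = independent_marker_data(n=300, m=10, seed=seed)
    md.geno[:, 5] = md.geno[:, 4]
    if r_noise:
        flip = np.random.default_rng(seed + 1).random(300) < r_noise
        md.geno[flip, 5] = 1 - md.geno[flip, 5]
    return jl.MarkerData(md.geno, md.fam_idx, md.fam_ids, md.line_ids,
                         md.markers)


def test_prune_keeps_one_of_duplicated_markers():
    md = duplicated_marker_data()
    y, _ = qtl_phenotype(md, "m4", pve_target=0.3, seed=7,
                         effects=np.full(4, 1.0))
    model = jl.JLModel("t", [4, 5], 1e-3, 2e-3)
    pruned = jl.prune_multicollinear(model, md, y, r_threshold=0.8)
    assert len(pruned.peaks) == 1
    assert pruned.peaks[0] in (4, 5)


def test_prune_boundary_is_strict():
    md = independent_marker_data(n=2000, m=4, seed=2)
    # construct a pair with |r| just below 0.8
    base = md.geno[:, 0]
    flip_n = int(0.1 * len(base))
    g2 = base.copy()
    g2[:flip_n] = 1 - g2[:flip_n]
    md.geno[:, 1] = g2
    r = np.corrcoef(md.geno[:, 0], md.geno[:, 1])[0, 1]
    assert r < 0.8
    y = pd.Series(base + np.random.default_rng(3).normal(0, 1, len(base)),
                  index=md.line_ids)
    model = jl.JLModel("t", [0, 1], 1e-3, 2e-3)
    pruned = jl.prune_multicollinear(model, md, y, r_threshold=0.8)
    assert pruned.peaks == [0, 1]


def test_prune_three_way_collinearity_keeps_max_ss():
    rng = np.random.default_rng(5)
    md = independent_marker_data(n=600, m=6, seed=5)
    base = md.geno[:, 0]
    for j in (1, 2):  # near-copies of column 0
        g = base.copy()
        flip = rng.random(600) < 0.03
        g[flip] = 1 - g[flip]
        md.geno[:, j] = g
    y = pd.Series(base + rng.normal(0, 0.8, 600), index=md.line_ids)
    model = jl.JLModel("t", [0, 1, 2], 1e-3, 2e-3)
    pruned = jl.prune_multicollinear(model, md, y, r_threshold=0.8)
    assert len(pruned.peaks) == 1
    # oracle: the survivor is the single marker with the highest lone-model SS
    sub, yv = jl.align_phenotype(md, y)
    lone_ss = {}
    for m in (0, 1, 2):
        scan = jl.NestedScan(sub, model=[], candidates=np.array([m]))
        lone_ss[m] = scan.stats(yv)[2][0]
    assert pruned.peaks[0] == max(lone_ss, key=lone_ss.get)


# ---------------------------------------------------------------------------
# Re-scan and support intervals
# ---------------------------------------------------------------------------

def test_rescan_fixed_point_when_peak_at_local_max(md10):
    y, _ = qtl_phenotype(md10, "c1_m50", pve_target=0.25, seed=11)
    thr = 1e-3
    model = jl.stepwise_jl(y, md10, entry_p=1e-5)
    rescanned = jl.rescan_peaks(model, md10, y, thr)
    again = jl.rescan_peaks(rescanned, md10, y, thr)
    assert rescanned.peaks == again.peaks


def test_rescan_moves_offset_peak_to_ss_maximum(md10):
    y, _ = qtl_phenotype(md10, "c1_m50", pve_target=0.25, seed=12)
    q = md10.marker_index("c1_m50")
    start = JLM = jl.JLModel("t", [q + 2], 1e-4, 2e-4)
    thr = 1e-3
    moved = jl.rescan_peaks(start, md10, y, thr)
    # oracle: exhaustive lone-marker SS over the final support interval
    si = jl.support_interval(moved, md10, y, moved.peaks[0], thr)
    sub, yv = jl.align_phenotype(md10, y)
    cand = np.array(si.member_markers)
    ss = jl.NestedScan(sub, model=[], candidates=cand).stats(yv)[2]
    assert moved.peaks[0] == cand[np.argmax(ss)]


def test_rescan_plateau_keeps_leftmost():
    md = duplicated_marker_data(seed=9)  # markers 4 and 5 identical
    y, _ = qtl_phenotype(md, "m4", pve_target=0.3, seed=13,
                         effects=np.full(4, 1.0))
    model = jl.JLModel("t", [5], 1e-3, 2e-3)
    moved = jl.rescan_peaks(model, md, y, threshold=0.05)
    assert moved.peaks == [4]  # identical SS, lower cM wins


def test_support_interval_single_marker_without_ld():
    md = independent_marker_data(n=500, m=20, seed=20)
    y, _ = qtl_phenotype(md, "m10", pve_target=0.3, seed=21,
                         effects=np.full(4, 1.0))
    model = jl.stepwise_jl(y, md, entry_p=1e-6)
    assert md.marker_index("m10") in model.peaks
    si = jl.support_interval(model, md, y, md.marker_index("m10"),
                             threshold=1e-6)
    assert si.member_markers == [md.marker_index("m10")]
    assert si.left_cM == si.right_cM == 10.0


def test_support_interval_covers_true_qtl(md10):
    thr01 = None
    covered = 0
    for s in range(10):
        y, _ = qtl_phenotype(md10, "c3_m40", pve_target=0.15, seed=40 + s)
        if thr01 is None:
            thr01 = jl.jl_permutation_threshold(y, md10, 200, 0.01, seed=1)
        model = jl.stepwise_jl(y, md10, entry_p=1e-4)
        on3 = [m for m in model.peaks if md10.markers.at[m, "chrom"] == 3]
        if not on3:
            continue
        peak = on3[0]
        si = jl.support_interval(model, md10, y, peak, thr01)
        covered += si.left_cM <= 40.0 <= si.right_cM
    assert covered >= 9


def test_support_interval_requires_model_peak(md10):
    y, _ = qtl_phenotype(md10, "c1_m50", pve_target=0.2, seed=30)
    model = jl.stepwise_jl(y, md10, entry_p=1e-5)
    with pytest.raises(ValueError):
        jl.support_interval(model, md10, y, 9999, threshold=1e-3)


# ---------------------------------------------------------------------------
# Allelic effects and PVE
# ---------------------------------------------------------------------------

def test_allelic_effects_exact_without_noise():
    md = independent_marker_data(n=400, m=5, seed=31)
    q = 2
    a = np.array([1.0, -0.5, 2.0, 0.0])
    y = pd.Series(md.geno[:, q] * a[md.fam_idx], index=md.line_ids)
    model = jl.JLModel("t", [q], 1e-3, 2e-3)
    eff = jl.allelic_effects(model, md, y).set_index("family")["effect"]
    for k, fam in enumerate(md.fam_ids):
        assert eff[fam] == pytest.approx(a[k], abs=1e-9)


def test_monomorphic_family_effect_is_missing():
    md = independent_marker_data(n=400, m=5, seed=32)
    geno = md.geno.copy()
    geno[md.fam_idx == 2, 1] = 0.0  # monomorphic in family F2
    md2 = jl.MarkerData(geno, md.fam_idx, md.fam_ids, md.line_ids, md.markers)
    y, _ = qtl_phenotype(md2, "m1", pve_target=0.3, seed=33,
                         effects=np.full(4, 1.0))
    eff = jl.allelic_effects(jl.JLModel("t", [1], 1e-3, 2e-3), md2, y)
    assert np.isnan(eff.set_index("family").loc["F2", "effect"])
    assert eff.set_index("family").loc["F0", "effect"] == pytest.approx(
        1.0, abs=0.5)


def test_effect_sign_recovery_at_moderate_pve(md10):
    signs = np.array([1, -1, 1, 1, -1, 1, -1, 1, 1, -1], dtype=float)
    correct = 0
    for s in range(3):
        y, _ = qtl_phenotype(md10, "c2_m60", pve_target=0.10, seed=60 + s,
                             effects=signs)
        eff = jl.allelic_effects(
            jl.JLModel("t", [md10.marker_index("c2_m60")], 1e-3, 2e-3),
            md10, y)
        est = eff.set_index("family")["effect"].loc[md10.fam_ids].to_numpy()
        correct += int((np.sign(est) == signs).sum())
    assert correct >= 27  # >= 9/10 on average over 3 draws


def test_pve_closed_form_single_family():
    # one family, allele frequency exactly 1/2, slope 2 (allelic effect 1),
    # total variance 2 -> PVE = (0.25 * 4) / 2 = 0.5
    rng = np.random.default_rng(70)
    n = 400
    g = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    rng.shuffle(g)
    e = rng.normal(0, 1, n)
    e = (e - e.mean()) / e.std(ddof=1)  # exact unit variance, mean 0
    e -= (e @ (g - g.mean())) / ((g - g.mean()) @ (g - g.mean())) * \
        (g - g.mean())  # orthogonal to genotype
    e *= np.sqrt(1.0 / e.var(ddof=1))
    y_arr = 2.0 * g + e
    scale = np.sqrt(2.0 / y_arr.var(ddof=1))
    y_arr = y_arr * scale  # total variance exactly 2
    markers = pd.DataFrame({"marker": ["m0"], "chrom": [1], "cM": [0.0],
                            "bp": [0]})
    md = jl.MarkerData(g[:, None].copy(), np.zeros(n, dtype=int), ["F0"],
                       [f"L{i}" for i in range(n)], markers)
    y = pd.Series(y_arr, index=md.line_ids)
    out = jl.pve(jl.JLModel("t", [0], 1e-3, 2e-3), md, y)
    assert out["pve"].iloc[0] == pytest.approx(0.5, abs=0.01)


def test_null_marker_has_negligible_pve():
    # expected null PVE ~ n_families / n_lines = 0.002 here
    md = independent_marker_data(n=2000, m=3, seed=80)
    y = pd.Series(np.random.default_rng(80).normal(0, 1, md.n_lines),
                  index=md.line_ids)
    out = jl.pve(jl.JLModel("t", [1], 1, 2), md, y)
    assert out["pve"].iloc[0] <= 0.01


def test_pve_recovery_with_distortion(gmap3):
    from namqtl import sim
    pop = sim.simulate_population(gmap3, n_ril=100, seed=90,
                                  distortion=[("c1_m50", "Z001", 0.2),
                                              ("c1_m50", "Z002", 0.8)])
    md = jl.marker_data_from_population(pop)
    ests = []
    for s in range(5):
        y, _ = qtl_phenotype(md, "c1_m50", pve_target=0.15, seed=90 + s)
        out = jl.pve(jl.JLModel("t", [md.marker_index("c1_m50")], 1, 2),
                     md, y)
        ests.append(out["pve"].iloc[0] * 100)
    assert abs(np.mean(ests) - 15.0) <= 4.0


def test_model_ss_nondecreasing_and_family_always_present(md10):
    y, _ = qtl_phenotype(md10, "c1_m50", pve_target=0.2, seed=95)
    sub, yv = jl.align_phenotype(md10, y)
    X0 = jl._design(sub, [])
    assert X0.shape[1] == len(md10.fam_ids)  # forced family intercepts
    # projection SS grows as peaks are added
    model = jl.stepwise_jl(y, md10, entry_p=1e-4)
    prev = -np.inf
    for k in range(len(model.peaks) + 1):
        Q = jl._ortho_basis(jl._design(sub, model.peaks[:k]))
        ss = float(np.sum((Q.T @ (yv - yv.mean())) ** 2))
        assert ss >= prev - 1e-9
        prev = ss
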