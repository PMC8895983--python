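"""Mixed-model BLUEs: REML against ANOVA closed forms, structure selection,
DFFITS outliers, Box-Cox identities, heritability."""

import numpy as np
import pandas as pd
import pytest

from namqtl import blues as bl
from namqtl import sim

DROP_YF = ("year", "field")


def one_way_plots(g=40, r=4, s2g=2.0, s2e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2g), g)
    rows = []
    for i in range(g):
        fam = "F1" if i < g // 2 else "F2"
        for j in range(r):
            rows.append((f"L{i:03d}", fam, 2009, "2009F1", "s", "b",
                         j + 1, i + 1, "P1", "t", u[i] + rng.normal(0, np.sqrt(s2e))))
    return pd.DataFrame(rows, columns=[
        "line", "family", "year", "field", "set", "block", "row", "range",
        "plate", "trait", "value"])


def design_plots(seed, n_ril=60, n_fam=2, rho_row=0.0, rho_range=0.0,
                 sigma2_block=0.0, sigma2_error=1.0, years=(2009, 2010)):
    gmap = sim.simulate_map(1, 50, 5.0)
    pop = sim.simulate_population(gmap, n_ril=n_ril,
                                  alt_parents=sim.DEFAULT_ALT_PARENTS[:n_fam],
                                  seed=seed)
    arch = sim.TraitArchitecture(qtl=[], h2_target={"t": 0.5},
                                 sigma2_family=0.5)
    design = sim.FieldDesign(fields_by_year={y: 1 for y in years},
                             sigma2_block=sigma2_block, rho_row=rho_row,
                             rho_range=rho_range, sigma2_error=sigma2_error)
    return sim.simulate_traits(pop, arch, design, seed=seed + 1000)


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def test_reml_matches_anova_on_balanced_oneway():
    plots = one_way_plots(seed=0)
    fit = bl.fit_mixed(plots, bl.ModelStructure((), "identity"), "t",
                       drop_terms=DROP_YF)
    y = plots.sort_values(["line"])["value"].to_numpy().reshape(40, 4)
    msl = 4 * np.var(y.mean(axis=1), ddof=1)
    mse = np.mean(np.var(y, axis=1, ddof=1))
    # family means carry no real signal; line component absorbs the rest
    assert fit.variance_components["line"] == pytest.approx((msl - mse) / 4,
                                                            rel=1e-2)
    resid = list(fit.residual_params.values())[0]["sigma2"]
    assert resid == pytest.approx(mse, rel=1e-2)
    assert np.isfinite(fit.loglik)
    assert fit.bic == pytest.approx(-2 * fit.loglik
                                    + fit.n_params * np.log(fit.n_obs))


def test_ar1_with_rho_zero_equals_identity_fit():
    plots = design_plots(seed=3, years=(2009,))
    f_id = bl.fit_mixed(plots, bl.ModelStructure((), "identity"), "t",
                        drop_terms=DROP_YF)
    f_ar = bl.fit_mixed(plots, bl.ModelStructure((), "ar1_both"), "t",
                        drop_terms=DROP_YF, fix_rho=0.0)
    assert f_ar.loglik == pytest.approx(f_id.loglik, abs=1e-5)


def test_ar1_rho_recovery():
    ests = []
    for s in range(6):
        plots = design_plots(seed=s, rho_row=0.6)
        fit = bl.fit_mixed(plots, bl.ModelStructure((), "ar1_row"), "t")
        ests.append(np.mean([v["rho_row"]
                             for v in fit.residual_params.values()]))
    assert abs(np.mean(ests) - 0.6) < 0.15


def test_single_level_random_term_rejected():
    plots = one_way_plots()
    with pytest.raises(ValueError, match="fewer than 2 levels"):
        bl.fit_mixed(plots, bl.ModelStructure((), "identity"), "t")


# ---------------------------------------------------------------------------
# Structure selection
# ---------------------------------------------------------------------------

def test_block_effects_detected_by_bic():
    hits = 0
    for s in range(10):
        plots = design_plots(seed=s + 50, sigma2_block=4.0)
        structure, _ = bl.select_structure(plots, "t", [(), ("block",)],
                                           ("identity",))
        hits += "block" in structure.extra_terms
    assert hits >= 8


def test_white_noise_prefers_identity_residual():
    hits = 0
    for s in range(10):
        plots = design_plots(seed=s + 100)
        structure, _ = bl.select_structure(plots, "t", [()],
                                           ("identity", "ar1_both"))
        hits += structure.residual == "identity"
    assert hits >= 8


def test_single_candidate_returned_unchanged():
    plots = design_plots(seed=7)
    structure, fit = bl.select_structure(plots, "t", [("block",)],
                                         ("ar1_row",))
    assert structure == bl.ModelStructure(("block",), "ar1_row")
    assert np.isfinite(fit.loglik)


def test_selection_invariant_to_candidate_order():
    plots = design_plots(seed=8, sigma2_block=2.0)
    cands = [(), ("block",), ("set",)]
    s1, _ = bl.select_structure(plots, "t", cands, ("identity", "ar1_both"))
    s2, _ = bl.select_structure(plots, "t", cands[::-1],
                                ("ar1_both", "identity"))
    assert s1 == s2


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def test_clean_data_rarely_flagged_at_conservative_threshold():
    fracs = []
    for s in range(10):
        plots = design_plots(seed=s + 200)
        flagged = bl.flag_outliers(plots, "t",
                                   bl.ModelStructure((), "identity"),
                                   threshold=3.0)
        fracs.append(len(flagged) / len(plots))
    assert np.mean(fracs) <= 0.01


def test_gross_outlier_is_flagged_and_removal_is_trait_specific():
    plots = design_plots(seed=9)
    plots2 = pd.concat([plots, plots.assign(trait="other")],
                       ignore_index=True)
    sd = plots2["value"].std()
    target = plots2.index[plots2.trait == "t"][17]
    plots2.loc[target, "value"] += 10 * sd
    flagged = bl.flag_outliers(plots2, "t", bl.ModelStructure((), "identity"),
                               threshold=3.0)
    assert target in flagged
    cleaned = bl.remove_outliers(plots2, flagged)
    assert cleaned.loc[cleaned.trait == "other", "value"].notna().all()
    assert np.isnan(cleaned.loc[target, "value"])


def test_outlier_threshold_edges():
    plots = design_plots(seed=10)
    assert len(bl.flag_outliers(plots, "t", bl.ModelStructure(),
                                threshold=np.inf)) == 0
    with pytest.raises(ValueError):
        bl.flag_outliers(plots, "t", bl.ModelStructure(), threshold=-1.0)


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------

def test_blue_equals_line_mean_without_random_terms():
    plots = one_way_plots(seed=1)
    tab = bl.compute_blues(plots, "t", bl.ModelStructure((), "identity"))
    means = plots.groupby("line")["value"].mean()
    assert np.allclose(tab.set_index("line")["blue"], means[tab["line"]],
                       atol=1e-10)


def test_blue_of_duplicate_plots_is_that_value():
    rows = [("L1", "F1", 2009, "f", "s", "b", 1, 1, "P1", "t", 5.5)] * 3 \
        + [("L2", "F1", 2009, "f", "s", "b", 1, 2, "P1", "t", 2.0)] * 2
    plots = pd.DataFrame(rows, columns=[
        "line", "family", "year", "field", "set", "block", "row", "range",
        "plate", "trait", "value"])
    tab = bl.compute_blues(plots, "t", bl.ModelStructure((), "identity"))
    assert tab.set_index("line").loc["L1", "blue"] == pytest.approx(5.5)
    assert tab.set_index("line").loc["L2", "blue"] == pytest.approx(2.0)


def test_blues_track_true_line_effects():
    # corr(BLUE, beta) ~ sqrt(h2); at h2 = 0.85 expect ~0.92 >= 0.9
    rng = np.random.default_rng(12)
    g, r = 150, 2
    beta = rng.normal(0, 1, g)
    s2e = r * (1 - 0.85) / 0.85
    rows = []
    for i in range(g):
        for j in range(r):
            rows.append((f"L{i:03d}", "F1" if i < 75 else "F2", 2009 + j,
                         f"{2009 + j}F1", "s", "b", j + 1, i + 1, "P1", "t",
                         beta[i] + rng.normal(0, np.sqrt(s2e))))
    plots = pd.DataFrame(rows, columns=[
        "line", "family", "year", "field", "set", "block", "row", "range",
        "plate", "trait", "value"])
    tab = bl.compute_blues(plots, "t", bl.ModelStructure((), "identity"))
    order = [f"L{i:03d}" for i in range(g)]
    est = tab.set_index("line").loc[order, "blue"].to_numpy()
    assert np.corrcoef(est, beta)[0, 1] >= 0.9


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lam,shift,y,expected", [
    (1.0, 0.0, 5.0, 4.0),
    (0.0, 0.0, np.e, 1.0),
    (0.5, 1.0, 3.0, 2.0),
])
def test_boxcox_closed_forms(lam, shift, y, expected):
    assert bl.boxcox([y], lam, shift)[0] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("lam", [-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5,
                                 2.0])
def test_boxcox_inverse_roundtrip(lam):
    y = np.linspace(0.2, 8.0, 40)
    z = bl.boxcox(y, lam)
    back = bl.boxcox_inverse(z, lam)
    assert np.allclose(back, y, atol=1e-10)
    assert np.all(np.diff(z) > 0)  # strictly increasing


def test_boxcox_rejects_nonpositive_and_reports_position():
    with pytest.raises(ValueError, match="position 2"):
        bl.boxcox([1.0, 2.0, -3.0], 0.5)


def test_choose_lambda_shifts_negative_data():
    lam, shift = bl.choose_lambda(np.array([-1.0, 0.5, 2.0, 4.0]))
    assert shift > 1.0
    assert lam in bl.LAMBDA_GRID


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

def test_heritability_closed_form():
    h = bl.line_mean_heritability({"line": 1.0, "error": 1.0},
                                  n_env_per_line=[1], n_plots_per_line=[2, 2])
    assert h.estimate == pytest.approx(2 / 3)
    h0 = bl.line_mean_heritability({"line": 0.0, "error": 1.0},
                                   n_env_per_line=[2], n_plots_per_line=[2])
    assert h0.estimate == 0.0
    with pytest.raises(ValueError):
        bl.line_mean_heritability({"line": 0.0, "error": 0.0}, [1], [1])


def test_heritability_recovery_with_delta_se():
    ests, ses = [], []
    for s in range(4):
        gmap = sim.simulate_map(2, 60, 2.0)
        pop = sim.simulate_population(
            gmap, n_ril=30, alt_parents=sim.DEFAULT_ALT_PARENTS[:4],
            seed=s)
        rng = np.random.default_rng(s)
        qtl = [sim.QTL(f"c{c}_m{m}",
                       {"t": dict(zip(pop.family_ids(),
                                      rng.normal(0, 1, 4)))})
               for c, m in [(1, 10), (1, 25), (2, 8), (2, 20)]]
        arch = sim.TraitArchitecture(qtl=qtl, h2_target={"t": 0.9},
                                     sigma2_family=0.5)
        plots = sim.simulate_traits(pop, arch, sim.FieldDesign(), seed=s + 7)
        fit = bl.fit_mixed(plots, bl.ModelStructure((), "identity"), "t",
                           compute_vc_cov=True)
        sub = plots[plots.trait == "t"]
        vc = dict(fit.variance_components)
        for g_, p_ in fit.residual_params.items():
            vc[f"residual:{g_}"] = p_["sigma2"]
        h = bl.line_mean_heritability(
            vc, sub.groupby("line")["year"].nunique(),
            sub.groupby("line").size(), fit.vc_cov, fit.vc_order)
        ests.append(h.estimate)
        ses.append(h.se)
    assert 0.85 <= np.mean(ests) <= 0.95
    assert all(0 < se < 0.2 for se in ses)
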