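"""End-to-end orchestration: BLUEs -> joint linkage -> GWAS -> pleiotropy ->
loci resolution -> color models, in real-data or synthetic-validation mode.

Every stage writes TSV outputs with a provenance header into the run
directory and appends counts/wall time to a manifest; a rerun with the same
config and seed is byte-identical. Stages are resumable: with ``resume``,
a stage whose output file already exists is loaded instead of recomputed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import blues as bl
from . import color as cl
from . import gwas as gw
from . import io as nio
from . import linkage as jl
from . import loci as lc
from . import pleiotropy as pl
from . import sim
from .config import PipelineConfig

log = logging.getLogger("namqtl")

TRAITS = ("kernel_color", "zeaxanthin", "lutein", "total_carotenoids")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# Synthetic scenario
# ---------------------------------------------------------------------------

def synthetic_scenario(cfg: PipelineConfig) -> dict:
    """Simulate the full input bundle for the validation workflow.

    Three mapped QTL drive four traits: a branchpoint-like locus with
    antagonistic pleiotropy (raises kernel color and zeaxanthin, lowers
    lutein), an upstream-pathway locus raising all pigmented traits (with
    segregation distortion in one family), and a lutein-specific locus.
    Causal dense variants segregate in every family at the QTL positions,
    and gene annotations place one true gene at each causal variant among
    decoys.
    """
    rng = np.random.default_rng(cfg.seed)
    gmap = sim.simulate_map(cfg.n_chrom, cfg.chrom_length_cM, cfg.step_cM)

    def marker_at(chrom_wanted: int, frac: float):
        chrom = (chrom_wanted - 1) % cfg.n_chrom + 1
        sl = gmap.chrom_slice(chrom)
        row = sl.iloc[int(frac * (len(sl) - 1))]
        return str(row["marker"]), chrom, int(row["bp"])

    q1_marker, q1_chrom, q1_bp = marker_at(1, 0.5)
    q2_marker, q2_chrom, q2_bp = marker_at(2, 0.3)
    q3_marker, q3_chrom, q3_bp = marker_at(3, 0.7)
    distortion = [(q2_marker, "Z003", 0.3)]
    pop = sim.simulate_population(gmap, n_ril=cfg.n_ril,
                                  seed=int(rng.integers(2 ** 31)),
                                  distortion=distortion)
    fams = pop.family_ids()

    def fam_effects(base: float, spread: float, seed: int) -> dict:
        r = np.random.default_rng(seed)
        return {f: float(base + r.normal(0, spread)) for f in fams}

    s = cfg.seed
    qtl = [
        sim.QTL(q1_marker, {                      # branchpoint-like locus
            "kernel_color": fam_effects(1.0, 0.3, s + 11),
            "zeaxanthin": fam_effects(1.2, 0.3, s + 12),
            "lutein": fam_effects(-1.0, 0.3, s + 13),
        }),
        sim.QTL(q2_marker, {                      # upstream-pathway locus
            "kernel_color": fam_effects(0.8, 0.25, s + 21),
            "zeaxanthin": fam_effects(0.8, 0.25, s + 22),
            "total_carotenoids": fam_effects(1.2, 0.3, s + 23),
        }),
        sim.QTL(q3_marker, {                      # alpha-branch locus
            "lutein": fam_effects(1.0, 0.3, s + 31),
            "total_carotenoids": fam_effects(0.6, 0.2, s + 32),
        }),
    ]
    arch = sim.TraitArchitecture(
        qtl=qtl,
        h2_target={"kernel_color": 0.85, "zeaxanthin": 0.9,
                   "lutein": 0.8, "total_carotenoids": 0.85},
        sigma2_family=0.8, distortion=distortion)
    design = sim.FieldDesign(sigma2_set=0.1, sigma2_block=0.15,
                             rho_row=0.4, rho_range=0.3)
    plots = sim.simulate_traits(pop, arch, design,
                                seed=int(rng.integers(2 ** 31)))

    all_parents = frozenset(f.alt_parent for f in pop.families)
    causal = [
        sim.CausalVariant(q1_chrom, q1_bp, all_parents, "cv_branchpoint"),
        sim.CausalVariant(q2_chrom, q2_bp, all_parents, "cv_upstream"),
        sim.CausalVariant(q3_chrom, q3_bp, all_parents, "cv_alpha"),
    ]
    variants = sim.simulate_dense_variants(
        pop, cfg.variant_density_per_Mb, causal_spec=causal,
        seed=int(rng.integers(2 ** 31)))

    gene_rows = [("gene_branchpoint", q1_chrom, q1_bp - 10_000, q1_bp + 10_000),
                 ("gene_upstream", q2_chrom, q2_bp - 10_000, q2_bp + 10_000),
                 ("gene_alpha", q3_chrom, q3_bp - 10_000, q3_bp + 10_000)]
    span = int(gmap.table["bp"].max())
    for k in range(12):  # decoys spread over the genome
        c = k % cfg.n_chrom + 1
        start = int((0.04 + 0.9 * (k / 12)) * span)
        gene_rows.append((f"decoy_{k}", c, start, start + 20_000))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chrom", "start", "end"])
    apriori = {"gene_branchpoint", "gene_upstream", "gene_alpha",
               "decoy_1", "decoy_5"}
    return {"map": gmap, "pop": pop, "arch": arch, "design": design,
            "plots": plots, "variants": variants, "genes": genes,
            "apriori": apriori}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def blues_stage(plots: pd.DataFrame, cfg: PipelineConfig) -> tuple:
    """Structure selection, outlier removal, BLUEs, Box-Cox, heritability."""
    traits = sorted(plots["trait"].unique())
    wide = None
    herit_rows = []
    for trait in traits:
        cands = [()] + [(t,) for t in bl.usable_extra_terms(
            plots, trait, ("set", "block"))]
        structure, _ = bl.select_structure(
            plots, trait, cands, ("identity", "ar1_both"))
        flagged = bl.flag_outliers(plots, trait, structure,
                                   cfg.dffits_threshold)
        log.info("blues[%s]: structure=%s, %d outliers flagged",
                 trait, structure, len(flagged))
        clean = bl.remove_outliers(plots, flagged)
        tab = bl.compute_blues(clean, trait, structure)
        tab = bl.transform_blues(tab)
        col = tab.set_index("line")
        if wide is None:
            wide = col[["family"]].copy()
        wide[trait] = col["blue"]
        wide[f"{trait}__transformed"] = col["blue_transformed"]
        # heritability from the all-random final model
        drop = bl.degenerate_terms(clean, trait)
        fit = bl.fit_mixed(clean, structure, trait, drop_terms=drop,
                           compute_vc_cov=True)
        sub = clean[(clean["trait"] == trait) & clean["value"].notna()]
        per_line_env = sub.groupby("line")["year"].nunique()
        per_line_plots = sub.groupby("line")["value"].size()
        vc = dict(fit.variance_components)
        for g, p in fit.residual_params.items():
            vc[f"residual:{g}"] = p["sigma2"]
        h2 = bl.line_mean_heritability(vc, per_line_env, per_line_plots,
                                       fit.vc_cov, fit.vc_order)
        herit_rows.append((trait, h2.estimate, h2.se,
                           tab.attrs["lambda"], tab.attrs["shift"],
                           len(flagged)))
    herit = pd.DataFrame(herit_rows, columns=[
        "trait", "h2", "h2_se", "boxcox_lambda", "boxcox_shift",
        "n_outliers"])
    return wide.reset_index(), herit


def jl_stage(blues_wide: pd.DataFrame, md: jl.MarkerData,
             cfg: PipelineConfig, rng: np.random.Generator) -> tuple:
    """Permutation thresholds, stepwise search, pruning, re-scan, intervals,
    allelic effects and PVE for each trait."""
    traits = [c for c in blues_wide.columns if c.endswith("__transformed")]
    models, peak_rows, interval_rows, effect_tabs = {}, [], [], []
    for col in traits:
        trait = col[:-len("__transformed")]
        y = nio.blues_to_series(blues_wide, trait)
        seed = int(rng.integers(2 ** 31))
        entry = jl.jl_permutation_threshold(y, md, cfg.n_perm, cfg.alpha,
                                            seed)
        thr01 = jl.jl_permutation_threshold(y, md, cfg.n_perm,
                                            cfg.interval_alpha, seed)
        model = jl.stepwise_jl(y, md, entry, trait=trait)
        model = jl.prune_multicollinear(model, md, y, cfg.r_threshold)
        model = jl.rescan_peaks(model, md, y, thr01, cfg.interval_alpha)
        models[trait] = model
        log.info("jl[%s]: entry_p=%.3g, %d peaks", trait, entry,
                 len(model.peaks))
        if not model.peaks:
            continue
        pves = jl.pve(model, md, y).set_index("marker")["pve"]
        eff = jl.allelic_effects(model, md, y)
        eff.insert(0, "trait", trait)
        effect_tabs.append(eff)
        for m in model.peaks:
            mk = md.markers.at[m, "marker"]
            peak_rows.append((trait, mk, md.markers.at[m, "chrom"],
                              float(md.markers.at[m, "cM"]),
                              int(md.markers.at[m, "bp"]),
                              entry, float(pves[mk])))
            try:
                si = jl.support_interval(model, md, y, m, thr01,
                                         cfg.interval_alpha)
            except ValueError as e:
                log.warning("jl[%s]: interval for %s skipped (%s)",
                            trait, mk, e)
                continue
            interval_rows.append((trait, mk, si.chrom, si.left_cM,
                                  si.right_cM, si.left_bp, si.right_bp,
                                  float(pves[mk])))
    peaks = pd.DataFrame(peak_rows, columns=[
        "trait", "marker", "chrom", "cM", "bp", "entry_p", "pve"])
    intervals = pd.DataFrame(interval_rows, columns=[
        "trait", "peak_marker", "chrom", "left_cM", "right_cM",
        "left_bp", "right_bp", "pve"]).rename_axis("interval")
    effects = (pd.concat(effect_tabs, ignore_index=True) if effect_tabs
               else pd.DataFrame(columns=["trait", "marker", "family",
                                          "effect", "se"]))
    return models, peaks, intervals, effects


def gwas_stage(models: dict, blues_wide: pd.DataFrame, md: jl.MarkerData,
               variants: pd.DataFrame, pop: sim.NAMPopulation,
               cfg: PipelineConfig, rng: np.random.Generator) -> pd.DataFrame:
    proj = gw.project_variants(variants, pop)
    tabs = []
    for trait, model in models.items():
        y = nio.blues_to_series(blues_wide, trait)
        res_by_chrom = gw.chromosome_residuals(model, md, y)
        full_res = jl.model_residuals(md, y, model.peaks)
        thr = gw.gwas_threshold(full_res, proj, cfg.n_perm, cfg.fdr,
                                int(rng.integers(2 ** 31)))
        tab = gw.rmip_scan(res_by_chrom, proj, thr, cfg.n_iter,
                           cfg.subsample, seed=int(rng.integers(2 ** 31)),
                           report_at=cfg.rmip_report)
        tab.insert(0, "trait", trait)
        log.info("gwas[%s]: threshold=%.3g, %d reported variants", trait,
                 thr, int(tab["reported"].sum()))
        tabs.append(tab)
    return pd.concat(tabs, ignore_index=True)


def loci_stage(intervals: pd.DataFrame, rmip: pd.DataFrame,
               genes: pd.DataFrame | None, apriori: set | None,
               proj: gw.ProjectedVariants, cfg: PipelineConfig,
               seed: int) -> tuple:
    iv = intervals.rename(columns={"left_bp": "start", "right_bp": "end"})
    merged = lc.merge_intervals(iv[["chrom", "start", "end"]].assign(
        trait=iv["trait"].to_numpy()))
    merged["members"] = merged["members"].map(
        lambda ms: ",".join(str(m) for m in ms))
    reported = rmip[rmip["reported"]]
    ld = lc.ld_profile(proj.dosages, proj.meta,
                       reported["variant"].unique(), cfg.window_bp,
                       n_null=50_000, seed=seed)
    ld_summary = pd.DataFrame({
        "set": ["observed", "null"],
        "n_pairs": [len(ld["observed"]), len(ld["null"])],
        "mean_r2": [float(np.mean(ld["observed"])) if len(ld["observed"])
                    else np.nan,
                    float(np.mean(ld["null"])) if len(ld["null"]) else np.nan],
        "median_r2": [float(np.median(ld["observed"])) if len(ld["observed"])
                      else np.nan,
                      float(np.median(ld["null"])) if len(ld["null"])
                      else np.nan],
    })
    if genes is None or apriori is None:
        log.warning("loci: gene annotations or a-priori list missing; "
                    "gene resolution skipped")
        return merged, ld_summary, None
    cands = lc.resolve_genes(iv, rmip, genes, apriori, cfg.window_bp,
                             cfg.rmip_report)
    return merged, ld_summary, lc.candidate_genes_table(cands)


def color_stage(blues_wide: pd.DataFrame, cfg: PipelineConfig,
                response: str = "kernel_color") -> tuple:
    traits = [c[:-len("__transformed")] for c in blues_wide.columns
              if c.endswith("__transformed")]
    predictors = [f"{t}__transformed" for t in traits if t != response]
    tab = blues_wide.copy()
    resp = f"{response}__transformed"
    specs = {
        "full_with_family": {"predictors": predictors, "family": True},
        "full_no_family": {"predictors": predictors, "family": False},
        "reduced_with_family": {"predictors": predictors[:2], "family": True},
    }
    comparison = cl.compare_linear_models(tab, resp, specs)
    report = cl.fit_random_forest(tab, resp, predictors,
                                  test_fraction=cfg.test_fraction,
                                  n_trees=cfg.n_trees,
                                  seeds=range(cfg.n_rf_seeds))
    corr = cl.trait_correlation_matrix(blues_wide, traits)
    metrics = pd.DataFrame([{
        "rf_r2_test": report.rf_r2_test,
        "linear_r2_test": report.linear_r2_test,
        "baseline_error": report.baseline_error,
        "percent_accuracy": report.percent_accuracy,
        "n_seeds": report.n_seeds,
        "n_trees": report.n_trees,
    }])
    importances = report.importances.rename("importance").rename_axis(
        "feature").reset_index()
    return comparison, metrics, importances, corr


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute all stages in order, writing TSVs and a provenance manifest.

    Returns a dict of in-memory stage results. A stage failure raises
    ``StageError`` naming the stage; with ``resume`` (and unchanged config),
    stages whose outputs exist are loaded rather than recomputed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    rng = np.random.default_rng(cfg.seed)
    manifest = {"config_hash": h, "seed": cfg.seed, "stages": {}}
    results: dict = {}

    def record(stage, t0, **counts):
        manifest["stages"][stage] = {
            "wall_s": round(time.time() - t0, 2), **counts}
        log.info("stage %s done (%.1fs) %s", stage,
                 time.time() - t0, counts)

    def wrap(stage, fn):
        t0 = time.time()
        try:
            out = fn()
        except StageError:
            raise
        except Exception as e:
            raise StageError(stage, str(e)) from e
        return out, t0

    # ---- inputs ------------------------------------------------------------
    t0 = time.time()
    genes = apriori = None
    if cfg.mode == "synthetic-validation":
        scen, t0 = wrap("simulate", lambda: synthetic_scenario(cfg))
        gmap, pop, plots = scen["map"], scen["pop"], scen["plots"]
        variants, genes, apriori = (scen["variants"], scen["genes"],
                                    scen["apriori"])
        nio.write_map(gmap, outdir / "map.tsv", config_hash=h, seed=cfg.seed)
        nio.write_genotypes(pop, outdir / "genotypes.tsv", config_hash=h,
                            seed=cfg.seed)
        nio.write_plot_table(plots, outdir / "plots.tsv", config_hash=h,
                             seed=cfg.seed)
        nio.write_tsv(variants, outdir / "variants.tsv", "simulate",
                      config_hash=h, seed=cfg.seed)
        nio.write_tsv(genes, outdir / "genes.tsv", "simulate",
                      config_hash=h, seed=cfg.seed)
        nio.write_tsv(pd.DataFrame({"gene": sorted(apriori)}),
                      outdir / "apriori.tsv", "simulate", config_hash=h,
                      seed=cfg.seed)
        record("simulate", t0, n_lines=len(pop.genotypes),
               n_markers=gmap.n_markers, n_plots=len(plots),
               n_variants=len(variants))
    else:
        if not (cfg.map_path and cfg.genotypes_path):
            raise StageError("inputs", "real-data mode needs map and genotypes")
        gmap = nio.load_map(cfg.map_path)
        pop = nio.load_genotypes(cfg.genotypes_path, gmap)
        plots = (nio.load_plot_table(cfg.plots_path)
                 if cfg.plots_path else None)
        variants = (nio.read_tsv(cfg.variants_path)
                    if cfg.variants_path else None)
        if cfg.annotations_path:
            genes = (lc.read_bed(cfg.annotations_path)
                     if str(cfg.annotations_path).endswith(".bed")
                     else lc.read_gff3_genes(cfg.annotations_path))
        if cfg.apriori_path:
            apriori = set(nio.read_tsv(cfg.apriori_path)["gene"].astype(str))
        record("inputs", t0, n_markers=gmap.n_markers)

    # ---- blues ---------------------------------------------------------------
    blues_file = outdir / "blues.tsv"
    if cfg.blues_path:
        blues_wide = nio.load_blues(cfg.blues_path)
        herit = None
    elif resume and blues_file.exists():
        blues_wide = nio.load_blues(blues_file)
        herit = nio.read_tsv(outdir / "heritability.tsv")
    else:
        (blues_wide, herit), t0 = wrap(
            "blues", lambda: blues_stage(plots, cfg))
        nio.write_blues(blues_wide, blues_file, config_hash=h, seed=cfg.seed)
        nio.write_tsv(herit, outdir / "heritability.tsv", "blues",
                      config_hash=h, seed=cfg.seed)
        record("blues", t0, n_lines=len(blues_wide))
    results["blues"] = blues_wide
    results["heritability"] = herit

    # ---- joint linkage -------------------------------------------------------
    md = jl.marker_data_from_population(pop)
    (models, peaks, intervals, effects), t0 = wrap(
        "jl", lambda: jl_stage(blues_wide, md, cfg, rng))
    nio.write_tsv(peaks, outdir / "jl_peaks.tsv", "jl", config_hash=h,
                  seed=cfg.seed)
    nio.write_tsv(intervals, outdir / "jl_intervals.tsv", "jl",
                  config_hash=h, seed=cfg.seed)
    nio.write_tsv(effects, outdir / "jl_effects.tsv", "jl", config_hash=h,
                  seed=cfg.seed)
    record("jl", t0, n_peaks=len(peaks), n_intervals=len(intervals))
    results.update(models=models, jl_peaks=peaks, jl_intervals=intervals,
                   jl_effects=effects)

    # ---- GWAS ----------------------------------------------------------------
    if variants is not None:
        rmip, t0 = wrap("gwas", lambda: gwas_stage(
            models, blues_wide, md, variants, pop, cfg, rng))
        nio.write_tsv(rmip, outdir / "rmip.tsv", "gwas", config_hash=h,
                      seed=cfg.seed)
        record("gwas", t0, n_reported=int(rmip["reported"].sum()))
        results["rmip"] = rmip
    else:
        rmip = None
        log.warning("gwas: no variant panel provided; stage skipped")

    # ---- pleiotropy ------------------------------------------------------------
    blues_by_trait = {
        c[:-len("__transformed")]: nio.blues_to_series(
            blues_wide, c[:-len("__transformed")])
        for c in blues_wide.columns if c.endswith("__transformed")}
    pleio, t0 = wrap("pleiotropy", lambda: pl.pleiotropy_scan(
        models, blues_by_trait, md))
    nio.write_tsv(pleio, outdir / "pleiotropy.tsv", "pleiotropy",
                  config_hash=h, seed=cfg.seed)
    edge = pleio[pleio["significant"]][
        ["trait_a", "trait_b", "scope", "r", "q", "sign"]]
    nio.write_tsv(edge, outdir / "pleiotropy_edges.tsv", "pleiotropy",
                  config_hash=h, seed=cfg.seed)
    record("pleiotropy", t0, n_tests=len(pleio),
           n_significant=int(pleio["significant"].sum()))
    results["pleiotropy"] = pleio

    # ---- loci ------------------------------------------------------------------
    if rmip is not None and len(intervals):
        proj = gw.project_variants(variants, pop)
        (merged, ld_summary, cand), t0 = wrap("loci", lambda: loci_stage(
            intervals, rmip, genes, apriori, proj, cfg,
            int(rng.integers(2 ** 31))))
        nio.write_tsv(merged, outdir / "common_intervals.tsv", "loci",
                      config_hash=h, seed=cfg.seed)
        nio.write_tsv(ld_summary, outdir / "ld_summary.tsv", "loci",
                      config_hash=h, seed=cfg.seed)
        if cand is not None:
            nio.write_tsv(cand, outdir / "candidate_genes.tsv", "loci",
                          config_hash=h, seed=cfg.seed)
        record("loci", t0, n_common=len(merged),
               n_genes=(len(cand) if cand is not None else 0))
        results.update(common_intervals=merged, candidate_genes=cand,
                       ld_summary=ld_summary)

    # ---- color models -----------------------------------------------------------
    if "kernel_color" in blues_by_trait:
        (comparison, metrics, importances, corr), t0 = wrap(
            "color", lambda: color_stage(blues_wide, cfg))
        nio.write_tsv(comparison, outdir / "color_linear_models.tsv",
                      "color", config_hash=h, seed=cfg.seed)
        nio.write_tsv(metrics, outdir / "color_rf_metrics.tsv", "color",
                      config_hash=h, seed=cfg.seed)
        nio.write_tsv(importances, outdir / "color_rf_importances.tsv",
                      "color", config_hash=h, seed=cfg.seed)
        nio.write_tsv(corr.rename_axis("trait").reset_index(),
                      outdir / "trait_correlations.tsv", "color",
                      config_hash=h, seed=cfg.seed)
        record("color", t0, n_models=len(comparison))
        results.update(color_comparison=comparison, color_metrics=metrics,
                       color_importances=importances,
                       trait_correlations=corr)

    import namqtl
    manifest["version"] = getattr(namqtl, "__version__", "unknown")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
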