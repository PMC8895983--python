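"""Resampling GWAS on dense projected variants with RMIP scoring.

Dense founder variants are projected onto the RILs through the genetic map
(linear interpolation of parental-origin codes in cM, mapped through the two
founders' alleles), tested family-nested against chromosome-specific
joint-linkage residuals, thresholded by a permutation-derived false discovery
rate, and scored by the resample model inclusion probability (RMIP): the
number of times a variant enters the forward-selection model over 100
bootstrap iterations, each using 80% of the RILs sampled with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import (JLModel, MarkerData, NestedScan, align_phenotype,
                      model_residuals, permute_within_family)
from .sim import COMMON_PARENT, NAMPopulation


# ---------------------------------------------------------------------------
# Projection of founder variants onto RILs
# ---------------------------------------------------------------------------

@dataclass
class ProjectedVariants:
    """RIL x variant dosage panel; dosage in [0, 1] is the expected
    alternate-allele count per (haploid-equivalent) inbred genome."""

    meta: pd.DataFrame        # variant, chrom, bp, cM
    dosages: np.ndarray       # (n_lines, n_variants)
    line_ids: list
    fam_idx: np.ndarray
    fam_ids: list

    def as_marker_data(self) -> MarkerData:
        meta = self.meta.rename(columns={"variant": "marker"}).reset_index(
            drop=True)
        return MarkerData(self.dosages.copy(), self.fam_idx, self.fam_ids,
                          list(self.line_ids), meta)


def project_variants(dense_variants: pd.DataFrame,
                     pop: NAMPopulation) -> ProjectedVariants:
    """Project founder variant alleles onto RILs via the genetic map.

    Within each family the RIL dosage is the linear cM-interpolation of the
    parental-origin codes between the flanking map markers, mapped through
    the common and alternate parents' alleles at the variant; positions
    outside the map span take the nearest marker's codes. Variants at which
    all founders carry the same allele are dropped.
    """
    founders = [COMMON_PARENT] + [f.alt_parent for f in pop.families]
    missing = [f for f in founders if f not in dense_variants.columns]
    if missing:
        raise ValueError(f"founder columns missing from variant table: {missing}")
    alle = dense_variants[founders].to_numpy(dtype=float)
    poly = alle.var(axis=1) > 0
    dv = dense_variants[poly].reset_index(drop=True)
    alle = alle[poly]

    geno = pop.genotypes.to_numpy(dtype=float)
    lines = list(pop.genotypes.index)
    fam_ids = pop.family_ids()
    fam_code = {f: i for i, f in enumerate(fam_ids)}
    fam_idx = pop.family_of.map(fam_code).to_numpy()
    fam_rows = [np.flatnonzero(fam_idx == i) for i in range(len(fam_ids))]

    n = len(lines)
    dos = np.empty((n, len(dv)))
    cm_out = np.empty(len(dv))
    mtab = pop.gmap.table.reset_index(drop=True)
    for chrom, vsub in dv.groupby("chrom", sort=False):
        msk = mtab["chrom"] == chrom
        if not msk.any():
            raise ValueError(f"variant chromosome {chrom!r} not on map")
        mcols = np.flatnonzero(msk.to_numpy())
        mcm = mtab.loc[msk, "cM"].to_numpy(dtype=float)
        if not np.all(np.diff(mcm) > 0):
            raise ValueError("map cM positions are unordered")
        mbp = mtab.loc[msk, "bp"].to_numpy(dtype=float)
        vbp = vsub["bp"].to_numpy(dtype=float)
        vcm = np.interp(vbp, mbp, mcm)     # clamps outside span: nearest end
        j = np.clip(np.searchsorted(mcm, vcm, side="right") - 1, 0,
                    len(mcm) - 2)
        w = (vcm - mcm[j]) / (mcm[j + 1] - mcm[j])
        w = np.clip(w, 0.0, 1.0)
        origin = (geno[:, mcols[j]] * (1.0 - w)
                  + geno[:, mcols[j + 1]] * w)     # (n, n_var_chrom)
        vv = vsub.index.to_numpy()
        cm_out[vv] = vcm
        b73 = alle[vv, 0]
        for fi, rows in enumerate(fam_rows):
            alt = alle[vv, fi + 1]
            dos[np.ix_(rows, vv)] = b73 + origin[rows] * (alt - b73)
    meta = dv[["variant", "chrom", "bp"]].copy()
    meta["cM"] = cm_out
    return ProjectedVariants(meta, dos, lines, fam_idx, fam_ids)


# ---------------------------------------------------------------------------
# Chromosome-specific residuals
# ---------------------------------------------------------------------------

def chromosome_residuals(model: JLModel, md: MarkerData, blues: pd.Series,
                         chroms=None) -> dict:
    """Per-chromosome residual phenotypes for GWAS.

    For each focal chromosome, the JL model is refit retaining the family
    term and all peaks EXCEPT those on that chromosome, so the focal
    chromosome's signal stays in its residuals while other chromosomes'
    signals are removed.
    """
    if chroms is None:
        chroms = pd.unique(md.markers["chrom"])
    peak_chrom = {m: md.markers.at[m, "chrom"] for m in model.peaks}
    out = {}
    for c in chroms:
        keep = [m for m in model.peaks if peak_chrom[m] != c]
        out[c] = model_residuals(md, blues, keep)
    return out


# ---------------------------------------------------------------------------
# Permutation FDR threshold
# ---------------------------------------------------------------------------

def gwas_threshold(residuals: pd.Series, variants: ProjectedVariants,
                   n_perm: int = 1000, fdr: float = 0.05, seed: int = 0,
                   ) -> float:
    """Per-trait significance threshold at a target empirical-null FDR.

    Joint-linkage residuals are permuted within family; each permutation is
    scanned over all variants, giving the null p-value distribution. The
    threshold is the largest observed p-value t such that the expected null
    count of p <= t per scan, divided by the observed count of p <= t, is at
    most ``fdr``. Deterministic given the seed; monotone non-increasing as
    ``fdr`` decreases.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if fdr >= 1.0:
        return 1.0
    vmd = variants.as_marker_data()
    sub, y = align_phenotype(vmd, residuals)
    if np.var(y) <= 0:
        raise ValueError("residual phenotype is constant")
    rng = np.random.default_rng(seed)
    scan = NestedScan(sub, model=())
    _, p_obs, _ = scan.stats(y)
    Y = permute_within_family(y, sub.fam_rows, n_perm, rng)
    _, p_null, _ = scan.stats(Y)
    null_flat = np.sort(p_null.ravel())
    cand = np.sort(p_obs)
    n_obs = np.arange(1, len(cand) + 1)
    e_fp = np.searchsorted(null_flat, cand, side="right") / n_perm
    ok = np.flatnonzero(e_fp / n_obs <= fdr)
    if ok.size == 0:
        # below the smallest observed p: interpolate from the null alone
        k = max(int(np.floor(fdr * n_perm)), 1) - 1
        mins = np.sort(p_null.min(axis=0))
        return float(mins[k])
    return float(cand[ok[-1]])


# ---------------------------------------------------------------------------
# RMIP resampling scan
# ---------------------------------------------------------------------------

def _subset_rows(vmd: MarkerData, rows: np.ndarray) -> MarkerData:
    return MarkerData(vmd.geno[rows].copy(), vmd.fam_idx[rows],
                      vmd.fam_ids, [vmd.line_ids[i] for i in rows],
                      vmd.markers)


def _forward_select(vmd: MarkerData, y: np.ndarray, cand: np.ndarray,
                    threshold: float, max_terms: int) -> list:
    model: list = []
    while len(model) < max_terms:
        remaining = np.setdiff1d(cand, model)
        if remaining.size == 0:
            break
        scan = NestedScan(vmd, model=model, candidates=remaining)
        _, pvals, _ = scan.stats(y)
        j = int(np.argmin(pvals))
        if pvals[j] <= threshold:
            model.append(int(remaining[j]))
        else:
            break
    return model


def rmip_scan(residuals_by_chrom: dict, variants: ProjectedVariants,
              threshold: float, n_iter: int = 100, subsample: float = 0.8,
              replace: bool = True, seed: int = 0, max_terms_per_chrom: int = 10,
              report_at: int = 5) -> pd.DataFrame:
    """Resample model inclusion probabilities.

    Per iteration, ceil(subsample * N) RILs are drawn (with replacement by
    default, honoring the bootstrap protocol); per chromosome, variants are
    added by forward selection against that chromosome's residuals while the
    best partial-F p-value passes ``threshold``. RMIP is the inclusion count
    over the iterations (an integer percent when n_iter = 100); the reported
    flag marks RMIP >= ``report_at``.
    """
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if n_iter != 100:
        warnings.warn("RMIP is conventionally a percentage over exactly 100 "
                      f"iterations; n_iter={n_iter} changes its scale")
    rng = np.random.default_rng(seed)
    vmd = variants.as_marker_data()
    counts = np.zeros(vmd.n_markers, dtype=int)
    chroms = list(residuals_by_chrom)
    cand_by_chrom = {
        c: np.flatnonzero((vmd.markers["chrom"] == c).to_numpy())
        for c in chroms
    }
    aligned = {}
    for c in chroms:
        sub_md, y = align_phenotype(vmd, residuals_by_chrom[c])
        aligned[c] = (sub_md, y)
    for _ in range(n_iter):
        for c in chroms:
            sub_md, y = aligned[c]
            n = sub_md.n_lines
            k = int(np.ceil(subsample * n))
            rows = (rng.choice(n, size=k, replace=True) if replace
                    else rng.permutation(n)[:k])
            boot = _subset_rows(sub_md, rows)
            sel = _forward_select(boot, y[rows], cand_by_chrom[c],
                                  threshold, max_terms_per_chrom)
            counts[sel] += 1
    out = vmd.markers[["marker", "chrom", "bp"]].rename(
        columns={"marker": "variant"}).copy()
    out["rmip"] = counts
    out["reported"] = out["rmip"] >= report_at
    return out
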