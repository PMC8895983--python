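"""Multi-family joint stepwise linkage (JL) mapping on transformed BLUEs.

The model always carries a forced family term (one intercept per family);
marker effects are nested within family, i.e. each marker contributes one
slope per family in which it segregates. Marker entry/exit is governed by
partial F-tests against permutation-derived thresholds; selected models are
pruned for multicollinearity, peaks re-scanned to the local sum-of-squares
maximum, and summarized by allelic effects, support intervals and
segregation-distortion-aware PVE.

Genotypes are coded 0 (common parent) / 1 (alternate parent); the fitted
per-family slope is therefore the difference between parental genotype class
means, i.e. twice the allelic substitution effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .sim import GeneticMap, NAMPopulation

_SEG_EPS = 1e-12


# ---------------------------------------------------------------------------
# Marker data container
# ---------------------------------------------------------------------------

@dataclass
class MarkerData:
    """Line-level genotypes aligned with family assignment and map positions.

    geno: (n_lines, n_markers) float array; missing codes are mean-imputed
    within family on construction (projection-based genotypes are continuous
    anyway). seg[f, m] flags markers truly segregating in family f.
    """

    geno: np.ndarray
    fam_idx: np.ndarray            # (n_lines,) integer family codes
    fam_ids: list
    line_ids: list
    markers: pd.DataFrame          # marker, chrom, cM, bp (cM/bp may be NaN)
    seg: np.ndarray = dc_field(init=False)
    fam_rows: list = dc_field(init=False)

    def __post_init__(self) -> None:
        self.fam_rows = [np.flatnonzero(self.fam_idx == f)
                         for f in range(len(self.fam_ids))]
        # within-family mean imputation of missing codes
        for rows in self.fam_rows:
            block = self.geno[rows]
            if np.isnan(block).any():
                mu = np.nanmean(block, axis=0)
                mu = np.where(np.isfinite(mu), mu, 0.0)
                ix = np.where(np.isnan(block))
                block[ix] = mu[ix[1]]
                self.geno[rows] = block
        self.seg = np.array([
            (self.geno[rows].var(axis=0) > _SEG_EPS) if rows.size
            else np.zeros(self.geno.shape[1], dtype=bool)
            for rows in self.fam_rows
        ])

    @property
    def n_lines(self) -> int:
        return self.geno.shape[0]

    @property
    def n_markers(self) -> int:
        return self.geno.shape[1]

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker {marker_id!r}")
        return int(idx[0])

    def subset_lines(self, line_ids: Sequence[str]) -> "MarkerData":
        pos = {l: i for i, l in enumerate(self.line_ids)}
        rows = np.array([pos[l] for l in line_ids])
        return MarkerData(self.geno[rows].copy(), self.fam_idx[rows],
                          self.fam_ids, list(line_ids), self.markers)


def marker_data_from_population(pop: NAMPopulation) -> MarkerData:
    fam_ids = pop.family_ids()
    fam_code = {f: i for i, f in enumerate(fam_ids)}
    fam_idx = pop.family_of.map(fam_code).to_numpy()
    meta = pop.gmap.table.reset_index(drop=True)
    return MarkerData(pop.genotypes.to_numpy(dtype=float).copy(), fam_idx,
                      fam_ids, list(pop.genotypes.index), meta)


def align_phenotype(md: MarkerData, blues: pd.Series) -> tuple:
    """Restrict marker data and phenotype to their common line set (order of
    the marker data preserved). Returns (MarkerData, y array)."""
    common = [l for l in md.line_ids if l in blues.index
              and np.isfinite(blues[l])]
    if not common:
        raise ValueError("no lines shared between genotypes and phenotype")
    sub = md.subset_lines(common)
    return sub, blues.loc[common].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Family-nested partial-F scan
# ---------------------------------------------------------------------------

def _design(md: MarkerData, model: Sequence[int]) -> np.ndarray:
    """Family intercepts plus family-nested columns of the model markers
    (segregating families only)."""
    n, F = md.n_lines, len(md.fam_ids)
    cols = [np.zeros(n) for _ in range(F)]
    for f, rows in enumerate(md.fam_rows):
        cols[f][rows] = 1.0
    for m in model:
        for f, rows in enumerate(md.fam_rows):
            if md.seg[f, m]:
                c = np.zeros(n)
                c[rows] = md.geno[rows, m]
                cols.append(c)
    return np.column_stack(cols)


def _ortho_basis(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    d = np.abs(np.diag(R))
    keep = d > 1e-9 * max(d.max(), 1.0)
    return Q[:, keep]


class NestedScan:
    """Partial F-tests of family-nested marker slopes given a base design.

    Precomputes, for the base design X0, everything that does not depend on
    the phenotype, so that scans over many permuted/resampled phenotypes are
    a single batched einsum.
    """

    def __init__(self, md: MarkerData, model: Sequence[int] = (),
                 candidates: np.ndarray | None = None):
        self.md = md
        self.model = list(model)
        self.cand = (np.arange(md.n_markers) if candidates is None
                     else np.asarray(candidates))
        self.Q = _ortho_basis(_design(md, self.model))
        self.p0 = self.Q.shape[1]
        F = len(md.fam_ids)
        M = len(self.cand)
        G = md.geno[:, self.cand]
        self.QtG = np.empty((F, self.p0, M))
        gn2 = np.empty((F, M))
        for f, rows in enumerate(md.fam_rows):
            self.QtG[f] = self.Q[rows].T @ G[rows]
            gn2[f] = np.einsum("ij,ij->j", G[rows], G[rows])
        seg = md.seg[:, self.cand]                      # (F, M)
        C = -np.einsum("fpm,gpm->mfg", self.QtG, self.QtG)
        C[:, np.arange(F), np.arange(F)] += gn2.T
        mask = seg.T                                    # (M, F)
        C *= mask[:, :, None] * mask[:, None, :]
        self.Cpinv = np.linalg.pinv(C, rcond=1e-10, hermitian=True)
        self.df1 = mask.sum(axis=1)                     # (M,)
        self.mask = mask
        self.G = G

    def stats(self, Y: np.ndarray) -> tuple:
        """F statistics and p-values for every candidate against each column
        of Y. Y: (n,) or (n, P). Returns (F, p, ss_add), each (M, P)."""
        md = self.md
        Y2 = Y[:, None] if Y.ndim == 1 else Y
        P = Y2.shape[1]
        M = len(self.cand)
        Fam = len(md.fam_ids)
        QtY = self.Q.T @ Y2                             # (p0, P)
        b = np.empty((M, Fam, P))
        for f, rows in enumerate(md.fam_rows):
            b[:, f, :] = self.G[rows].T @ Y2[rows] - \
                np.einsum("pm,pq->mq", self.QtG[f], QtY)
        b *= self.mask[:, :, None]
        ss_add = np.einsum("mfp,mfg,mgp->mp", b, self.Cpinv, b)
        rss0 = np.einsum("ip,ip->p", Y2, Y2) - np.einsum("pq,pq->q", QtY, QtY)
        df1 = np.maximum(self.df1, 1)[:, None]
        df2 = md.n_lines - self.p0 - df1
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = np.maximum(rss0[None, :] - ss_add, 1e-300)
            Fstat = (ss_add / df1) / (denom / np.maximum(df2, 1))
            pval = st.f.sf(Fstat, df1, np.maximum(df2, 1))
        pval = np.where(self.df1[:, None] == 0, 1.0, pval)
        if Y.ndim == 1:
            return Fstat[:, 0], pval[:, 0], ss_add[:, 0]
        return Fstat, pval, ss_add


def _tie_order(md: MarkerData, idx: np.ndarray) -> np.ndarray:
    """Stable order for equal p-values: lower chromosome, then lower cM."""
    chrom = pd.factorize(md.markers["chrom"], sort=True)[0][idx]
    cm = md.markers["cM"].to_numpy(dtype=float)[idx]
    return np.lexsort((cm, chrom))


def _best_candidate(md: MarkerData, scan: NestedScan, y: np.ndarray) -> tuple:
    _, pvals, _ = scan.stats(y)
    best_p = np.nanmin(pvals)
    ties = scan.cand[np.flatnonzero(pvals <= best_p * (1 + 1e-12))]
    ties = ties[_tie_order(md, ties)]
    return int(ties[0]), float(best_p)


# ---------------------------------------------------------------------------
# Permutation entry threshold
# ---------------------------------------------------------------------------

def permute_within_family(y: np.ndarray, fam_rows: Sequence[np.ndarray],
                          n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_perm) matrix of phenotypes shuffled within each family,
    preserving family means under the null."""
    Y = np.tile(y[:, None], (1, n_perm))
    for rows in fam_rows:
        for j in range(n_perm):
            Y[rows, j] = y[rng.permutation(rows)]
    return Y


def jl_permutation_threshold(blues: pd.Series, md: MarkerData,
                             n_perm: int = 1000, alpha: float = 0.05,
                             seed: int = 0) -> float:
    """Permutation-derived stepwise entry threshold.

    Phenotypes are permuted within family; for each permutation the minimum
    partial-F p-value over all markers (family term fixed) is recorded, and
    the threshold is the empirical alpha-quantile of those minima (the
    floor(alpha * n_perm)-th smallest).
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if n_perm * alpha < 1:
        raise ValueError("n_perm * alpha must be >= 1")
    sub, y = align_phenotype(md, blues)
    rng = np.random.default_rng(seed)
    scan = NestedScan(sub, model=())
    Y = permute_within_family(y, sub.fam_rows, n_perm, rng)
    _, pvals, _ = scan.stats(Y)
    minima = np.sort(pvals.min(axis=0))
    k = min(int(np.floor(alpha * n_perm)), n_perm) - 1
    return float(minima[max(k, 0)])


# ---------------------------------------------------------------------------
# Stepwise model search
# ---------------------------------------------------------------------------

@dataclass
class JLModel:
    trait: str
    peaks: list                    # marker column indices into MarkerData
    entry_p: float
    exit_p: float
    n_steps: int = 0

    def peak_markers(self, md: MarkerData) -> list:
        return [md.markers.at[m, "marker"] for m in self.peaks]


def _drop_one_pvalues(md: MarkerData, y: np.ndarray,
                      model: Sequence[int]) -> dict:
    out = {}
    for m in model:
        others = [k for k in model if k != m]
        scan = NestedScan(md, model=others, candidates=np.array([m]))
        _, p, ss = scan.stats(y)
        out[m] = (float(p[0]), float(ss[0]))
    return out


def stepwise_jl(blues: pd.Series, md: MarkerData, entry_p: float,
                exit_p: float | None = None, trait: str = "trait",
                max_steps: int = 200) -> JLModel:
    """Joint stepwise regression with the family term forced first.

    Forward: add the marker with the smallest partial-F p-value if it passes
    the entry threshold (ties broken toward lower chromosome then lower cM).
    Backward: remove any included marker whose drop-one p-value exceeds the
    exit threshold (worst first). Iterates to a fixed point.
    """
    if exit_p is None:
        exit_p = 2.0 * entry_p
    if exit_p < entry_p:
        raise ValueError("exit_p must be >= entry_p")
    sub, y = align_phenotype(md, blues)
    model: list = []
    steps = 0
    while True:
        steps += 1
        if steps > max_steps:
            raise RuntimeError(f"stepwise did not converge in {max_steps} steps")
        remaining = np.setdiff1d(np.arange(sub.n_markers), model)
        changed = False
        if remaining.size:
            scan = NestedScan(sub, model=model, candidates=remaining)
            best, best_p = _best_candidate(sub, scan, y)
            if best_p <= entry_p:
                model.append(best)
                changed = True
        # backward elimination to fixed point
        while len(model) > 1:
            stats = _drop_one_pvalues(sub, y, model)
            worst = max(model, key=lambda m: stats[m][0])
            if stats[worst][0] > exit_p:
                model.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return JLModel(trait=trait, peaks=sorted(model), entry_p=entry_p,
                   exit_p=exit_p, n_steps=steps)


# ---------------------------------------------------------------------------
# Multicollinearity pruning and peak re-scan
# ---------------------------------------------------------------------------

def prune_multicollinear(model: JLModel, md: MarkerData, y_blues: pd.Series,
                         r_threshold: float = 0.8) -> JLModel:
    """Remove, from each pair of model markers whose genotype-code Pearson
    correlation exceeds ``r_threshold`` in magnitude (strict), the member
    with the lower drop-one sum of squares; iterate and refit."""
    sub, y = align_phenotype(md, y_blues)
    peaks = list(model.peaks)
    while len(peaks) > 1:
        G = sub.geno[:, peaks]
        R = np.corrcoef(G.T)
        np.fill_diagonal(R, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
        if not np.abs(R[i, j]) > r_threshold:
            break
        stats = _drop_one_pvalues(sub, y, peaks)
        drop = peaks[i] if stats[peaks[i]][1] <= stats[peaks[j]][1] else peaks[j]
        peaks.remove(drop)
    return JLModel(model.trait, sorted(peaks), model.entry_p, model.exit_p,
                   model.n_steps)


@dataclass
class SupportInterval:
    trait: str
    peak_marker: str
    chrom: object
    left_cM: float
    right_cM: float
    left_bp: int
    right_bp: int
    alpha: float
    pve: float = np.nan
    member_markers: list = dc_field(default_factory=list)


def support_interval(model: JLModel, md: MarkerData, y_blues: pd.Series,
                     peak: int, threshold: float, alpha: float = 0.01,
                     ) -> SupportInterval:
    """Substitution-mapping support interval at the given significance level.

    Walking outward from the peak along its chromosome, a marker belongs to
    the interval while substituting it for the peak keeps its partial-F
    p-value at or below the alpha-level permutation threshold; bounds are the
    outermost qualifying markers (always on the peak's chromosome).
    """
    if peak not in model.peaks:
        raise ValueError("peak is not part of the model")
    sub, y = align_phenotype(md, y_blues)
    others = [m for m in model.peaks if m != peak]
    chrom = sub.markers.at[peak, "chrom"]
    on_chr = sub.markers.index[sub.markers["chrom"] == chrom].to_numpy()
    scan = NestedScan(sub, model=others, candidates=on_chr)
    _, pvals, _ = scan.stats(y)
    ok = dict(zip(on_chr.tolist(), pvals <= threshold))
    if not ok.get(peak, False):
        raise ValueError(
            f"peak {sub.markers.at[peak, 'marker']} itself fails the "
            f"alpha={alpha} threshold")
    pos = int(np.flatnonzero(on_chr == peak)[0])
    lo = pos
    while lo - 1 >= 0 and ok[on_chr[lo - 1]]:
        lo -= 1
    hi = pos
    while hi + 1 < len(on_chr) and ok[on_chr[hi + 1]]:
        hi += 1
    members = on_chr[lo:hi + 1].tolist()
    tab = sub.markers
    return SupportInterval(
        trait=model.trait, peak_marker=tab.at[peak, "marker"], chrom=chrom,
        left_cM=float(tab.at[members[0], "cM"]),
        right_cM=float(tab.at[members[-1], "cM"]),
        left_bp=int(tab.at[members[0], "bp"]),
        right_bp=int(tab.at[members[-1], "bp"]),
        alpha=alpha, member_markers=members)


def rescan_peaks(model: JLModel, md: MarkerData, y_blues: pd.Series,
                 threshold: float, alpha: float = 0.01,
                 max_rounds: int = 50) -> JLModel:
    """Iteratively substitute each peak by the in-interval marker with the
    largest drop-one sum of squares until every peak is a local SS maximum.
    Flat plateaus keep the leftmost (lowest-cM) plateau marker; a revisit of
    a previous model state raises (oscillation guard)."""
    sub, y = align_phenotype(md, y_blues)
    peaks = list(model.peaks)
    seen = {frozenset(peaks)}
    for _ in range(max_rounds):
        changed = False
        for i, peak in enumerate(list(peaks)):
            cur = JLModel(model.trait, peaks, model.entry_p, model.exit_p)
            try:
                si = support_interval(cur, sub, y_blues, peak, threshold, alpha)
            except ValueError:
                continue
            others = [m for m in peaks if m != peak]
            cand = np.array(si.member_markers)
            scan = NestedScan(sub, model=others, candidates=cand)
            _, _, ss = scan.stats(y)
            best_ss = ss.max()
            ties = cand[ss >= best_ss * (1 - 1e-12)]
            cms = sub.markers["cM"].to_numpy(dtype=float)[ties]
            best = int(ties[np.argmin(cms)])
            peak_ss = float(ss[np.flatnonzero(cand == peak)[0]])
            # move on strictly larger SS, or leftward along a flat plateau
            if best != peak and best_ss >= peak_ss * (1 - 1e-12):
                peaks[i] = best
                changed = True
        if not changed:
            break
        key = frozenset(peaks)
        if key in seen:
            raise RuntimeError("re-scan oscillated between model states")
        seen.add(key)
    return JLModel(model.trait, sorted(peaks), model.entry_p, model.exit_p,
                   model.n_steps)


# ---------------------------------------------------------------------------
# Allelic effects and PVE
# ---------------------------------------------------------------------------

def allelic_effects(model: JLModel, md: MarkerData,
                    y_blues: pd.Series) -> pd.DataFrame:
    """Family-nested allelic effect estimates at the model peaks.

    One row per (peak, family); the effect is the within-family slope on the
    0/1 parental-origin coding (difference between genotype class means;
    half of this is the per-allele substitution effect). Families in which
    the marker is monomorphic get missing estimates.
    """
    sub, y = align_phenotype(md, y_blues)
    X = _design(sub, model.peaks)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(len(y) - np.linalg.matrix_rank(X), 1)
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    ses = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0.0))
    rows = []
    pos = len(sub.fam_ids)
    for m in model.peaks:
        for f, fam in enumerate(sub.fam_ids):
            if sub.seg[f, m]:
                rows.append((sub.markers.at[m, "marker"], fam,
                             float(coef[pos]), float(ses[pos])))
                pos += 1
            else:
                rows.append((sub.markers.at[m, "marker"], fam,
                             np.nan, np.nan))
    return pd.DataFrame(rows, columns=["marker", "family", "effect", "se"])


def pve(model: JLModel, md: MarkerData, y_blues: pd.Series) -> pd.DataFrame:
    """Per-peak percent phenotypic variance explained, allowing for
    segregation distortion.

    Per QTL: sum over families of w_f * p_f (1 - p_f) * a_f^2 where p_f is
    the observed within-family alternate-allele frequency (not the Mendelian
    0.5), a_f the family-nested slope on 0/1 codes and w_f = n_f / N;
    divided by the variance of the transformed BLUEs. The model R^2 is
    reported alongside as ``total``.
    """
    sub, y = align_phenotype(md, y_blues)
    var_y = float(np.var(y, ddof=1))
    if var_y <= 0:
        raise ValueError("phenotype has zero variance")
    eff = allelic_effects(model, sub, y_blues)
    n = sub.n_lines
    rows = []
    for m in model.peaks:
        mk = sub.markers.at[m, "marker"]
        v = 0.0
        for f, fam in enumerate(sub.fam_ids):
            if not sub.seg[f, m]:
                continue
            g = sub.geno[sub.fam_rows[f], m]
            p_f = float(np.mean(g))
            w_f = len(g) / n
            a_f = eff.loc[(eff["marker"] == mk) & (eff["family"] == fam),
                          "effect"].iloc[0]
            v += w_f * p_f * (1.0 - p_f) * a_f ** 2
        rows.append((mk, v / var_y))
    X = _design(sub, model.peaks)
    Q = _ortho_basis(X)
    fitted_ss = float(np.sum((Q.T @ (y - y.mean())) ** 2))
    r2 = fitted_ss / (var_y * (n - 1))
    out = pd.DataFrame(rows, columns=["marker", "pve"])
    out.attrs["model_r2"] = r2
    return out


def model_residuals(md: MarkerData, y_blues: pd.Series,
                    peaks: Sequence[int]) -> pd.Series:
    """Residuals of the family + nested-peaks least-squares fit, indexed by
    line id."""
    sub, y = align_phenotype(md, y_blues)
    X = _design(sub, peaks)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ coef, index=sub.line_ids)
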