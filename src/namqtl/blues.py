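"""Per-line BLUEs from plot data via REML mixed models.

Workflow mirroring multi-environment NAM trials: fit a baseline mixed model
(family, line-within-family, year, field-within-year random), select extra
random terms and a spatial residual structure by BIC, flag influential
observations by DFFITS, re-fit with lines as fixed effects to obtain BLUEs,
Box-Cox transform, and estimate line-mean heritability with delta-method
standard errors.

REML is computed by direct maximization of the restricted likelihood with
variance parameters on the log scale and AR1 correlations through an atanh
reparameterization, using analytic score equations. Residual structures are
blocked by field-within-year; the AR1 x AR1 structure has covariance
sigma^2 * rho_row^|d_row| * rho_range^|d_range| between plots of the same
field, i.e. the Kronecker AR1(rho_range) x AR1(rho_row) form evaluated on
the occupied grid cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.stats as st

#: Random terms always present (the baseline model).
BASELINE_TERMS = ("family", "line", "year", "field")
#: Candidate additional random terms.
EXTRA_TERMS = ("plate", "set", "block", "family_year", "line_year")
RESIDUAL_KINDS = ("identity", "ar1_range", "ar1_row", "ar1_both")


def _term_labels(plots: pd.DataFrame, term: str) -> pd.Series:
    """Grouping labels for a random term; nested ids are pre-combined."""
    if term in ("family", "line", "year", "field", "set", "block", "plate"):
        return plots[term].astype(str)
    if term == "family_year":
        return plots["family"].astype(str) + ":" + plots["year"].astype(str)
    if term == "line_year":
        return plots["line"].astype(str) + ":" + plots["year"].astype(str)
    raise KeyError(f"unknown random term {term!r}")


@dataclass(frozen=True)
class ModelStructure:
    """Random-term set (baseline always included) plus one residual structure."""

    extra_terms: tuple = ()
    residual: str = "identity"

    def __post_init__(self) -> None:
        unknown = set(self.extra_terms) - set(EXTRA_TERMS) - set(BASELINE_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        if self.residual not in RESIDUAL_KINDS:
            raise ValueError(f"unknown residual structure {self.residual!r}")

    @property
    def random_terms(self) -> tuple:
        extras = tuple(t for t in self.extra_terms if t not in BASELINE_TERMS)
        return BASELINE_TERMS + extras


@dataclass
class FitResult:
    loglik: float
    bic: float
    variance_components: dict          # term -> sigma^2
    residual_params: dict              # group -> {"sigma2":, "rho_row":, "rho_range":}
    fixed_effects: pd.DataFrame        # index term, columns estimate/se
    n_obs: int
    n_params: int
    structure: ModelStructure
    converged: bool
    n_iter: int
    vc_cov: np.ndarray | None = None   # covariance of variance parameters
    vc_order: list = dc_field(default_factory=list)
    trait: str | None = None


class _REMLProblem:
    """Dense REML machinery for one trait's plot table."""

    def __init__(self, plots: pd.DataFrame, trait: str,
                 structure: ModelStructure, fixed_X: np.ndarray | None = None,
                 drop_terms: Sequence[str] = ()):
        sub = plots[plots["trait"] == trait]
        sub = sub[np.isfinite(sub["value"].to_numpy(dtype=float))]
        if sub.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        self.plots = sub.reset_index(drop=True)
        self.trait = trait
        self.structure = structure
        self.y = self.plots["value"].to_numpy(dtype=float)
        self.n = len(self.y)
        self.X = np.ones((self.n, 1)) if fixed_X is None else fixed_X
        self.p = self.X.shape[1]

        self.terms = [t for t in structure.random_terms if t not in drop_terms]
        self.G = []
        for t in self.terms:
            labels = _term_labels(self.plots, t)
            if labels.nunique() < 2:
                raise ValueError(
                    f"random term {t!r} has fewer than 2 levels; drop it")
            Z = pd.get_dummies(labels).to_numpy(dtype=float)
            self.G.append(Z @ Z.T)

        # residual blocks
        if structure.residual == "identity":
            group_col = self.plots["year"].astype(str)
        else:
            group_col = self.plots["field"].astype(str)
        self.res_groups = []
        for g, idx in self.plots.groupby(group_col, sort=True).groups.items():
            ii = np.asarray(idx)
            dr = dc = None
            if structure.residual != "identity":
                row = self.plots.loc[ii, "row"].to_numpy(dtype=float)
                rng_ = self.plots.loc[ii, "range"].to_numpy(dtype=float)
                dr = np.abs(row[:, None] - row[None, :])
                dc = np.abs(rng_[:, None] - rng_[None, :])
            self.res_groups.append((str(g), ii, dr, dc))
        self.use_row = structure.residual in ("ar1_row", "ar1_both")
        self.use_range = structure.residual in ("ar1_range", "ar1_both")
        self.n_rho = int(self.use_row) + int(self.use_range)

        # parameter layout: log s2 per term, then per group (log s2, atanh rhos)
        self.k_terms = len(self.terms)
        self.k_groups = len(self.res_groups)
        self.k = self.k_terms + self.k_groups * (1 + self.n_rho)

    # -- parameter packing ---------------------------------------------------
    def start(self) -> np.ndarray:
        v0 = np.var(self.y) / (self.k_terms + 1)
        v0 = max(v0, 1e-6)
        theta = np.full(self.k_terms, np.log(v0)).tolist()
        for _ in range(self.k_groups):
            theta.append(np.log(v0))
            theta.extend([0.0] * self.n_rho)
        return np.array(theta)

    def _rho_pair(self, rhos: list) -> tuple:
        """(rho_row, rho_range); a dimension without AR1 is pinned at 0, so
        its factor rho^d reduces to the identity indicator [d == 0]."""
        ri = 0
        rho_row = rho_range = 0.0
        if self.use_row:
            rho_row = rhos[ri]; ri += 1
        if self.use_range:
            rho_range = rhos[ri]
        return rho_row, rho_range

    def _residual_block(self, ls2: float, rhos: list, dr, dc):
        s2 = np.exp(ls2)
        if dr is None:
            return None, s2  # identity group: diagonal s2
        rho_row, rho_range = self._rho_pair(rhos)
        C = rho_row ** dr * rho_range ** dc
        return s2 * C, s2

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for j in range(self.k_terms):
            V += np.exp(theta[j]) * self.G[j]
        pos = self.k_terms
        for (_, ii, dr, dc) in self.res_groups:
            ls2 = theta[pos]
            rhos = [np.tanh(theta[pos + 1 + r]) for r in range(self.n_rho)]
            block, s2 = self._residual_block(ls2, rhos, dr, dc)
            if block is None:
                V[ii, ii] += s2
            else:
                V[np.ix_(ii, ii)] += block
            pos += 1 + self.n_rho
        V[np.diag_indices_from(V)] += 1e-8 * max(np.var(self.y), 1.0)
        return V

    # -- REML objective and score --------------------------------------------
    def reml(self, theta: np.ndarray, grad: bool = True):
        V = self.build_V(theta)
        try:
            cf = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            bad = np.full(self.k, np.nan)
            return np.inf, bad
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vinv = sla.cho_solve(cf, np.eye(self.n), check_finite=False)
        VX = Vinv @ self.X
        XtVX = self.X.T @ VX
        cfx = sla.cho_factor(XtVX, lower=True, check_finite=False)
        logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        beta = sla.cho_solve(cfx, VX.T @ self.y, check_finite=False)
        Py = Vinv @ self.y - VX @ beta
        quad = float(self.y @ Py)
        nll = 0.5 * ((self.n - self.p) * np.log(2 * np.pi)
                     + logdetV + logdetX + quad)
        if not grad:
            return nll, None
        # P = Vinv - VX (X'VinvX)^-1 VX'
        P = Vinv - VX @ sla.cho_solve(cfx, VX.T, check_finite=False)
        g = np.empty(self.k)
        for j in range(self.k_terms):
            Vj = np.exp(theta[j]) * self.G[j]
            g[j] = 0.5 * (np.sum(P * Vj) - Py @ Vj @ Py)
        pos = self.k_terms
        for (_, ii, dr, dc) in self.res_groups:
            ls2 = theta[pos]
            rhos = [np.tanh(theta[pos + 1 + r]) for r in range(self.n_rho)]
            block, s2 = self._residual_block(ls2, rhos, dr, dc)
            Psub = P[np.ix_(ii, ii)]
            Pysub = Py[ii]
            if block is None:
                dV = s2 * np.eye(len(ii))
            else:
                dV = block
            g[pos] = 0.5 * (np.sum(Psub * dV) - Pysub @ dV @ Pysub)
            if self.n_rho:
                rho_row, rho_range = self._rho_pair(rhos)
                r = 0
                for is_row in (True, False):
                    if (is_row and not self.use_row) or \
                       (not is_row and not self.use_range):
                        continue
                    rho = rho_row if is_row else rho_range
                    D = dr if is_row else dc
                    Do = dc if is_row else dr
                    rho_o = rho_range if is_row else rho_row
                    other = rho_o ** Do
                    # d/d rho of rho^D (distances are integers; exact at rho=0)
                    dpow = D * rho ** np.maximum(D - 1.0, 0.0)
                    dpow[D == 0] = 0.0
                    dV = s2 * dpow * other * (1.0 - rho ** 2)  # atanh chain rule
                    g[pos + 1 + r] = 0.5 * (np.sum(Psub * dV)
                                            - Pysub @ dV @ Pysub)
                    r += 1
            pos += 1 + self.n_rho
        return nll, g

    def fixed_solution(self, theta: np.ndarray):
        V = self.build_V(theta)
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        Vinv_X = sla.cho_solve(cf, self.X, check_finite=False)
        XtVX = self.X.T @ Vinv_X
        cov = np.linalg.pinv(XtVX)
        beta = cov @ (Vinv_X.T @ self.y)
        return beta, cov


def fit_mixed(plots: pd.DataFrame, structure: ModelStructure, trait: str,
              fixed_X: np.ndarray | None = None,
              fix_rho: float | None = None,
              compute_vc_cov: bool = False,
              drop_terms: Sequence[str] = (),
              maxiter: int = 200) -> FitResult:
    """REML fit of one trait under the given random/residual structure.

    ``fix_rho`` pins every AR1 correlation at the given value instead of
    estimating it (used for structure-equivalence checks). ``drop_terms``
    removes named baseline terms that the design cannot support (e.g. a
    single-year trial). Raises on random terms with fewer than 2 levels and
    reports non-convergence with the iteration count in the result.
    """
    prob = _REMLProblem(plots, trait, structure, fixed_X=fixed_X,
                        drop_terms=drop_terms)
    theta0 = prob.start()

    if fix_rho is not None and prob.n_rho > 0:
        rho_idx = []
        pos = prob.k_terms
        for _ in range(prob.k_groups):
            rho_idx.extend(range(pos + 1, pos + 1 + prob.n_rho))
            pos += 1 + prob.n_rho
        rho_idx = np.array(rho_idx, dtype=int)
        free = np.setdiff1d(np.arange(prob.k), rho_idx)
        pinned = np.arctanh(np.clip(fix_rho, -0.999, 0.999))

        def expand(tf):
            th = np.empty(prob.k)
            th[free] = tf
            th[rho_idx] = pinned
            return th

        def fun(tf):
            nll, g = prob.reml(expand(tf))
            return nll, (g[free] if g is not None else None)

        res = opt.minimize(fun, theta0[free], jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter})
        theta = expand(res.x)
        n_free = len(free)
    else:
        res = opt.minimize(lambda t: prob.reml(t), theta0, jac=True,
                           method="L-BFGS-B", options={"maxiter": maxiter})
        theta = res.x
        n_free = prob.k

    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(
            f"REML did not converge for {trait!r} after {res.nit} iterations")
    loglik = -float(res.fun)

    vcs = {t: float(np.exp(theta[j])) for j, t in enumerate(prob.terms)}
    resid = {}
    pos = prob.k_terms
    for (gname, _, _, _) in prob.res_groups:
        entry = {"sigma2": float(np.exp(theta[pos]))}
        r = 0
        if prob.use_row:
            entry["rho_row"] = float(np.tanh(theta[pos + 1 + r])); r += 1
        if prob.use_range:
            entry["rho_range"] = float(np.tanh(theta[pos + 1 + r]))
        resid[gname] = entry
        pos += 1 + prob.n_rho

    beta, cov = prob.fixed_solution(theta)
    fe = pd.DataFrame({"estimate": beta,
                       "se": np.sqrt(np.maximum(np.diag(cov), 0.0))})

    bic = -2.0 * loglik + n_free * np.log(prob.n)

    vc_cov = None
    vc_order = prob.terms + [f"residual:{g}" for (g, _, _, _) in prob.res_groups]
    if compute_vc_cov:
        vc_cov = _vc_covariance(prob, theta)

    return FitResult(loglik=loglik, bic=float(bic), variance_components=vcs,
                     residual_params=resid, fixed_effects=fe, n_obs=prob.n,
                     n_params=n_free, structure=structure,
                     converged=bool(res.success), n_iter=int(res.nit),
                     vc_cov=vc_cov, vc_order=vc_order, trait=trait)


def _vc_covariance(prob: _REMLProblem, theta: np.ndarray) -> np.ndarray:
    """Covariance of (term sigma^2s, group residual sigma^2s) by the observed
    information of the REML likelihood, finite-differenced on the score and
    mapped from the log scale through the Jacobian."""
    # indices of variance (not correlation) parameters
    var_idx = list(range(prob.k_terms))
    pos = prob.k_terms
    for _ in range(prob.k_groups):
        var_idx.append(pos)
        pos += 1 + prob.n_rho
    var_idx = np.array(var_idx)
    h = 1e-4
    H = np.zeros((prob.k, prob.k))
    for j in range(prob.k):
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        _, gp = prob.reml(tp)
        _, gm = prob.reml(tm)
        H[:, j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    C_u = np.linalg.pinv(H)
    J = np.exp(theta[var_idx])  # d sigma^2 / d log sigma^2
    C = C_u[np.ix_(var_idx, var_idx)] * np.outer(J, J)
    return C


# ---------------------------------------------------------------------------
# Structure selection
# ---------------------------------------------------------------------------

def usable_extra_terms(plots: pd.DataFrame, trait: str,
                       candidates: Sequence[str] = EXTRA_TERMS) -> list:
    """Candidate terms having >= 2 levels among this trait's observations."""
    sub = plots[(plots["trait"] == trait)
                & np.isfinite(plots["value"].to_numpy(dtype=float))]
    out = []
    for t in candidates:
        try:
            if _term_labels(sub, t).nunique() >= 2:
                out.append(t)
        except KeyError:
            pass
    return out


def select_structure(plots: pd.DataFrame, trait: str,
                     candidate_random: Sequence[Sequence[str]],
                     candidate_residual: Sequence[str] = RESIDUAL_KINDS,
                     ) -> tuple:
    """Two-stage BIC structure selection.

    Stage 1: among the explicit candidate extra-random-term sets (identity
    residual), keep the minimum-BIC set. Stage 2: conditional on that random
    structure, keep the minimum-BIC residual structure. Ties break toward
    fewer parameters; selection is invariant to candidate ordering. Returns
    (ModelStructure, FitResult of the winning combination).
    """
    if not candidate_random or not candidate_residual:
        raise ValueError("candidate lists must be non-empty")
    drop = degenerate_terms(plots, trait)

    def keyed(cands, fit_of):
        results = []
        for cand in cands:
            try:
                f = fit_of(cand)
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as e:
                warnings.warn(f"candidate {cand!r} failed: {e}")
                continue
            results.append((f.bic, f.n_params, f))
        if not results:
            raise RuntimeError("all candidate structures failed to fit")
        results.sort(key=lambda r: (round(r[0], 6), r[1]))
        return results[0][2]

    best_rand = keyed(
        [tuple(sorted(c)) for c in candidate_random],
        lambda c: fit_mixed(plots, ModelStructure(c, "identity"), trait,
                            drop_terms=drop))
    extra = best_rand.structure.extra_terms
    best = keyed(
        list(candidate_residual),
        lambda r: (best_rand if r == "identity"
                   else fit_mixed(plots, ModelStructure(extra, r), trait,
                                  drop_terms=drop)))
    return best.structure, best


def degenerate_terms(plots: pd.DataFrame, trait: str) -> tuple:
    """Baseline terms the data cannot support (fewer than 2 levels)."""
    sub = plots[(plots["trait"] == trait)
                & np.isfinite(plots["value"].to_numpy(dtype=float))]
    return tuple(t for t in BASELINE_TERMS
                 if _term_labels(sub, t).nunique() < 2)


def default_random_candidates(plots: pd.DataFrame, trait: str) -> list:
    """Empty set plus each usable single extra term (kept small so the BIC
    comparison stays cheap on large tables; pass richer combinations
    explicitly if wanted)."""
    singles = usable_extra_terms(plots, trait)
    return [()] + [(t,) for t in singles]


# ---------------------------------------------------------------------------
# Outlier flagging (DFFITS)
# ---------------------------------------------------------------------------

def _fixed_design(plots: pd.DataFrame, structure: ModelStructure) -> np.ndarray:
    cols = [pd.get_dummies(_term_labels(plots, t), drop_first=(t != "family"))
            for t in structure.random_terms]
    X = pd.concat(cols, axis=1).to_numpy(dtype=float)
    return X


def flag_outliers(plots: pd.DataFrame, trait: str, structure: ModelStructure,
                  threshold: float | None = None) -> pd.Index:
    """Flag influential plot observations for one trait by |DFFITS|.

    DFFITS is computed from the fixed-effect projection of the final model
    (all model terms as fixed). Default threshold is the conventional
    2*sqrt(p/n). Returns the index labels of flagged rows of ``plots``;
    only this trait's rows can be flagged.
    """
    if threshold is not None and threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = (plots["trait"] == trait) & np.isfinite(
        plots["value"].to_numpy(dtype=float))
    sub = plots[mask]
    X = _fixed_design(sub, structure)
    y = sub["value"].to_numpy(dtype=float)
    n, p_full = X.shape
    # hat diagonal via economy QR (rank-deficiency safe through pivoted lstsq)
    Q, R_, = np.linalg.qr(X)
    keep = np.abs(np.diag(R_)) > 1e-10 * max(np.abs(np.diag(R_)).max(), 1.0)
    Q = Q[:, keep]
    h = np.einsum("ij,ij->i", Q, Q)
    h = np.clip(h, 0.0, 1.0 - 1e-10)
    resid = y - Q @ (Q.T @ y)
    p_eff = int(keep.sum())
    dof = max(n - p_eff, 1)
    s2 = float(resid @ resid) / dof
    # leave-one-out variance
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_i = np.maximum((s2 * dof - resid ** 2 / (1 - h)) / max(dof - 1, 1),
                          1e-300)
        t_i = resid / np.sqrt(s2_i * (1 - h))
        dffits = t_i * np.sqrt(h / (1 - h))
    if threshold is None:
        threshold = 2.0 * np.sqrt(p_eff / n)
    if not np.isfinite(threshold):
        return sub.index[[]]
    return sub.index[np.abs(dffits) > threshold]


def remove_outliers(plots: pd.DataFrame, flagged: pd.Index) -> pd.DataFrame:
    """Set flagged observations' values to missing (copy); other traits'
    records are untouched."""
    out = plots.copy()
    out.loc[flagged, "value"] = np.nan
    return out


# ---------------------------------------------------------------------------
# BLUEs
# ---------------------------------------------------------------------------

def compute_blues(plots: pd.DataFrame, trait: str, structure: ModelStructure,
                  ) -> pd.DataFrame:
    """Generalized-least-squares per-line BLUEs.

    Lines become (sparse) fixed effects; the remaining random terms and the
    selected residual structure are re-estimated by REML with the line design
    as the fixed part, and BLUEs are the GLS line coefficients. With no
    usable random terms and an identity residual this reduces to per-line
    arithmetic means. Returns a DataFrame (line, family, blue, se).
    """
    mask = (plots["trait"] == trait) & np.isfinite(
        plots["value"].to_numpy(dtype=float))
    sub = plots[mask].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    line_d = pd.get_dummies(sub["line"].astype(str))
    lines = list(line_d.columns)
    X = line_d.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("line effects are rank deficient")

    keep_random = [t for t in structure.random_terms
                   if t not in ("line", "family", "line_year")]
    keep_random = [t for t in keep_random
                   if _term_labels(sub, t).nunique() >= 2]
    if keep_random or structure.residual != "identity":
        eff_struct = ModelStructure(
            tuple(t for t in keep_random if t not in BASELINE_TERMS),
            structure.residual)
        prob = _REMLProblem.__new__(_REMLProblem)
        # build a reduced problem: random terms = keep_random only
        prob.plots = sub
        prob.trait = trait
        prob.structure = eff_struct
        prob.y = sub["value"].to_numpy(dtype=float)
        prob.n = len(prob.y)
        prob.X = X
        prob.p = X.shape[1]
        prob.terms = keep_random
        prob.G = []
        for t in keep_random:
            Z = pd.get_dummies(_term_labels(sub, t)).to_numpy(dtype=float)
            prob.G.append(Z @ Z.T)
        if eff_struct.residual == "identity":
            group_col = sub["year"].astype(str)
        else:
            group_col = sub["field"].astype(str)
        prob.res_groups = []
        for g, idx in sub.groupby(group_col, sort=True).groups.items():
            ii = np.asarray(idx)
            dr = dc = None
            if eff_struct.residual != "identity":
                row = sub.loc[ii, "row"].to_numpy(dtype=float)
                rng_ = sub.loc[ii, "range"].to_numpy(dtype=float)
                dr = np.abs(row[:, None] - row[None, :])
                dc = np.abs(rng_[:, None] - rng_[None, :])
            prob.res_groups.append((str(g), ii, dr, dc))
        prob.use_row = eff_struct.residual in ("ar1_row", "ar1_both")
        prob.use_range = eff_struct.residual in ("ar1_range", "ar1_both")
        prob.n_rho = int(prob.use_row) + int(prob.use_range)
        prob.k_terms = len(prob.terms)
        prob.k_groups = len(prob.res_groups)
        prob.k = prob.k_terms + prob.k_groups * (1 + prob.n_rho)
        res = opt.minimize(lambda t: prob.reml(t), prob.start(), jac=True,
                           method="L-BFGS-B", options={"maxiter": 200})
        beta, cov = prob.fixed_solution(res.x)
    else:
        beta, se_res = np.linalg.lstsq(X, sub["value"].to_numpy(dtype=float),
                                       rcond=None)[:2]
        counts = X.sum(axis=0)
        resid = sub["value"].to_numpy(dtype=float) - X @ beta
        dof = max(len(sub) - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = np.diag(s2 / counts)

    fam = sub.groupby("line")["family"].first()
    return pd.DataFrame({
        "line": lines,
        "family": [fam[l] for l in lines],
        "blue": beta,
        "se": np.sqrt(np.maximum(np.diag(cov), 0.0)),
    })


# ---------------------------------------------------------------------------
# Box-Cox transformation
# ---------------------------------------------------------------------------

LAMBDA_GRID = (-2.0, -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.0)


def boxcox(values, lam: float, shift: float = 0.0) -> np.ndarray:
    """Box-Cox power transform of (values + shift); strictly increasing.

    lam != 0: ((y+shift)^lam - 1)/lam; lam == 0: ln(y+shift).
    """
    y = np.asarray(values, dtype=float) + shift
    bad = np.flatnonzero(~(y > 0) & np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"non-positive shifted value at position {bad[0]} "
            f"(value {y[bad[0]] - shift}); increase shift")
    if lam == 0.0:
        return np.log(y)
    return (y ** lam - 1.0) / lam


def boxcox_inverse(z, lam: float, shift: float = 0.0) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if lam == 0.0:
        return np.exp(z) - shift
    return (lam * z + 1.0) ** (1.0 / lam) - shift


def choose_lambda(values, grid: Sequence[float] = LAMBDA_GRID) -> tuple:
    """'Convenient lambda': the grid value maximizing the Box-Cox profile
    log-likelihood, with an automatic positivity shift for non-positive data.
    Returns (lambda, shift)."""
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise ValueError("need at least 3 finite values")
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 0.001 * (y.max() - y.min() + 1.0)
    lls = [st.boxcox_llf(l, y + shift) for l in grid]
    return float(grid[int(np.argmax(lls))]), float(shift)


def transform_blues(blues: pd.DataFrame, value_col: str = "blue") -> pd.DataFrame:
    """Add Box-Cox transformed values with the chosen convenient lambda."""
    lam, shift = choose_lambda(blues[value_col])
    out = blues.copy()
    out["blue_transformed"] = boxcox(out[value_col], lam, shift)
    out.attrs["lambda"] = lam
    out.attrs["shift"] = shift
    return out


# ---------------------------------------------------------------------------
# Heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    estimate: float
    se: float


def _harmonic_mean(x) -> float:
    x = np.asarray(x, dtype=float)
    x = x[x > 0]
    return len(x) / np.sum(1.0 / x)


def line_mean_heritability(variance_components: Mapping[str, float],
                           n_env_per_line, n_plots_per_line,
                           vc_cov: np.ndarray | None = None,
                           vc_order: Sequence[str] | None = None,
                           ) -> HeritabilityEstimate:
    """Line-mean heritability h2 = s2_g / (s2_g + s2_ge/e + s2_err/p).

    s2_g is the line(-within-family) component, s2_ge the line-by-year
    component, s2_err the (mean) residual variance; e and p are harmonic
    means of per-line environment and plot counts. The SE is a first-order
    delta-method propagation of the variance-component covariance.
    """
    s2_g = float(variance_components.get("line", 0.0))
    s2_ge = float(variance_components.get("line_year", 0.0))
    res_keys = [k for k in variance_components if k.startswith("residual")]
    if res_keys:
        s2_err = float(np.mean([variance_components[k] for k in res_keys]))
    else:
        s2_err = float(variance_components.get("error", 0.0))
    e_bar = _harmonic_mean(np.atleast_1d(n_env_per_line))
    p_bar = _harmonic_mean(np.atleast_1d(n_plots_per_line))
    denom = s2_g + s2_ge / e_bar + s2_err / p_bar
    if denom <= 0:
        raise ValueError("total line-mean variance is zero")
    h2 = s2_g / denom
    se = 0.0
    if vc_cov is not None and vc_order is not None:
        grad = np.zeros(len(vc_order))
        for i, name in enumerate(vc_order):
            if name == "line":
                grad[i] = (denom - s2_g) / denom ** 2
            elif name == "line_year":
                grad[i] = -s2_g / (e_bar * denom ** 2)
            elif name.startswith("residual"):
                grad[i] = -s2_g / (p_bar * denom ** 2) / max(len(res_keys), 1)
        se = float(np.sqrt(max(grad @ vc_cov @ grad, 0.0)))
    return HeritabilityEstimate(float(np.clip(h2, 0.0, 1.0)), se)
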