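"""Pleiotropy between traits via correlation of family-nested allelic effects.

For a pair of traits (A, B), trait A's final joint-linkage model is refit
with trait B's transformed BLUEs as the phenotype, and the per-(peak, family)
allelic-effect estimates of the two fits are correlated — per peak (the
"interval" scope) and pooled genome-wide. Significance uses two-sided
Pearson p-values with Benjamini-Hochberg FDR adjustment across the whole
batch of tests at a 0.05 type-I error rate. Effects are standardized per
trait (divided by the SD of that trait's transformed BLUEs) before
correlation so traits on different Box-Cox scales are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .linkage import JLModel, MarkerData, allelic_effects


def cross_fit(model: JLModel, md: MarkerData, blues_other: pd.Series,
              ) -> pd.DataFrame:
    """Allelic effects of another trait at this model's peaks: identical
    model terms, phenotype swapped (line sets intersected)."""
    return allelic_effects(model, md, blues_other)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n, "too_few"
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan, n, "zero_variance"
    r, p = st.pearsonr(x, y)
    return float(r), float(p), n, "ok"


def effect_correlation(effects_a: pd.DataFrame, effects_b: pd.DataFrame,
                       trait_a: str, trait_b: str,
                       sd_a: float = 1.0, sd_b: float = 1.0) -> pd.DataFrame:
    """Correlate paired allelic effects per peak and genome-wide.

    ``effects_*`` are allelic-effect tables (marker, family, effect) from the
    same model terms; ``sd_*`` are the trait BLUE standard deviations used to
    standardize effects. Untestable scopes (fewer than 3 paired effects or a
    zero-variance vector) are kept with a status flag rather than raised.
    """
    merged = effects_a.merge(effects_b, on=["marker", "family"],
                             suffixes=("_a", "_b"))
    ea = merged["effect_a"].to_numpy(dtype=float) / sd_a
    eb = merged["effect_b"].to_numpy(dtype=float) / sd_b
    rows = []
    for mk, grp in merged.groupby("marker", sort=False):
        r, p, n, status = _pearson(
            grp["effect_a"].to_numpy(dtype=float) / sd_a,
            grp["effect_b"].to_numpy(dtype=float) / sd_b)
        rows.append((trait_a, trait_b, str(mk), r, p, n, status))
    r, p, n, status = _pearson(ea, eb)
    rows.append((trait_a, trait_b, "genome-wide", r, p, n, status))
    return pd.DataFrame(rows, columns=[
        "trait_a", "trait_b", "scope", "r", "p", "n_effects", "status"])


def pleiotropy_scan(models: dict, blues: dict, md: MarkerData,
                    standardize: bool = True, alpha: float = 0.05,
                    ) -> pd.DataFrame:
    """All ordered trait pairs: effects of each trait's model under every
    other trait's phenotype, correlated per peak and genome-wide, with BH-FDR
    q-values across the full batch. Both model directions are reported
    separately, never averaged.
    """
    sds = {t: (float(np.nanstd(b.to_numpy(dtype=float), ddof=1))
               if standardize else 1.0) for t, b in blues.items()}
    own = {t: allelic_effects(m, md, blues[t]) for t, m in models.items()
           if m.peaks}
    batches = []
    for ta, model_a in models.items():
        if not model_a.peaks:
            continue
        for tb in blues:
            if tb == ta:
                continue
            eff_b = cross_fit(model_a, md, blues[tb])
            batches.append(effect_correlation(own[ta], eff_b, ta, tb,
                                              sds[ta], sds[tb]))
    if not batches:
        return pd.DataFrame(columns=["trait_a", "trait_b", "scope", "r", "p",
                                     "n_effects", "status", "q",
                                     "significant", "sign"])
    out = pd.concat(batches, ignore_index=True)
    out["q"] = np.nan
    testable = out["status"] == "ok"
    if testable.any():
        out.loc[testable, "q"] = multipletests(
            out.loc[testable, "p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] <= alpha).fillna(False)
    out["sign"] = np.where(out["r"] > 0, "positive",
                           np.where(out["r"] < 0, "negative", "zero"))
    out.loc[~testable, "sign"] = "untestable"
    return out
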