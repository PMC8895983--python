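"""Shared fixtures: one mid-sized synthetic NAM panel reused across modules
(session scoped — tests must not mutate it)."""

import numpy as np
import pandas as pd
import pytest

from namqtl import linkage as jl
from namqtl import sim


@pytest.fixture(scope="session")
def gmap3():
    """3 chromosomes x 100 cM at 1 cM steps (~1 Mb/cM)."""
    return sim.simulate_map(3, 100, 1.0)


@pytest.fixture(scope="session")
def pop10(gmap3):
    """Ten families x 100 RILs on the 3-chromosome map."""
    return sim.simulate_population(gmap3, n_ril=100, seed=42)


@pytest.fixture(scope="session")
def md10(pop10):
    return jl.marker_data_from_population(pop10)


def qtl_phenotype(md, marker_id, pve_target, seed, effects=None):
    """Line-level phenotype with one QTL of a given within-family PVE.

    The QTL's explainable variance is its within-family variance (the family
    term absorbs between-family differences); noise is scaled so that this
    variance is ``pve_target`` of the total phenotypic variance.
    """
    rng = np.random.default_rng(seed)
    q = md.marker_index(marker_id)
    if effects is None:
        effects = rng.normal(1.0, 0.3, len(md.fam_ids))
    a = np.asarray(effects)[md.fam_idx]
    g = md.geno[:, q] * a
    gw = g - pd.Series(g).groupby(md.fam_idx).transform("mean").to_numpy()
    vw = gw.var()
    vb = g.var() - vw
    ve = vw / pve_target - vw - vb
    y = g + rng.normal(0, np.sqrt(max(ve, 0.0)), len(g))
    return pd.Series(y, index=md.line_ids), np.asarray(effects)
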