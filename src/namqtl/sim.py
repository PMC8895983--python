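"""Synthetic nested-association-mapping (NAM) data generator.

Emulates the statistical structure of a multi-family maize NAM experiment:
a dense consensus genetic map, biparental RIL families sharing one common
parent, family-nested QTL effects with cross-trait pleiotropy, optional
segregation distortion, a dense founder variant panel for projection-based
association testing, and an augmented incomplete-block field design over
multiple years/fields with spatially correlated (AR1 x AR1) plot error.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COMMON_PARENT = "B73"
#: Alternate parents of the ten yellow-to-orange grain NAM families.
DEFAULT_ALT_PARENTS = (
    "B97", "CML228", "CML52", "Hp301", "Ki11",
    "Ki3", "NC350", "NC358", "Oh7B", "Tx303",
)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: one row per marker with chrom, cM and bp position.

    Invariants (checked on construction): marker ids unique; cM and bp
    strictly increasing within each chromosome.
    """

    table: pd.DataFrame  # columns: marker, chrom, cM, bp

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chrom", "cM", "bp"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table must have columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if (t["cM"] < 0).any() or (t["bp"] < 0).any():
            raise ValueError("cM and bp positions must be non-negative")
        for chrom, grp in t.groupby("chrom", sort=False):
            if not grp["cM"].is_monotonic_increasing or grp["cM"].duplicated().any():
                raise ValueError(f"cM not strictly increasing on chrom {chrom}")
            if not grp["bp"].is_monotonic_increasing or grp["bp"].duplicated().any():
                raise ValueError(f"bp not strictly increasing on chrom {chrom}")

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chrom_slice(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def position(self, marker_id: str) -> tuple:
        row = self.table[self.table["marker"] == marker_id]
        if row.empty:
            raise KeyError(f"marker {marker_id!r} not on map")
        r = row.iloc[0]
        return r["chrom"], float(r["cM"]), int(r["bp"])


def simulate_map(n_chrom: int, length_cM: float, step_cM: float,
                 bp_per_cM: float = 1_000_000.0) -> GeneticMap:
    """Regular-grid consensus map: markers at 0, step, ..., length per chromosome.

    bp positions are round(cM * bp_per_cM); the default ~1 Mb/cM is of the
    order of the maize genome-wide average.
    """
    if n_chrom <= 0 or length_cM <= 0 or step_cM <= 0 or bp_per_cM <= 0:
        raise ValueError("all map arguments must be positive")
    if step_cM > length_cM:
        raise ValueError("step_cM must not exceed length_cM")
    pos = np.arange(0.0, length_cM + step_cM / 2, step_cM)
    pos = pos[pos <= length_cM + 1e-9]
    rows = []
    for c in range(1, n_chrom + 1):
        for i, p in enumerate(pos):
            rows.append((f"c{c}_m{i}", c, float(p), int(round(p * bp_per_cM))))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


# ---------------------------------------------------------------------------
# RIL families and population
# ---------------------------------------------------------------------------

def _ril_recomb_fraction(d_cM: np.ndarray) -> np.ndarray:
    """Observed recombination fraction between loci d cM apart in selfed RILs.

    Haldane single-meiosis fraction r = (1 - exp(-2d/100)) / 2, expanded for
    the extra effective meioses accumulated during inbreeding: R = 2r/(1+2r).
    """
    r = 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_family(gmap: GeneticMap, n_ril: int, seed: int) -> np.ndarray:
    """Simulate one biparental RIL family as parental-origin mosaics.

    Returns an (n_ril, n_markers) int8 array coded 0 = common-parent allele,
    1 = alternate-parent allele. Lines are fully inbred (no residual
    heterozygosity). Along each chromosome the origin process is a Markov
    chain whose marker-to-marker switch probability is the RIL-expanded
    recombination fraction, i.e. crossovers follow a Poisson (Haldane,
    no-interference) process with map expansion R = 2r/(1+2r).
    """
    if n_ril < 1:
        raise ValueError("n_ril must be >= 1")
    if gmap.n_markers == 0:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(seed)
    out = np.empty((n_ril, gmap.n_markers), dtype=np.int8)
    col = 0
    for chrom in gmap.chromosomes():
        cm = gmap.chrom_slice(chrom)["cM"].to_numpy()
        m = len(cm)
        geno = np.empty((n_ril, m), dtype=np.int8)
        geno[:, 0] = rng.integers(0, 2, size=n_ril)
        if m > 1:
            switch_p = _ril_recomb_fraction(np.diff(cm))
            switches = rng.random((n_ril, m - 1)) < switch_p
            # cumulative XOR of switch indicators gives the mosaic
            flips = np.cumsum(switches, axis=1) % 2
            geno[:, 1:] = geno[:, [0]] ^ flips.astype(np.int8)
        out[:, col:col + m] = geno
        col += m
    return out


def _apply_distortion(geno: np.ndarray, marker_idx: int, target_freq: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Viability-selection style segregation distortion at one locus.

    RILs are accept/reject resampled so the alternate-allele frequency at
    ``marker_idx`` is ``target_freq`` in expectation; rejected lines are
    replaced by lines redrawn (with replacement) from the accepted classes.
    Linkage structure around the locus is preserved because whole lines are
    kept or dropped.
    """
    if not 0.0 < target_freq < 1.0:
        raise ValueError("distortion target frequency must be in (0,1)")
    carrier = geno[:, marker_idx] == 1
    n = len(geno)
    n_alt_target = int(round(target_freq * n))
    alt_pool = np.flatnonzero(carrier)
    ref_pool = np.flatnonzero(~carrier)
    if len(alt_pool) == 0 or len(ref_pool) == 0:
        return geno  # already fixed; nothing to distort toward
    idx = np.concatenate([
        rng.choice(alt_pool, size=n_alt_target, replace=True),
        rng.choice(ref_pool, size=n - n_alt_target, replace=True),
    ])
    rng.shuffle(idx)
    return geno[idx]


@dataclass
class Family:
    family_id: str
    alt_parent: str
    ril_ids: list


@dataclass
class NAMPopulation:
    """Multi-family RIL panel on a shared map.

    genotypes: DataFrame indexed by RIL id, one column per marker, coded
    0 = common parent, 1 = alternate parent (0.5 would denote heterozygous /
    uncertain calls; the simulator emits fully inbred 0/1 lines).
    """

    families: list  # of Family
    genotypes: pd.DataFrame
    gmap: GeneticMap
    dense_variants: pd.DataFrame | None = None  # variant, chrom, bp, founder cols

    def __post_init__(self) -> None:
        ids = [r for f in self.families for r in f.ril_ids]
        if len(ids) != len(set(ids)):
            raise ValueError("a RIL id appears in more than one family")
        if set(ids) != set(self.genotypes.index):
            raise ValueError("genotype rows do not match family RIL ids")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 0.5, 1.0))
        if not ok.all():
            raise ValueError("genotype codes must be 0, 0.5, 1 or missing")

    @property
    def family_of(self) -> pd.Series:
        return pd.Series(
            {r: f.family_id for f in self.families for r in f.ril_ids},
            name="family",
        ).loc[self.genotypes.index]

    def family_ids(self) -> list:
        return [f.family_id for f in self.families]


def simulate_population(gmap: GeneticMap, n_ril: int = 170,
                        alt_parents: Sequence[str] = DEFAULT_ALT_PARENTS,
                        seed: int = 0,
                        distortion: Sequence[tuple] | None = None) -> NAMPopulation:
    """Simulate the full NAM panel: one RIL family per alternate parent.

    distortion: optional sequence of (marker_id, family_id, target_alt_freq)
    applying within-family segregation distortion at a locus.
    """
    rng = np.random.default_rng(seed)
    marker_ids = list(gmap.markers)
    marker_pos = {m: i for i, m in enumerate(marker_ids)}
    families, blocks, index = [], [], []
    for k, parent in enumerate(alt_parents):
        fam_id = f"Z{k + 1:03d}"
        geno = simulate_family(gmap, n_ril, seed=int(rng.integers(2 ** 31)))
        if distortion:
            for marker_id, fam, freq in distortion:
                if fam == fam_id:
                    geno = _apply_distortion(geno, marker_pos[marker_id], freq, rng)
        ril_ids = [f"{fam_id}E{j + 1:04d}" for j in range(n_ril)]
        families.append(Family(fam_id, parent, ril_ids))
        blocks.append(geno)
        index.extend(ril_ids)
    genotypes = pd.DataFrame(np.vstack(blocks), index=index, columns=marker_ids)
    return NAMPopulation(families, genotypes, gmap)


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

@dataclass
class QTL:
    """One mapped locus with family-nested additive effects per trait.

    effects[trait] is either a scalar (same additive effect in every family)
    or a mapping family_id -> effect. Effects are on the 0/1 parental-origin
    coding: the value is the difference between the alternate- and
    common-parent genotype class means.
    """

    marker: str
    effects: Mapping[str, float | Mapping[str, float]]

    def traits(self) -> list:
        return list(self.effects)

    def family_effect(self, trait: str, family_id: str) -> float:
        e = self.effects.get(trait, 0.0)
        if isinstance(e, Mapping):
            return float(e.get(family_id, 0.0))
        return float(e)


@dataclass
class TraitArchitecture:
    qtl: list  # of QTL
    h2_target: Mapping[str, float]
    sigma2_family: float = 1.0
    distortion: Sequence[tuple] | None = None  # (marker, family, alt_freq)

    def __post_init__(self) -> None:
        for t, h2 in self.h2_target.items():
            if not 0.0 < h2 <= 1.0:
                raise ValueError(f"h2_target for {t!r} must be in (0, 1]")

    def traits(self) -> list:
        seen = dict.fromkeys(self.h2_target)
        for q in self.qtl:
            for t in q.traits():
                seen.setdefault(t)
        return list(seen)


def pleiotropic_effects(families: Sequence[str], trait_sds: Mapping[str, float],
                        corr: float, seed: int) -> dict:
    """Draw correlated per-family effects for a shared QTL across traits.

    Effects for the listed traits are jointly Gaussian across families with
    pairwise correlation ``corr`` (negative values give antagonistic,
    branch-switching pleiotropy).
    """
    traits = list(trait_sds)
    k = len(traits)
    C = np.full((k, k), corr) + (1 - corr) * np.eye(k)
    L = np.linalg.cholesky(C)
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((len(families), k)) @ L.T
    return {
        t: {f: float(draws[i, j] * trait_sds[t]) for i, f in enumerate(families)}
        for j, t in enumerate(traits)
    }


# ---------------------------------------------------------------------------
# Field design and phenotype simulation
# ---------------------------------------------------------------------------

@dataclass
class FieldDesign:
    """Augmented incomplete-block layout over years and fields.

    One replicate of the panel is grown per year; the replicate is split
    across ``fields_by_year[year]`` fields, each family forming one set per
    field, sets divided into blocks of ``block_size`` plots laid out on a
    ``grid_rows``-row grid. Variance components are on the trait scale;
    the residual variance is derived from the architecture's h2 target
    unless ``sigma2_error`` is given explicitly.
    """

    fields_by_year: Mapping[int, int] = field(
        default_factory=lambda: {2009: 2, 2010: 1})
    block_size: int = 20
    grid_rows: int = 20
    sigma2_year: float = 0.0
    sigma2_field: float = 0.0
    sigma2_set: float = 0.0
    sigma2_block: float = 0.0
    sigma2_plate: float = 0.0
    plate_size: int = 96
    rho_row: float = 0.0
    rho_range: float = 0.0
    sigma2_error: float | None = None

    @property
    def n_plots_per_line(self) -> int:
        return len(self.fields_by_year)  # one replicate per year


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    if n == 1 or rho == 0.0:
        base = np.eye(n)
    else:
        idx = np.arange(n)
        base = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(base)


def _spatial_noise(n_row: int, n_range: int, rho_row: float, rho_range: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR1(row) x AR1(range) Gaussian field on a grid."""
    Lr = _ar1_chol(n_row, rho_row)
    Lc = _ar1_chol(n_range, rho_range)
    return Lr @ rng.standard_normal((n_row, n_range)) @ Lc.T


def simulate_traits(pop: NAMPopulation, arch: TraitArchitecture,
                    design: FieldDesign, seed: int) -> pd.DataFrame:
    """Simulate plot-level phenotypes (long format).

    plot value = sum over QTL of family-nested effect x 0/1 genotype
    + family intercept + year + field + set + block (+ plate) random draws
    + AR1 x AR1 spatial residual scaled so the line-mean heritability of the
    genetic signal matches ``arch.h2_target`` given the realized genotypes.

    Returns columns: line, family, year, field, set, block, row, range,
    plate, trait, value.
    """
    rng = np.random.default_rng(seed)
    traits = arch.traits()
    fam_of = pop.family_of
    lines = list(pop.genotypes.index)
    n_lines = len(lines)

    # genetic values per line per trait
    gvals = pd.DataFrame(0.0, index=lines, columns=traits)
    for q in arch.qtl:
        codes = pop.genotypes[q.marker].to_numpy(dtype=float)
        fams = fam_of.to_numpy()
        for t in q.traits():
            eff = np.array([q.family_effect(t, f) for f in fams])
            gvals[t] += codes * eff
    fam_ids = pop.family_ids()
    fam_intercepts = {
        t: dict(zip(fam_ids,
                    rng.normal(0.0, np.sqrt(arch.sigma2_family), len(fam_ids))))
        for t in traits
    }

    # within-family genetic variance drives the error scale
    sigma2_g = {}
    for t in traits:
        centered = gvals[t] - gvals[t].groupby(fam_of).transform("mean")
        sigma2_g[t] = float(centered.var(ddof=1)) if n_lines > 1 else 0.0
    p_bar = design.n_plots_per_line
    sigma2_e = {}
    for t in traits:
        if design.sigma2_error is not None:
            sigma2_e[t] = design.sigma2_error
        else:
            h2 = arch.h2_target.get(t, 1.0)
            sigma2_e[t] = sigma2_g[t] * p_bar * (1.0 - h2) / h2

    # plot layout: per year, families split round-robin over fields
    rows = []
    plate_counter = 0
    for year, n_fields in design.fields_by_year.items():
        y_eff = rng.normal(0.0, np.sqrt(design.sigma2_year))
        for fi in range(n_fields):
            field_id = f"{year}F{fi + 1}"
            f_eff = rng.normal(0.0, np.sqrt(design.sigma2_field))
            fam_here = fam_ids[fi::n_fields]
            plots = []  # (line, family, set, block)
            for fam in fam_here:
                set_id = f"{field_id}S{fam}"
                s_eff = rng.normal(0.0, np.sqrt(design.sigma2_set))
                fam_lines = [ln for ln in lines if fam_of[ln] == fam]
                for bi in range(0, len(fam_lines), design.block_size):
                    block_id = f"{set_id}B{bi // design.block_size + 1}"
                    b_eff = rng.normal(0.0, np.sqrt(design.sigma2_block))
                    for ln in fam_lines[bi:bi + design.block_size]:
                        plots.append((ln, fam, set_id, s_eff, block_id, b_eff))
            n_plot = len(plots)
            n_range = int(np.ceil(n_plot / design.grid_rows))
            noise = {
                t: _spatial_noise(design.grid_rows, n_range, design.rho_row,
                                  design.rho_range, rng) * np.sqrt(sigma2_e[t])
                for t in traits
            }
            for i, (ln, fam, set_id, s_eff, block_id, b_eff) in enumerate(plots):
                r, c = i % design.grid_rows, i // design.grid_rows
                plate_id = f"P{plate_counter // design.plate_size + 1}"
                plate_counter += 1
                for t in traits:
                    rows.append((
                        ln, fam, year, field_id, set_id, block_id,
                        r + 1, c + 1, plate_id, t,
                        gvals.at[ln, t] + fam_intercepts[t][fam] + y_eff
                        + f_eff + s_eff + b_eff + noise[t][r, c],
                    ))
    plot_tab = pd.DataFrame(rows, columns=[
        "line", "family", "year", "field", "set", "block",
        "row", "range", "plate", "trait", "value",
    ])
    if design.sigma2_plate > 0:
        plates = plot_tab["plate"].unique()
        eff = dict(zip(plates, rng.normal(0.0, np.sqrt(design.sigma2_plate),
                                          len(plates))))
        plot_tab["value"] += plot_tab["plate"].map(eff)
    return plot_tab


# ---------------------------------------------------------------------------
# Dense founder variant panel
# ---------------------------------------------------------------------------

@dataclass
class CausalVariant:
    chrom: object
    bp: int
    carriers: frozenset  # founders carrying the alternate allele
    variant_id: str = ""


def simulate_dense_variants(pop: NAMPopulation, density_per_Mb: float,
                            causal_spec: Sequence[CausalVariant] = (),
                            seed: int = 0) -> pd.DataFrame:
    """Simulate a biallelic founder variant panel on the map's bp backbone.

    Variant count per chromosome is Poisson(density x span in Mb), positions
    uniform; founder allele sharing patterns are random but polymorphic.
    Causal variants are placed at the requested bp with the requested carrier
    set. Returns a DataFrame (variant, chrom, bp, one 0/1 column per founder)
    and stores it on ``pop.dense_variants``.
    """
    if density_per_Mb <= 0:
        raise ValueError("density_per_Mb must be positive")
    rng = np.random.default_rng(seed)
    founders = [COMMON_PARENT] + [f.alt_parent for f in pop.families]
    rows = []
    for chrom in pop.gmap.chromosomes():
        sl = pop.gmap.chrom_slice(chrom)
        lo, hi = int(sl["bp"].min()), int(sl["bp"].max())
        span_mb = max(hi - lo, 1) / 1e6
        n_var = rng.poisson(density_per_Mb * span_mb)
        positions = np.sort(rng.integers(lo, hi + 1, size=n_var))
        for j, bp in enumerate(positions):
            while True:
                q = rng.uniform(0.1, 0.9)
                alleles = (rng.random(len(founders)) < q).astype(int)
                if 0 < alleles.sum() < len(founders):
                    break
            rows.append((f"v{chrom}_{j}_{bp}", chrom, int(bp), *alleles))
    for cv in causal_spec:
        vid = cv.variant_id or f"causal_{cv.chrom}_{cv.bp}"
        alleles = [1 if f in cv.carriers else 0 for f in founders]
        rows.append((vid, cv.chrom, int(cv.bp), *alleles))
    tab = pd.DataFrame(rows, columns=["variant", "chrom", "bp"] + founders)
    tab = tab.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)
    pop.dense_variants = tab
    return tab
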