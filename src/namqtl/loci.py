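"""Common-interval merging, LD profiling and candidate-gene resolution.

QTL support intervals from all traits are merged per chromosome wherever
they physically overlap (1-based, closed-interval convention throughout);
linkage disequilibrium around associated variants is profiled against a
random-variant null; and genes are resolved by the triple criterion:
(i) within the +/- window search space of a reported marker-trait
association, (ii) overlapping an individual-trait QTL interval for at least
one of the same traits, and (iii) present on the a-priori candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Interval merging
# ---------------------------------------------------------------------------

def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Union of physically overlapping intervals per chromosome.

    ``intervals`` needs columns chrom, start, end (closed, bp) and
    optionally trait / an id; intervals sharing at least 1 bp are combined
    (sweep line). Returns one row per merged interval with columns chrom,
    start, end, n_members, members (list of input row labels).
    """
    if (intervals["start"] > intervals["end"]).any():
        bad = intervals.index[intervals["start"] > intervals["end"]][0]
        raise ValueError(f"interval {bad!r} has start > end")
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur_start = cur_end = None
        members: list = []
        for label, r in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end, members = r["start"], r["end"], [label]
            elif r["start"] <= cur_end:          # closed intervals: touching counts
                cur_end = max(cur_end, r["end"])
                members.append(label)
            else:
                rows.append((chrom, cur_start, cur_end, len(members), members))
                cur_start, cur_end, members = r["start"], r["end"], [label]
        if cur_start is not None:
            rows.append((chrom, cur_start, cur_end, len(members), members))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members",
                                      "members"])
    out.insert(0, "interval_id",
               [f"ci_{c}_{s}" for c, s in zip(out["chrom"], out["start"])])
    return out


# ---------------------------------------------------------------------------
# LD profile
# ---------------------------------------------------------------------------

def ld_profile(dosages: np.ndarray, meta: pd.DataFrame, focal_ids,
               window_bp: int = 250_000, n_null: int = 50_000,
               seed: int = 0) -> dict:
    """Pairwise r^2 between focal variants and all variants within the
    window, plus a same-window null from randomly selected variants.

    dosages: (n_lines, n_variants); meta: variant, chrom, bp in column order
    of ``dosages``. Zero-variance columns are skipped and counted. Returns
    {"observed": r2 array, "null": r2 array, "n_skipped": int}.
    """
    meta = meta.reset_index(drop=True)
    sd = dosages.std(axis=0)
    ok = sd > 0
    n_skipped = int((~ok).sum())
    Z = np.where(ok, 1.0, np.nan) * (dosages - dosages.mean(axis=0)) / \
        np.where(ok, sd, 1.0)
    n = dosages.shape[0]

    def window_r2(focal_idx: np.ndarray) -> np.ndarray:
        vals = []
        for i in focal_idx:
            if not ok[i]:
                continue
            m = (meta["chrom"] == meta.at[i, "chrom"]) & \
                (np.abs(meta["bp"] - meta.at[i, "bp"]) <= window_bp)
            j = np.flatnonzero(m.to_numpy() & ok)
            j = j[j != i]
            if j.size == 0:
                continue
            r = Z[:, j].T @ Z[:, i] / n
            vals.append(r ** 2)
        return np.concatenate(vals) if vals else np.array([])

    id_pos = {v: i for i, v in enumerate(meta["variant"])}
    focal_idx = np.array([id_pos[v] for v in focal_ids], dtype=int)
    observed = window_r2(focal_idx)
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(ok)
    k = min(n_null, pool.size)
    null_idx = rng.choice(pool, size=k, replace=False)
    null = window_r2(null_idx)
    return {"observed": observed, "null": null, "n_skipped": n_skipped}


# ---------------------------------------------------------------------------
# Annotation readers (1-based closed coordinates internally)
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Gene spans from BED (0-based half-open on disk -> 1-based closed)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#")
    if tab.shape[1] < 4:
        raise ValueError("BED file needs at least 4 columns (incl. name)")
    out = pd.DataFrame({
        "gene": tab[3].astype(str),
        "chrom": tab[0],
        "start": tab[1].astype(int) + 1,
        "end": tab[2].astype(int),
    })
    return out


def read_gff3_genes(path, feature: str = "gene",
                    id_attr: str = "ID") -> pd.DataFrame:
    """Gene spans from GFF3 (already 1-based closed)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "source", "type", "start", "end",
                             "score", "strand", "phase", "attributes"])
    tab = tab[tab["type"] == feature]

    def get_id(attrs: str) -> str:
        for fielditem in str(attrs).split(";"):
            k, _, v = fielditem.partition("=")
            if k.strip() == id_attr:
                return v.strip()
        return str(attrs)

    return pd.DataFrame({
        "gene": tab["attributes"].map(get_id),
        "chrom": tab["chrom"],
        "start": tab["start"].astype(int),
        "end": tab["end"].astype(int),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene resolution
# ---------------------------------------------------------------------------

@dataclass
class CandidateGene:
    gene: str
    chrom: object
    start: int
    end: int
    supporting_traits: list = dc_field(default_factory=list)
    supporting_variants: list = dc_field(default_factory=list)  # (variant, trait, rmip)
    containing_intervals: list = dc_field(default_factory=list)


def _span_overlap(a_start, a_end, b_start, b_end) -> bool:
    return a_start <= b_end and b_start <= a_end


def resolve_genes(trait_intervals: pd.DataFrame, rmip_table: pd.DataFrame,
                  genes: pd.DataFrame, apriori: set,
                  window_bp: int = 250_000, rmip_min: int = 5,
                  require_containment: bool = False) -> list:
    """Resolve candidate genes by the triple criterion.

    A gene qualifies iff (i) its span intersects [variant - window,
    variant + window] for >= 1 reported association (rmip >= rmip_min),
    (ii) its span overlaps (or, with ``require_containment``, lies within)
    an individual-trait QTL interval for >= 1 of the same traits, and
    (iii) it is on the a-priori list. ``trait_intervals`` needs columns
    trait, chrom, start, end; ``rmip_table`` trait, variant, chrom, bp, rmip.
    Chromosome name mismatches between tables raise.
    """
    gene_chroms = set(genes["chrom"].unique())
    iv_chroms = set(trait_intervals["chrom"].unique()) if len(
        trait_intervals) else set()
    if iv_chroms and not (iv_chroms & gene_chroms):
        raise ValueError(
            f"no shared chromosome names between annotations {sorted(map(str, gene_chroms))} "
            f"and intervals {sorted(map(str, iv_chroms))}")
    hits = rmip_table[rmip_table["rmip"] >= rmip_min]
    out = []
    for _, g in genes.iterrows():
        if g["gene"] not in apriori:
            continue
        near = hits[(hits["chrom"] == g["chrom"])
                    & (hits["bp"] >= g["start"] - window_bp)
                    & (hits["bp"] <= g["end"] + window_bp)]
        if near.empty:
            continue
        assoc_traits = set(near["trait"])
        cand = CandidateGene(g["gene"], g["chrom"], int(g["start"]),
                             int(g["end"]))
        for _, iv in trait_intervals.iterrows():
            if iv["trait"] not in assoc_traits or iv["chrom"] != g["chrom"]:
                continue
            if require_containment:
                inside = iv["start"] <= g["start"] and g["end"] <= iv["end"]
            else:
                inside = _span_overlap(g["start"], g["end"],
                                       iv["start"], iv["end"])
            if inside:
                cand.containing_intervals.append(
                    (iv["trait"], iv["chrom"], int(iv["start"]),
                     int(iv["end"])))
        sup_traits = {t for t, *_ in cand.containing_intervals}
        if not sup_traits:
            continue
        sup = near[near["trait"].isin(sup_traits)]
        cand.supporting_traits = sorted(sup_traits)
        cand.supporting_variants = list(
            sup[["variant", "trait", "rmip"]].itertuples(index=False,
                                                         name=None))
        out.append(cand)
    return out


def candidate_genes_table(cands: list) -> pd.DataFrame:
    rows = [(c.gene, c.chrom, c.start, c.end,
             ",".join(c.supporting_traits),
             ",".join(sorted({v for v, *_ in c.supporting_variants})),
             len(c.containing_intervals)) for c in cands]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "traits", "variants", "n_intervals"])
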