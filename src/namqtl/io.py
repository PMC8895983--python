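"""Tabular and variant-format I/O.

Long/wide TSV is the interchange spine; VCF/BED/GFF3 are accepted at the
boundary. Every written file carries a provenance header line naming the
producing stage, config hash and seed, as a ``#``-comment that readers skip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .sim import COMMON_PARENT, Family, GeneticMap, NAMPopulation


def _header(stage: str, config_hash: str = "-", seed="-") -> str:
    return f"# namqtl stage={stage} config_hash={config_hash} seed={seed}\n"


def write_tsv(df: pd.DataFrame, path, stage: str, config_hash: str = "-",
              seed="-", index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(stage, config_hash, seed))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def write_map(gmap: GeneticMap, path, **hdr) -> None:
    write_tsv(gmap.table, path, stage=hdr.pop("stage", "map"), **hdr)


def load_map(path) -> GeneticMap:
    """Load a 4-column marker map; rows are sorted on load (with a warning
    if the file was unordered) and invariants enforced."""
    tab = read_tsv(path)
    required = ["marker", "chrom", "cM", "bp"]
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise ValueError(f"map file {path} lacks columns {missing}")
    sorted_tab = tab.sort_values(["chrom", "cM"], kind="stable").reset_index(
        drop=True)
    if not sorted_tab["marker"].equals(tab["marker"].reset_index(drop=True)):
        warnings.warn(f"map file {path} was not position-sorted; sorted on load")
    try:
        return GeneticMap(sorted_tab[required])
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_genotypes(pop: NAMPopulation, path, **hdr) -> None:
    """Wide TSV: line, family, alt_parent, then one column per marker."""
    fam_of = pop.family_of
    parent_of = {f.family_id: f.alt_parent for f in pop.families}
    out = pop.genotypes.copy()
    out.insert(0, "alt_parent", fam_of.map(parent_of))
    out.insert(0, "family", fam_of)
    out.index.name = "line"
    write_tsv(out.reset_index(), path, stage=hdr.pop("stage", "genotypes"),
              **hdr)


def load_genotypes(path, gmap: GeneticMap) -> NAMPopulation:
    tab = read_tsv(path)
    for col in ("line", "family"):
        if col not in tab.columns:
            raise ValueError(f"genotype file {path} lacks column {col!r}")
    marker_cols = [c for c in tab.columns
                   if c not in ("line", "family", "alt_parent")]
    unknown = set(marker_cols) - set(gmap.markers)
    if unknown:
        raise ValueError(f"{path}: markers not on map: {sorted(unknown)[:5]}")
    families = []
    for fam, grp in tab.groupby("family", sort=True):
        parent = (str(grp["alt_parent"].iloc[0]) if "alt_parent" in grp
                  else f"P_{fam}")
        families.append(Family(str(fam), parent, grp["line"].astype(str).tolist()))
    geno = tab.set_index("line")[list(gmap.markers)].astype(float)
    geno.index = geno.index.astype(str)
    geno.index.name = None
    return NAMPopulation(families, geno, gmap)


def write_genotypes_vcf(pop: NAMPopulation, path, **hdr) -> None:
    """Minimal VCF 4.2 with one pseudo-sample per RIL; parental-origin codes
    become haploid-style GT (0 = common parent, 1 = alternate)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = list(pop.genotypes.index)
    tab = pop.gmap.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Parental origin">\n')
        for chrom in pop.gmap.chromosomes():
            ln = int(pop.gmap.chrom_slice(chrom)["bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(lines) + "\n")
        G = pop.genotypes.to_numpy(dtype=float)
        for j, (_, r) in enumerate(tab.iterrows()):
            calls = []
            for v in G[:, j]:
                if np.isnan(v):
                    calls.append("./.")
                elif v == 0.5:
                    calls.append("0/1")
                else:
                    gt = int(v)
                    calls.append(f"{gt}/{gt}")
            fh.write(f"{r['chrom']}\t{max(int(r['bp']), 1)}\t{r['marker']}"
                     f"\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def write_founder_vcf(dense_variants: pd.DataFrame, path) -> None:
    """Founder variant panel as VCF (one sample per founder, homozygous)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    founders = [c for c in dense_variants.columns
                if c not in ("variant", "chrom", "bp")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(dense_variants["chrom"]):
            ln = int(dense_variants.loc[dense_variants["chrom"] == chrom,
                                        "bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(founders) + "\n")
        for _, r in dense_variants.iterrows():
            calls = "\t".join(f"{int(r[f])}/{int(r[f])}" for f in founders)
            fh.write(f"{r['chrom']}\t{max(int(r['bp']), 1)}\t{r['variant']}"
                     f"\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_founder_vcf(path) -> pd.DataFrame:
    """Founder variant table (variant, chrom, bp, one 0/1 column per founder)
    from a VCF of homozygous founder calls; heterozygous calls become 0.5,
    missing calls NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    founders = list(vcf.samples)
    rows = []
    for i, rec in enumerate(vcf):
        gts = [(np.nan if g[0] < 0 else (g[0] + g[1]) / 2.0)
               for g in rec.genotypes]
        vid = rec.ID or f"v{rec.CHROM}_{rec.POS}"
        rows.append([vid, rec.CHROM, rec.POS] + gts)
    return pd.DataFrame(rows, columns=["variant", "chrom", "bp"] + founders)


# ---------------------------------------------------------------------------
# Plot tables and BLUEs
# ---------------------------------------------------------------------------

PLOT_COLUMNS = ["line", "family", "year", "field", "set", "block",
                "row", "range", "plate", "trait", "value"]


def write_plot_table(plots: pd.DataFrame, path, **hdr) -> None:
    write_tsv(plots[PLOT_COLUMNS], path, stage=hdr.pop("stage", "plots"), **hdr)


def load_plot_table(path) -> pd.DataFrame:
    tab = read_tsv(path)
    missing = [c for c in PLOT_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"plot table {path} lacks columns {missing}")
    return tab[PLOT_COLUMNS]


def write_blues(blues_wide: pd.DataFrame, path, **hdr) -> None:
    """Wide BLUE table: line, family, one column per trait (untransformed)
    plus ``<trait>__transformed`` blocks when available."""
    write_tsv(blues_wide, path, stage=hdr.pop("stage", "blues"), **hdr)


def load_blues(path) -> pd.DataFrame:
    tab = read_tsv(path)
    if "line" not in tab.columns:
        raise ValueError(f"BLUE table {path} lacks a 'line' column")
    return tab


def blues_to_series(blues_wide: pd.DataFrame, trait: str,
                    transformed: bool = True) -> pd.Series:
    col = f"{trait}__transformed" if transformed else trait
    if col not in blues_wide.columns:
        raise KeyError(f"column {col!r} not in BLUE table")
    return pd.Series(blues_wide[col].to_numpy(dtype=float),
                     index=blues_wide["line"].astype(str), name=trait)
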