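"""Lineage-specific SNP partitioning and windowed SNP-density scanning.

A SNP is lineage-specific when its alternate allele is present in every
dataset of one lineage that covers the site and absent from every covering
dataset of all other lineages (all-vs-all comparison across the A, D and AD
clades).  "Absent" means no alternate-allele support in a dataset with at
least ``min_allele_depth`` reads at the site; datasets without coverage
neither support nor veto.  Tetraploid genotypes are reduced to allele
presence/absence — dosage is ignored.

Variant calling and effect prediction are upstream: the module consumes a
multi-sample VCF (sample names = manifest dataset ids) and a SnpEff-style
annotation table.  Positions are 1-based on disk and 0-based internally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pysam

from .io import DatasetManifest

logger = logging.getLogger("allotetra")

SITE_COLUMNS = ["contig", "pos0", "ref", "alt", "lineage"]


def read_vcf_presence(path: str, manifest: DatasetManifest, min_depth: int = 3) -> pd.DataFrame:
    """Read a VCF into per-site, per-dataset alternate-allele presence.

    Returns one row per site with columns contig, pos0, ref, alt and one
    column per dataset holding 1 (alt present), 0 (alt absent, covered) or
    -1 (not covered: missing genotype or depth < ``min_depth``).
    """
    dataset_ids = manifest.dataset_ids
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = set(dataset_ids) - set(samples)
        if missing:
            raise ValueError(f"manifest datasets absent from VCF: {sorted(missing)}")
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            row = [rec.contig, rec.pos - 1, rec.ref, alt]
            for did in dataset_ids:
                call = rec.samples[did]
                gt = call.get("GT")
                dp = call.get("DP")
                if gt is None or all(a is None for a in gt) or (
                    dp is not None and dp < min_depth
                ):
                    row.append(-1)
                else:
                    row.append(1 if any(a not in (0, None) for a in gt) else 0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["contig", "pos0", "ref", "alt"] + dataset_ids)


def partition_lineage_specific(
    presence: pd.DataFrame, manifest: DatasetManifest
) -> pd.DataFrame:
    """Partition sites into lineage-specific sets.

    A site is lineage-L-specific iff the alternate allele is present in every
    covering L dataset (at least one) and absent from every covering dataset
    of all other lineages.  Sites covered by no dataset are skipped (logged).
    The resulting sets are pairwise disjoint by construction.
    """
    lineages = sorted({d.clade for d in manifest.datasets})
    if len(lineages) < 2:
        raise ValueError("at least two lineages are required")
    cols = {lin: manifest.ids_for_clade(lin) for lin in lineages}

    n_skipped = 0
    rows = []
    mat = {lin: presence[cols[lin]].to_numpy() for lin in lineages}
    for i in range(len(presence)):
        covering = {lin: mat[lin][i][mat[lin][i] >= 0] for lin in lineages}
        if all(v.size == 0 for v in covering.values()):
            n_skipped += 1
            continue
        assigned = None
        for lin in lineages:
            own = covering[lin]
            others = [covering[o] for o in lineages if o != lin]
            if (
                own.size > 0
                and np.all(own == 1)
                and all(np.all(o == 0) for o in others)
            ):
                assigned = lin
                break
        if assigned is not None:
            rec = presence.iloc[i]
            rows.append((rec["contig"], rec["pos0"], rec["ref"], rec["alt"], assigned))
    if n_skipped:
        logger.info("partition_lineage_specific: skipped %d uncovered sites", n_skipped)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def effect_summary(
    ls_snps: pd.DataFrame, annotation: pd.DataFrame | None
) -> dict[str, pd.DataFrame]:
    """Summarize coding effects of lineage-specific SNPs.

    ``annotation`` columns: contig, pos0, effect, gene (effect classes as
    produced upstream, e.g. synonymous / non-synonymous).  Sites without an
    annotation are classed "other/none".  Returns per-lineage per-class SNP
    tallies, a per-gene table, and per-lineage counts of genes affected by
    non-synonymous lineage-specific SNPs (each gene counted once).
    """
    snps = ls_snps.copy()
    if annotation is not None and not annotation.empty:
        snps = snps.merge(
            annotation[["contig", "pos0", "effect", "gene"]],
            on=["contig", "pos0"], how="left",
        )
    else:
        snps["effect"] = np.nan
        snps["gene"] = np.nan
    snps["effect"] = snps["effect"].fillna("other/none")

    per_class = (
        snps.groupby(["lineage", "effect"]).size().rename("n_snps").reset_index()
    )
    with_gene = snps.dropna(subset=["gene"])
    per_gene = (
        with_gene.groupby(["lineage", "gene"]).size().rename("n_snps").reset_index()
    )
    nonsyn = with_gene[with_gene["effect"] == "non-synonymous"]
    affected = (
        nonsyn.groupby("lineage")["gene"].nunique().rename("n_genes").reset_index()
    )
    return {"per_class": per_class, "per_gene": per_gene, "affected_genes": affected}


DENSITY_COLUMNS = ["contig", "start", "end", "count", "density", "z", "flag"]


def density_scan(
    sites: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 1_000_000,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Windowed SNP counts with z-score flags for low/high-density regions.

    Windows tile each contig (the last window may be short; a contig shorter
    than the window yields a single short window).  z-scores are computed
    against the genome-wide distribution of window counts; windows at
    z <= -threshold are flagged "low" (candidate swept/conserved regions),
    z >= +threshold "high".  A degenerate distribution (zero spread, e.g. an
    empty site list) suppresses all flags.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    frames = []
    for contig, length in contig_lengths.items():
        n_win = max(1, -(-length // window))
        starts = np.arange(n_win) * window
        ends = np.minimum(starts + window, length)
        pos = sites.loc[sites["contig"] == contig, "pos0"].to_numpy()
        if np.any((pos < 0) | (pos >= length)):
            raise ValueError(f"site position outside contig {contig!r}")
        counts = np.bincount(pos // window, minlength=n_win) if pos.size else np.zeros(n_win, dtype=int)
        frames.append(
            pd.DataFrame(
                {"contig": contig, "start": starts, "end": ends, "count": counts}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["density"] = df["count"] / (df["end"] - df["start"])
    mean, std = df["count"].mean(), df["count"].std(ddof=1)
    if not np.isfinite(std) or std == 0:
        df["z"] = 0.0
        df["flag"] = "normal"
        return df[DENSITY_COLUMNS]
    df["z"] = (df["count"] - mean) / std
    df["flag"] = np.where(
        df["z"] <= -z_threshold, "low", np.where(df["z"] >= z_threshold, "high", "normal")
    )
    return df[DENSITY_COLUMNS]
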