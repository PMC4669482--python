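"""Homoeologous gene-pair expression profiling and bias classification.

Works on an FPKM matrix (genes x tissues; the tissue panel includes the
fibre elongation FE and secondary-wall FS stages) and a table pairing each
At gene with its Dt homoeolog.  A pair is called At- or Dt-biased in a focal
tissue when |log2((FPKM_At + 1) / (FPKM_Dt + 1))| reaches the bias threshold
(default 1, i.e. a two-fold difference); "highly and specifically expressed"
pairs are those whose combined expression in the focal tissue clears an
expression floor and exceeds every other tissue by a specificity factor.
Profiles are normalized per gene (log2(FPKM + 1), then z-score across
tissues) before k-means clustering, which is seeded and applied after
sorting genes by id so results are permutation-invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

PAIR_COLUMNS = ["pair_id", "at_gene", "dt_gene"]
BIAS_COLUMNS = ["pair_id", "tissue", "log2_ratio", "bias", "combined_fpkm"]


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")


def normalize_profiles(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene log2(FPKM + 1) followed by z-scoring across tissues.

    Genes with zero variance across tissues get an all-zero profile; the
    returned boolean Series flags them.
    """
    validate_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two tissues to normalize profiles")
    logged = np.log2(matrix.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    std = logged.std(axis=1, ddof=0, keepdims=True)
    flat = (std[:, 0] == 0)
    std[flat] = 1.0
    profiles = (logged - mean) / std
    profiles[flat] = 0.0
    return (
        pd.DataFrame(profiles, index=matrix.index, columns=matrix.columns),
        pd.Series(flat, index=matrix.index, name="zero_variance"),
    )


def kmeans_cluster(profiles: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """Seeded k-means on normalized profiles, invariant to gene order.

    Genes are sorted by id before fitting so any permutation of the input
    yields identical assignments; cluster ids are relabelled by first sorted
    member for determinism.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(profiles):
        raise ValueError(f"k = {k} exceeds the number of genes ({len(profiles)})")
    ordered = profiles.sort_index(kind="stable")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=300)
    raw = km.fit_predict(ordered.to_numpy(dtype=float))
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    by_gene = pd.Series([relabel[l] for l in raw], index=ordered.index)
    return pd.DataFrame(
        {"gene": profiles.index, "cluster": by_gene.loc[profiles.index].to_numpy()}
    )


def validate_pairs(pairs: pd.DataFrame, matrix: pd.DataFrame) -> None:
    genes = pd.concat([pairs["at_gene"], pairs["dt_gene"]])
    if genes.duplicated().any():
        raise ValueError("a gene may belong to at most one homoeolog pair")
    missing = set(genes) - set(matrix.index)
    if missing:
        raise ValueError(f"pair genes absent from matrix: {sorted(missing)[:5]}")


def combined_expression(pairs: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-pair combined (At + Dt) FPKM, one row per pair."""
    validate_pairs(pairs, matrix)
    at = matrix.loc[pairs["at_gene"]].to_numpy(dtype=float)
    dt = matrix.loc[pairs["dt_gene"]].to_numpy(dtype=float)
    return pd.DataFrame(at + dt, index=pairs["pair_id"], columns=matrix.columns)


def tissue_specific_pairs(
    matrix: pd.DataFrame,
    pairs: pd.DataFrame,
    focal_tissue: str,
    floor: float = 5.0,
    factor: float = 2.0,
) -> pd.DataFrame:
    """Pairs highly and specifically expressed in the focal tissue.

    A pair qualifies iff its combined FPKM in the focal tissue is at least
    ``floor`` and at least ``factor`` times the combined FPKM of every other
    tissue.
    """
    if focal_tissue not in matrix.columns:
        raise ValueError(f"tissue {focal_tissue!r} not in matrix")
    combined = combined_expression(pairs, matrix)
    focal = combined[focal_tissue]
    others = combined.drop(columns=[focal_tissue])
    ok = (focal >= floor) & (focal.to_numpy()[:, None] >= factor * others.to_numpy()).all(axis=1)
    return pairs[ok.to_numpy()].reset_index(drop=True)


def call_bias(
    pairs: pd.DataFrame,
    matrix: pd.DataFrame,
    focal_tissue: str,
    log2_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify each pair as At-biased, Dt-biased or unbiased in one tissue.

    ratio = log2((FPKM_At + c) / (FPKM_Dt + c)); At-biased at
    ratio >= threshold, Dt-biased at ratio <= -threshold.
    """
    validate_pairs(pairs, matrix)
    if focal_tissue not in matrix.columns:
        raise ValueError(f"tissue {focal_tissue!r} not in matrix")
    at = matrix.loc[pairs["at_gene"], focal_tissue].to_numpy(dtype=float)
    dt = matrix.loc[pairs["dt_gene"], focal_tissue].to_numpy(dtype=float)
    ratio = np.log2((at + pseudocount) / (dt + pseudocount))
    bias = np.where(
        ratio >= log2_threshold, "At-biased",
        np.where(ratio <= -log2_threshold, "Dt-biased", "unbiased"),
    )
    return pd.DataFrame(
        {
            "pair_id": pairs["pair_id"].to_numpy(),
            "tissue": focal_tissue,
            "log2_ratio": ratio,
            "bias": bias,
            "combined_fpkm": at + dt,
        },
        columns=BIAS_COLUMNS,
    )


def group_expression_sum(matrix: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Per-group, per-tissue FPKM sums (e.g. summing a gene clade's members).

    Missing genes are an error; an empty group yields a zero row (flagged by
    ``n_genes = 0``).
    """
    validate_matrix(matrix)
    rows = []
    for name, genes in groups.items():
        missing = set(genes) - set(matrix.index)
        if missing:
            raise ValueError(f"group {name!r}: genes absent from matrix: {sorted(missing)}")
        total = (
            matrix.loc[list(genes)].sum(axis=0)
            if genes else pd.Series(0.0, index=matrix.columns)
        )
        rows.append([name, len(genes)] + list(total))
    return pd.DataFrame(rows, columns=["group", "n_genes"] + list(matrix.columns))
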