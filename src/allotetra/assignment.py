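"""Subgenome assignment of scaffolds from clade-structured coverage.

Each scaffold of the allotetraploid assembly is classified as At (A-genome
derived), Dt (D-genome derived) or ungrouped from the read coverage of
progenitor shotgun datasets, using three criteria applied jointly:

1. more than ``covered_fraction_min`` (default 40%) of the scaffold's bases
   are covered by reads from any diploid progenitor dataset (union over the
   A- and D-clade tracks);
2. the log2 ratio of mean base-pair coverage between the A-clade and D-clade
   exceeds ``log2_ratio_min`` (default 2) in magnitude, with the sign giving
   the direction (positive -> At, negative -> Dt);
3. the A-vs-D depth difference is significant (p < ``ttest_alpha``, default
   0.01) by Student's two-sample t-test over per-dataset normalized mean
   depths, treating replicate lines of each diploid clade as replicates.

Per-dataset depths are library-size normalized by each dataset's genome-wide
mean depth, so depth differences reflect mappability rather than sequencing
effort.  Tetraploid (AD) tracks are summarized for display but never used in
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import CoverageTrack, DatasetManifest, ScaffoldSet, union_covered_fraction

ASSIGNMENT_COLUMNS = [
    "scaffold_id", "label", "covered_fraction_union", "mean_cov_A", "mean_cov_D",
    "log2_ratio", "t_statistic", "p_value",
    "criterion_coverage", "criterion_ratio", "criterion_ttest",
]


@dataclass
class CoverageSummary:
    """Normalized per-dataset mean depths and clade covered fractions."""

    scaffold_ids: list[str]
    dataset_ids: list[str]
    depths: np.ndarray            # (n_scaffolds, n_datasets) normalized mean depth
    frac_A: np.ndarray            # union covered fraction over A-clade tracks
    frac_D: np.ndarray
    frac_union: np.ndarray        # union over all progenitor (A + D) tracks
    clades: list[str]             # clade per dataset column

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.depths, columns=self.dataset_ids)
        df.insert(0, "scaffold_id", self.scaffold_ids)
        df["covered_fraction_A"] = self.frac_A
        df["covered_fraction_D"] = self.frac_D
        df["covered_fraction_union"] = self.frac_union
        return df

    def clade_columns(self, clade: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.clades) if c == clade]
        return self.depths[:, idx]


def summarize_coverage(
    tracks: list[CoverageTrack],
    manifest: DatasetManifest,
    scaffolds: ScaffoldSet,
    config: PipelineConfig | None = None,
) -> CoverageSummary:
    """Compute per-scaffold normalized depths and clade covered fractions.

    A scaffold absent from every track gets an all-zero summary rather than
    an error.
    """
    config = config or PipelineConfig()
    by_id = {t.dataset_id: t for t in tracks}
    unknown = set(by_id) - set(manifest.dataset_ids)
    if unknown:
        raise ValueError(f"tracks not in manifest: {sorted(unknown)}")
    for clade in ("A", "D"):
        if not any(manifest.clade_of(d) == clade for d in by_id):
            raise ValueError(f"no {clade}-clade coverage track supplied")

    dataset_ids = [d for d in manifest.dataset_ids if d in by_id]
    clades = [manifest.clade_of(d) for d in dataset_ids]
    sids = scaffolds.ids
    lengths = np.array([scaffolds[s].length for s in sids], dtype=float)

    depths = np.zeros((len(sids), len(dataset_ids)))
    for j, did in enumerate(dataset_ids):
        track = by_id[did]
        col = np.array([track.depth_sum(s) for s in sids]) / lengths
        if config.normalize_depths:
            gmean = track.genome_mean_depth(scaffolds)
            if gmean > 0:
                col = col / gmean
        depths[:, j] = col

    a_tracks = [by_id[d] for d, c in zip(dataset_ids, clades) if c == "A"]
    d_tracks = [by_id[d] for d, c in zip(dataset_ids, clades) if c == "D"]
    frac_A = np.array([union_covered_fraction(a_tracks, s, scaffolds[s].length) for s in sids])
    frac_D = np.array([union_covered_fraction(d_tracks, s, scaffolds[s].length) for s in sids])
    frac_union = np.array(
        [union_covered_fraction(a_tracks + d_tracks, s, scaffolds[s].length) for s in sids]
    )
    return CoverageSummary(sids, dataset_ids, depths, frac_A, frac_D, frac_union, clades)


def assign_scaffolds(
    summary: CoverageSummary,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Apply the three assignment criteria to every scaffold.

    Returns one row per scaffold with the label and every intermediate
    statistic (covered fraction, clade means, log2 ratio, t, p and the three
    per-criterion booleans).
    """
    config = config or PipelineConfig()
    a_vals = summary.clade_columns("A")
    d_vals = summary.clade_columns("D")
    if a_vals.shape[1] < 2 or d_vals.shape[1] < 2:
        raise ValueError(
            "Student's t-test needs >= 2 replicate datasets per diploid clade; "
            "supply more lines or disable criterion 3 explicitly via config"
        )

    mean_a = a_vals.mean(axis=1)
    mean_d = d_vals.mean(axis=1)
    eps = config.pseudocount
    log2_ratio = np.log2((mean_a + eps) / (mean_d + eps))

    t_stat, p_val = stats.ttest_ind(
        a_vals, d_vals, axis=1, equal_var=config.equal_var
    )
    # zero variance in both clades (e.g. all-zero coverage): no evidence
    p_val = np.where(np.isnan(p_val), 1.0, p_val)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)

    c_cov = summary.frac_union > config.covered_fraction_min
    c_ratio = np.abs(log2_ratio) > config.log2_ratio_min
    c_test = p_val < config.ttest_alpha

    label = np.where(
        c_cov & c_test & (log2_ratio > config.log2_ratio_min), "At",
        np.where(c_cov & c_test & (log2_ratio < -config.log2_ratio_min), "Dt", "ungrouped"),
    )
    return pd.DataFrame(
        {
            "scaffold_id": summary.scaffold_ids,
            "label": label,
            "covered_fraction_union": summary.frac_union,
            "mean_cov_A": mean_a,
            "mean_cov_D": mean_d,
            "log2_ratio": log2_ratio,
            "t_statistic": t_stat,
            "p_value": p_val,
            "criterion_coverage": c_cov,
            "criterion_ratio": c_ratio,
            "criterion_ttest": c_test,
        },
        columns=ASSIGNMENT_COLUMNS,
    )


def assign(
    tracks: list[CoverageTrack],
    manifest: DatasetManifest,
    scaffolds: ScaffoldSet,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: summarize coverage then assign every scaffold."""
    return assign_scaffolds(summarize_coverage(tracks, manifest, scaffolds, config), config)


def n50(lengths) -> int:
    """N50 of a collection of lengths (0 for an empty collection)."""
    arr = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    if arr.size == 0:
        return 0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


def assignment_report(assignments: pd.DataFrame, scaffolds: ScaffoldSet) -> pd.DataFrame:
    """Per-label scaffold counts, total lengths and N50; totals partition the assembly."""
    lengths = scaffolds.lengths
    rows = []
    for lab in ("At", "Dt", "ungrouped"):
        sub = assignments.loc[assignments["label"] == lab, "scaffold_id"]
        lens = [lengths[s] for s in sub]
        rows.append((lab, len(lens), int(sum(lens)), n50(lens)))
    rows.append(
        ("total", len(assignments),
         int(sum(lengths[s] for s in assignments["scaffold_id"])),
         n50([lengths[s] for s in assignments["scaffold_id"]]))
    )
    return pd.DataFrame(rows, columns=["label", "n_scaffolds", "total_length", "n50"])
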