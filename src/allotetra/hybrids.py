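"""Detection of At-Dt hybrid scaffolds and translocation-site summaries.

A hybrid scaffold carries one segment of A-genome origin and one of D-genome
origin, the signature of an inter-subgenome translocation (or an assembly
chimera; distinguishing the two is out of scope and left to paired-end or
PCR evidence, which can be attached as annotation).  Detection proceeds by
windowed coverage classification: each window is labelled A or D from the
pooled, normalized progenitor depths using the same log2-ratio threshold as
whole-scaffold assignment, segments of like label are merged (ambiguous
windows neither break nor extend a segment), and a junction is emitted
between adjacent A and D segments when both flanks are long enough.
Junctions are projected onto reference chromosomes through a scaffold-to-
reference alignment table, and positional enrichment near chromosome ends is
tested by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import CoverageTrack, DatasetManifest, ScaffoldSet


@dataclass
class WindowLabelTrack:
    """Per-window A/D/ambiguous labels for one scaffold."""

    scaffold_id: str
    window: int
    length: int
    starts: np.ndarray
    ends: np.ndarray
    mean_A: np.ndarray
    mean_D: np.ndarray
    log2_ratio: np.ndarray
    labels: np.ndarray  # "A", "D" or "ambiguous"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaffold_id": self.scaffold_id,
                "start": self.starts,
                "end": self.ends,
                "mean_A": self.mean_A,
                "mean_D": self.mean_D,
                "log2_ratio": self.log2_ratio,
                "label": self.labels,
            }
        )


JUNCTION_COLUMNS = [
    "scaffold_id", "junction_start", "junction_end",
    "left_label", "right_label", "left_flank", "right_flank",
]


def window_classify(
    tracks: list[CoverageTrack],
    manifest: DatasetManifest,
    scaffolds: ScaffoldSet,
    config: PipelineConfig | None = None,
    window: int | None = None,
) -> dict[str, WindowLabelTrack]:
    """Label each window of each scaffold A, D or ambiguous.

    Pools the normalized per-window depths of the A-clade and D-clade tracks
    and thresholds the log2 ratio at ``log2_ratio_min``; windows whose ratio
    is inside the band (including zero-coverage windows, where the
    pseudocount drives the ratio to 0) are ambiguous.  A scaffold shorter
    than one window yields a single-window track.
    """
    config = config or PipelineConfig()
    window = window or config.hybrid_window
    by_id = {t.dataset_id: t for t in tracks}
    a_ids = [d for d in manifest.ids_for_clade("A") if d in by_id]
    d_ids = [d for d in manifest.ids_for_clade("D") if d in by_id]
    if not a_ids or not d_ids:
        raise ValueError("need at least one A-clade and one D-clade track")

    norms = {}
    for did in a_ids + d_ids:
        g = by_id[did].genome_mean_depth(scaffolds)
        norms[did] = g if (config.normalize_depths and g > 0) else 1.0

    out: dict[str, WindowLabelTrack] = {}
    eps = config.pseudocount
    for sc in scaffolds:
        n_win = max(1, -(-sc.length // window))
        starts = np.arange(n_win) * window
        ends = np.minimum(starts + window, sc.length)
        mean_a = np.mean(
            [by_id[d].binned_mean_depth(sc.scaffold_id, sc.length, window) / norms[d]
             for d in a_ids], axis=0)
        mean_d = np.mean(
            [by_id[d].binned_mean_depth(sc.scaffold_id, sc.length, window) / norms[d]
             for d in d_ids], axis=0)
        ratio = np.log2((mean_a + eps) / (mean_d + eps))
        labels = np.where(
            ratio > config.log2_ratio_min, "A",
            np.where(ratio < -config.log2_ratio_min, "D", "ambiguous"),
        )
        out[sc.scaffold_id] = WindowLabelTrack(
            sc.scaffold_id, window, sc.length, starts, ends, mean_a, mean_d, ratio, labels
        )
    return out


def _segments(track: WindowLabelTrack) -> list[dict]:
    """Merge same-label windows into segments; ambiguous windows are skipped
    (they neither break nor extend a segment)."""
    segs: list[dict] = []
    for i, lab in enumerate(track.labels):
        if lab == "ambiguous":
            continue
        if segs and segs[-1]["label"] == lab:
            segs[-1]["end"] = track.ends[i]
            segs[-1]["last_win"] = i
        else:
            segs.append(
                {"label": lab, "start": track.starts[i], "end": track.ends[i],
                 "first_win": i, "last_win": i}
            )
    return segs


def call_hybrids(
    track: WindowLabelTrack, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Emit junction calls between adjacent A and D segments of one scaffold.

    Both flanking segments must span at least ``hybrid_min_segment`` bases.
    The junction is reported as the interval between the end of the last
    unambiguous window on one side and the start of the first unambiguous
    window on the other (zero-width when the windows are adjacent).
    """
    config = config or PipelineConfig()
    segs = _segments(track)
    rows = []
    for left, right in zip(segs, segs[1:]):
        llen = left["end"] - left["start"]
        rlen = right["end"] - right["start"]
        if llen >= config.hybrid_min_segment and rlen >= config.hybrid_min_segment:
            rows.append(
                (track.scaffold_id, int(left["end"]), int(right["start"]),
                 left["label"], right["label"], int(llen), int(rlen))
            )
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


def call_all_hybrids(
    window_tracks: dict[str, WindowLabelTrack],
    config: PipelineConfig | None = None,
    ungrouped_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Scan every scaffold; optionally annotate the ungrouped subset.

    Scanning runs on all scaffolds, but when the set of ungrouped scaffold
    ids from whole-scaffold assignment is supplied each call is annotated
    with whether it falls in that subset (where hybrids are expected, since
    a half-A half-D scaffold fails the whole-scaffold ratio criterion).
    """
    frames = [call_hybrids(t, config) for t in window_tracks.values()]
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=JUNCTION_COLUMNS)
    )
    if ungrouped_ids is not None:
        calls["in_ungrouped"] = calls["scaffold_id"].isin(ungrouped_ids)
    return calls


# ---------------------------------------------------------------------------
# projection onto reference chromosomes
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "scaffold_id", "scaffold_start", "scaffold_end",
    "ref_chrom", "ref_start", "ref_end", "strand",
]


def project_junctions(calls: pd.DataFrame, alignments: pd.DataFrame) -> pd.DataFrame:
    """Project junction midpoints onto reference chromosome coordinates.

    Each junction midpoint is mapped through the alignment interval that
    contains it by linear interpolation, strand-aware.  Calls with no
    containing interval are returned with ``projected = False``.
    Overlapping alignment intervals on the same scaffold are an error.
    """
    for col in ALIGNMENT_COLUMNS:
        if col not in alignments.columns:
            raise ValueError(f"alignment table missing column {col!r}")
    for sid, sub in alignments.groupby("scaffold_id"):
        sub = sub.sort_values("scaffold_start")
        if (sub["scaffold_start"].values[1:] < sub["scaffold_end"].values[:-1]).any():
            raise ValueError(f"overlapping alignment intervals on scaffold {sid!r}")

    rows = []
    for _, call in calls.iterrows():
        mid = (call["junction_start"] + call["junction_end"]) / 2.0
        sub = alignments[alignments["scaffold_id"] == call["scaffold_id"]]
        hit = sub[(sub["scaffold_start"] <= mid) & (mid < sub["scaffold_end"])]
        if hit.empty:
            rows.append((call["scaffold_id"], mid, None, np.nan, False))
            continue
        aln = hit.iloc[0]
        frac = (mid - aln["scaffold_start"]) / (aln["scaffold_end"] - aln["scaffold_start"])
        span = aln["ref_end"] - aln["ref_start"]
        if aln["strand"] == "+":
            ref_pos = aln["ref_start"] + frac * span
        else:
            ref_pos = aln["ref_end"] - frac * span
        rows.append((call["scaffold_id"], mid, aln["ref_chrom"], ref_pos, True))
    return pd.DataFrame(
        rows, columns=["scaffold_id", "scaffold_pos", "ref_chrom", "ref_pos", "projected"]
    )


def subtelomeric_enrichment(
    sites: pd.DataFrame,
    chromosome_lengths: dict[str, int],
    n_permutations: int = 10_000,
    seed: int = 0,
    terminal_fraction: float = 0.10,
) -> dict:
    """Test whether projected sites cluster near chromosome ends.

    Reports the observed fraction of sites within the outer
    ``terminal_fraction`` of either end of their chromosome, and a
    permutation p-value against uniform random placement on the same
    chromosomes.  With ``n_permutations = 0`` only the observed fraction is
    reported and the p-value is flagged undefined (NaN).
    """
    placed = sites[sites["projected"]] if "projected" in sites.columns else sites
    if placed.empty:
        raise ValueError("no projected sites to test")
    chroms = placed["ref_chrom"].to_numpy()
    pos = placed["ref_pos"].to_numpy(dtype=float)
    lens = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    end_dist = np.minimum(pos, lens - pos)
    observed = float(np.mean(end_dist / lens <= terminal_fraction))
    result = {
        "n_sites": int(len(pos)),
        "terminal_fraction": terminal_fraction,
        "observed_fraction": observed,
        "expected_fraction": 2 * terminal_fraction,
        "p_value": float("nan"),
    }
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        upos = rng.uniform(0, lens, size=(n_permutations, len(pos)))
        frac = np.mean(np.minimum(upos, lens - upos) / lens <= terminal_fraction, axis=1)
        result["p_value"] = float((1 + np.sum(frac >= observed)) / (n_permutations + 1))
    return result
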