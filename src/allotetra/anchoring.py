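"""Pseudochromosome construction from a genetic map of SNP segments.

The genetic map supplies ordered markers, each carrying a 201 bp segment
(100 bp left of the SNP, the SNP base, 100 bp right).  Scaffolds are
anchored by three criteria: (1) a segment must align uniquely to the
scaffold set with at least 196 of its 201 bases matching (ungapped,
substitutions only — 196/201 implies at most 5 mismatches; indels are not
tolerated); (2) a scaffold must be hit by at least 5 markers continuous in
within-chromosome map order; (3) a scaffold may anchor to only one
chromosome.  Anchored scaffolds are ordered by the median map position of
their supporting run and oriented by the sign of the correlation between map
order and scaffold coordinate.

The matcher is exact for the mismatch budget: a segment with at most m
mismatches must contain an exact seed of length ``201 // (m + 1)`` at one of
m + 1 disjoint offsets (pigeonhole), so candidate placements are generated
from rolling-hash seed lookups and verified by direct mismatch counting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import Scaffold, ScaffoldSet, reverse_complement

logger = logging.getLogger("allotetra")

MARKER_COLUMNS = ["marker_id", "chromosome", "cM", "segment"]
HIT_COLUMNS = ["marker_id", "scaffold_id", "start", "strand", "matched", "unique"]

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_B = np.uint64(1_000_003)
_BINV = np.uint64(pow(1_000_003, -1, 2**64))


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; non-ACGT -> 4 (matches nothing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pow_array(base: np.uint64, n: int) -> np.ndarray:
    out = np.empty(n, dtype=np.uint64)
    out[0] = np.uint64(1)
    if n > 1:
        np.multiply.accumulate(np.full(n - 1, base, dtype=np.uint64), out=out[1:])
    return out


def window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling polynomial hash (mod 2^64) of every length-k window."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    powb = _pow_array(_B, n)
    prefix = np.zeros(n + 1, dtype=np.uint64)
    np.cumsum(codes.astype(np.uint64) * powb, out=prefix[1:])
    inv = _pow_array(_BINV, n - k + 1)
    return (prefix[k:] - prefix[: n - k + 1]) * inv


def mismatch_count(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming mismatches; any position with a non-ACGT code counts as a mismatch."""
    return int(np.sum((a != b) | (a >= 4) | (b >= 4)))


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------

def extract_segments(
    snp_table: pd.DataFrame,
    reference: ScaffoldSet,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Truncate a fixed-length segment around each mapped SNP.

    ``snp_table`` columns: marker_id, chromosome, cM, contig, pos (1-based
    SNP position on ``reference``).  The segment spans 100 bp left of the
    SNP, the SNP base and 100 bp right (201 bp total by default).  SNPs too
    close to a sequence end are skipped with a logged count.
    """
    config = config or PipelineConfig()
    flank = (config.segment_length - 1) // 2
    rows, skipped = [], 0
    for rec in snp_table.itertuples(index=False):
        if rec.contig not in reference:
            raise ValueError(f"reference sequence {rec.contig!r} absent")
        seq = reference[rec.contig].sequence
        if seq is None:
            raise ValueError(f"reference sequence {rec.contig!r} has no bases")
        p0 = int(rec.pos) - 1  # to 0-based
        if p0 < 0 or p0 >= len(seq):
            raise ValueError(f"SNP position {rec.pos} outside {rec.contig!r}")
        if p0 < flank or p0 + flank + 1 > len(seq):
            skipped += 1
            continue
        rows.append((rec.marker_id, rec.chromosome, rec.cM, seq[p0 - flank : p0 + flank + 1]))
    if skipped:
        logger.info("extract_segments: skipped %d SNPs within %d bp of a sequence end",
                    skipped, flank)
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def map_order(markers: pd.DataFrame) -> pd.DataFrame:
    """Add a within-chromosome map order index (by cM, stable on ties)."""
    markers = markers.copy()
    markers["order"] = (
        markers.groupby("chromosome")["cM"].rank(method="first").astype(int) - 1
    )
    return markers


# ---------------------------------------------------------------------------
# segment matching
# ---------------------------------------------------------------------------

def match_segments(
    markers: pd.DataFrame,
    scaffolds: ScaffoldSet,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Place each marker segment on the scaffolds by ungapped scan of both strands.

    Returns the best placements per marker (mismatches <= ``max_mismatches``),
    flagged ``unique`` when a marker has exactly one best placement
    genome-wide.  Markers with no placement or tied best placements carry
    ``unique = False`` (or are absent) and are logged; anchoring uses unique
    hits only.
    """
    config = config or PipelineConfig()
    seg_len = config.segment_length
    max_mm = config.max_mismatches
    k = seg_len // (max_mm + 1)
    offsets = [i * k for i in range(max_mm + 1)]

    marker_ids = markers["marker_id"].tolist()
    seg_codes: list[tuple[np.ndarray, np.ndarray]] = []
    seed_map: dict[int, list[tuple[int, str, int]]] = {}
    for m, seg in enumerate(markers["segment"]):
        if len(seg) != seg_len:
            raise ValueError(
                f"marker {marker_ids[m]!r}: segment length {len(seg)} != {seg_len}"
            )
        fwd = encode(seg)
        rev = encode(reverse_complement(seg))
        seg_codes.append((fwd, rev))
        for strand, codes in (("+", fwd), ("-", rev)):
            wh = window_hashes(codes, k)
            for off in offsets:
                seed_map.setdefault(int(wh[off]), []).append((m, strand, off))
    seed_hashes = np.array(sorted(seed_map), dtype=np.uint64)

    candidates: dict[tuple[int, str, int, str], int] = {}
    for sc in scaffolds:
        if sc.sequence is None:
            continue
        codes = encode(sc.sequence)
        wh = window_hashes(codes, k)
        if wh.size == 0:
            continue
        hit_pos = np.nonzero(np.isin(wh, seed_hashes))[0]
        for pos in hit_pos:
            for m, strand, off in seed_map.get(int(wh[pos]), ()):
                start = int(pos) - off
                if start < 0 or start + seg_len > sc.length:
                    continue
                key = (m, sc.scaffold_id, start, strand)
                if key in candidates:
                    continue
                seg = seg_codes[m][0] if strand == "+" else seg_codes[m][1]
                mm = mismatch_count(seg, codes[start : start + seg_len])
                if mm <= max_mm:
                    candidates[key] = seg_len - mm

    by_marker: dict[int, list[tuple[str, int, str, int]]] = {}
    for (m, sid, start, strand), matched in candidates.items():
        by_marker.setdefault(m, []).append((sid, start, strand, matched))

    rows, n_unplaced, n_tied = [], 0, 0
    for m in range(len(marker_ids)):
        hits = by_marker.get(m)
        if not hits:
            n_unplaced += 1
            continue
        best = max(h[3] for h in hits)
        best_hits = [h for h in hits if h[3] == best]
        unique = len(best_hits) == 1
        if not unique:
            n_tied += 1
        for sid, start, strand, matched in best_hits:
            rows.append((marker_ids[m], sid, start, strand, matched, unique))
    if n_unplaced or n_tied:
        logger.info("match_segments: %d markers unplaced, %d dropped as non-unique",
                    n_unplaced, n_tied)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = [
    "scaffold_id", "chromosome", "position", "median_cM", "orientation",
    "n_markers", "span_cM",
]


def _runs_for_chromosome(
    order_to_hit: dict[int, tuple[str, int]], n_markers: int, max_gap: int
) -> list[dict]:
    """Maximal runs of consecutive map-order markers hitting one scaffold.

    A missing marker (no unique hit) breaks a run once more than ``max_gap``
    consecutive orders are missing; a marker hitting a different scaffold
    always breaks.
    """
    runs: list[dict] = []
    current: dict | None = None
    gap = 0
    for order in range(n_markers):
        hit = order_to_hit.get(order)
        if hit is None:
            gap += 1
            if current is not None and gap > max_gap:
                runs.append(current)
                current = None
            continue
        sid, start = hit
        if current is not None and current["scaffold_id"] == sid:
            current["orders"].append(order)
            current["starts"].append(start)
        else:
            if current is not None:
                runs.append(current)
            current = {"scaffold_id": sid, "orders": [order], "starts": [start]}
        gap = 0
    if current is not None:
        runs.append(current)
    return runs


def anchor_scaffolds(
    hits: pd.DataFrame,
    markers: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Anchor scaffolds supported by continuous runs of uniquely placed markers.

    "Continuous" means consecutive in within-chromosome map order.  A
    scaffold is anchored to the chromosome of its longest qualifying run
    (>= ``min_continuous_segments`` markers); scaffolds with qualifying runs
    on more than one chromosome are rejected and logged.  Orientation comes
    from the sign of the correlation between map order and scaffold
    coordinate over the run's hits (zero/undefined -> unknown); scaffolds are
    ordered along each chromosome by the run's median cM.
    """
    config = config or PipelineConfig()
    if "order" not in markers.columns:
        markers = map_order(markers)
    uhits = hits[hits["unique"]].merge(
        markers[["marker_id", "chromosome", "cM", "order"]], on="marker_id"
    )

    best_runs: dict[str, dict[str, dict]] = {}  # scaffold -> chromosome -> best run
    for chrom, sub in uhits.groupby("chromosome"):
        n_markers = int(markers.loc[markers["chromosome"] == chrom, "order"].max()) + 1
        order_to_hit = {
            int(r.order): (r.scaffold_id, int(r.start)) for r in sub.itertuples()
        }
        cm_of = dict(
            zip(markers.loc[markers["chromosome"] == chrom, "order"].astype(int),
                markers.loc[markers["chromosome"] == chrom, "cM"])
        )
        for run in _runs_for_chromosome(order_to_hit, n_markers, config.max_run_gap):
            if len(run["orders"]) < config.min_continuous_segments:
                continue
            run["chromosome"] = chrom
            run["cMs"] = [cm_of[o] for o in run["orders"]]
            per = best_runs.setdefault(run["scaffold_id"], {})
            if chrom not in per or len(run["orders"]) > len(per[chrom]["orders"]):
                per[chrom] = run

    rows, rejected = [], []
    for sid, per_chrom in best_runs.items():
        if len(per_chrom) > 1:
            rejected.append(sid)
            continue
        run = next(iter(per_chrom.values()))
        orders = np.asarray(run["orders"], dtype=float)
        starts = np.asarray(run["starts"], dtype=float)
        if np.ptp(starts) == 0 or np.ptp(orders) == 0:
            orientation = "unknown"
        else:
            corr = np.corrcoef(orders, starts)[0, 1]
            orientation = "+" if corr > 0 else "-" if corr < 0 else "unknown"
        cms = np.asarray(run["cMs"], dtype=float)
        rows.append(
            (sid, run["chromosome"], float(np.median(cms)), orientation,
             len(orders), float(cms.max() - cms.min()))
        )
    if rejected:
        logger.info("anchor_scaffolds: rejected %d scaffolds with qualifying runs "
                    "on multiple chromosomes: %s", len(rejected), sorted(rejected)[:10])

    df = pd.DataFrame(
        rows,
        columns=["scaffold_id", "chromosome", "median_cM", "orientation",
                 "n_markers", "span_cM"],
    ).sort_values(["chromosome", "median_cM"], kind="stable")
    df["position"] = df.groupby("chromosome").cumcount()
    return df[ANCHOR_COLUMNS].reset_index(drop=True)


def build_pseudochromosomes(
    anchored: pd.DataFrame,
    scaffolds: ScaffoldSet,
    gap_size: int = 100,
) -> tuple[ScaffoldSet, pd.DataFrame]:
    """Concatenate anchored scaffolds into chromosome sequences.

    Scaffolds are placed in map order, reverse-complemented when orientation
    is "-" (unknown treated as "+"), separated by ``gap_size`` N bases.
    Returns the chromosome sequences and an AGP-like layout table with the
    coordinates of every placement.
    """
    if anchored["scaffold_id"].duplicated().any():
        dup = anchored.loc[anchored["scaffold_id"].duplicated(), "scaffold_id"].iloc[0]
        raise ValueError(f"scaffold {dup!r} placed more than once")
    chrom_records, layout = [], []
    for chrom, sub in anchored.sort_values(["chromosome", "position"]).groupby("chromosome"):
        parts, cursor = [], 0
        for rec in sub.itertuples():
            sc = scaffolds[rec.scaffold_id]
            if sc.sequence is None:
                raise ValueError(f"scaffold {rec.scaffold_id!r} has no sequence")
            seq = (
                reverse_complement(sc.sequence)
                if rec.orientation == "-" else sc.sequence
            )
            if parts:
                parts.append("N" * gap_size)
                cursor += gap_size
            parts.append(seq)
            layout.append(
                (chrom, cursor, cursor + sc.length, rec.scaffold_id, rec.orientation,
                 rec.position)
            )
            cursor += sc.length
        seq = "".join(parts)
        chrom_records.append(Scaffold(str(chrom), len(seq), seq))
    layout_df = pd.DataFrame(
        layout,
        columns=["chromosome", "start", "end", "scaffold_id", "orientation", "position"],
    )
    return ScaffoldSet(chrom_records), layout_df
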