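"""Readers, writers and shared domain containers.

Internal coordinates are 0-based half-open (BED convention) throughout the
package; VCF positions and SNP-table positions are converted at the format
boundary.  Tabular artefacts are tab-separated with a header row and
round-trip losslessly through :func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("allotetra")

VALID_CLADES = ("A", "D", "AD")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """One assembly scaffold; ``sequence`` may be None for a length-only stub."""

    scaffold_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.scaffold_id!r}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"scaffold {self.scaffold_id!r}: length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


class ScaffoldSet:
    """An ordered collection of scaffolds with unique ids."""

    def __init__(self, scaffolds: Iterable[Scaffold]) -> None:
        self._by_id: dict[str, Scaffold] = {}
        for sc in scaffolds:
            if sc.scaffold_id in self._by_id:
                raise ValueError(f"duplicate scaffold id {sc.scaffold_id!r}")
            self._by_id[sc.scaffold_id] = sc

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self._by_id.values())

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._by_id

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        return self._by_id[scaffold_id]

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def lengths(self) -> dict[str, int]:
        return {sid: sc.length for sid, sc in self._by_id.items()}

    @property
    def total_length(self) -> int:
        return sum(sc.length for sc in self)


@dataclass(frozen=True)
class Dataset:
    """One sequencing dataset (a progenitor or tetraploid line)."""

    dataset_id: str
    clade: str
    line_label: str = ""

    def __post_init__(self) -> None:
        if self.clade not in VALID_CLADES:
            raise ValueError(
                f"dataset {self.dataset_id!r}: clade must be one of {VALID_CLADES}, "
                f"got {self.clade!r}"
            )


class DatasetManifest:
    """Maps each coverage/variant dataset to its clade (A, D or AD)."""

    def __init__(self, datasets: Iterable[Dataset]) -> None:
        self.datasets = list(datasets)
        ids = [d.dataset_id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate dataset ids in manifest")
        self._clade = {d.dataset_id: d.clade for d in self.datasets}

    def __len__(self) -> int:
        return len(self.datasets)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    def clade_of(self, dataset_id: str) -> str:
        return self._clade[dataset_id]

    def ids_for_clade(self, clade: str) -> list[str]:
        if clade not in VALID_CLADES:
            raise ValueError(f"unknown clade {clade!r}")
        return [d.dataset_id for d in self.datasets if d.clade == clade]

    def require_replicates(self, clade: str, n: int = 2) -> None:
        have = len(self.ids_for_clade(clade))
        if have < n:
            raise ValueError(
                f"clade {clade} has {have} dataset(s); at least {n} replicate "
                f"lines are required for the t-test (disable criterion 3 "
                f"explicitly via config if replicates are unavailable)"
            )


class CoverageTrack:
    """Per-scaffold interval depth for one sequencing dataset.

    Intervals are stored per scaffold as a float array of columns
    (start, end, depth), 0-based half-open, non-overlapping, sorted by start.
    Bases not covered by any interval have implicit depth 0.
    """

    def __init__(
        self,
        dataset_id: str,
        intervals: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.dataset_id = dataset_id
        self.intervals: dict[str, np.ndarray] = {}
        if intervals:
            for sid, arr in intervals.items():
                self.intervals[sid] = self._validate(sid, np.asarray(arr, dtype=float))

    @staticmethod
    def _validate(sid: str, arr: np.ndarray) -> np.ndarray:
        if arr.size == 0:
            return arr.reshape(0, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"{sid}: intervals must be (n, 3) [start, end, depth]")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        if np.any(arr[:, 1] <= arr[:, 0]):
            raise ValueError(f"{sid}: empty or inverted interval")
        if np.any(arr[:, 2] < 0):
            raise ValueError(f"{sid}: negative depth")
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError(f"{sid}: overlapping intervals")
        return arr

    def add(self, scaffold_id: str, arr: np.ndarray) -> None:
        self.intervals[scaffold_id] = self._validate(
            scaffold_id, np.asarray(arr, dtype=float)
        )

    def get(self, scaffold_id: str) -> np.ndarray:
        return self.intervals.get(scaffold_id, np.empty((0, 3)))

    def depth_sum(self, scaffold_id: str) -> float:
        """Total depth x length over the scaffold's intervals."""
        arr = self.get(scaffold_id)
        if arr.size == 0:
            return 0.0
        return float(np.sum((arr[:, 1] - arr[:, 0]) * arr[:, 2]))

    def mean_depth(self, scaffold_id: str, length: int) -> float:
        """Mean depth averaged over ALL bases, covered or not."""
        return self.depth_sum(scaffold_id) / length

    def genome_mean_depth(self, scaffolds: ScaffoldSet) -> float:
        total = sum(self.depth_sum(sid) for sid in self.intervals)
        return total / scaffolds.total_length

    def covered_intervals(self, scaffold_id: str, min_depth: float = 1.0) -> np.ndarray:
        """(n, 2) start/end array of intervals with depth >= min_depth."""
        arr = self.get(scaffold_id)
        if arr.size == 0:
            return np.empty((0, 2))
        return arr[arr[:, 2] >= min_depth, :2]

    def binned_mean_depth(self, scaffold_id: str, length: int, window: int) -> np.ndarray:
        """Mean depth in consecutive windows tiling the scaffold (last may be short)."""
        n_win = max(1, -(-length // window))
        sums = np.zeros(n_win)
        arr = self.get(scaffold_id)
        for start, end, depth in arr:
            w0, w1 = int(start // window), int((end - 1) // window)
            for w in range(w0, w1 + 1):
                lo = max(start, w * window)
                hi = min(end, (w + 1) * window)
                sums[w] += (hi - lo) * depth
        sizes = np.full(n_win, window, dtype=float)
        sizes[-1] = length - (n_win - 1) * window
        return sums / sizes


def merge_intervals(pieces: Sequence[np.ndarray]) -> np.ndarray:
    """Union of (n, 2) interval arrays; returns merged, sorted (m, 2) array."""
    stacked = [np.asarray(p, dtype=float).reshape(-1, 2) for p in pieces if len(p)]
    if not stacked:
        return np.empty((0, 2))
    arr = np.concatenate(stacked)
    arr = arr[np.argsort(arr[:, 0], kind="stable")]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged)


def union_covered_fraction(
    tracks: Sequence[CoverageTrack], scaffold_id: str, length: int,
    min_depth: float = 1.0,
) -> float:
    """Fraction of bases covered at >= min_depth by the union of the tracks."""
    merged = merge_intervals(
        [t.covered_intervals(scaffold_id, min_depth) for t in tracks]
    )
    if merged.size == 0:
        return 0.0
    return float(np.sum(merged[:, 1] - merged[:, 0]) / length)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a FASTA file into a :class:`ScaffoldSet`.

    Record ids are the first whitespace-delimited header token; sequences are
    uppercased with IUPAC ambiguity codes preserved.  Duplicate ids are a hard
    error; an empty file yields an empty set with a warning.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(Scaffold(rec.id, len(rec.seq), str(rec.seq).upper()))
    if not records:
        warnings.warn(f"FASTA file {path} contains no records", stacklevel=2)
    return ScaffoldSet(records)


def write_fasta(scaffolds: Iterable[Scaffold], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sc in scaffolds:
            if sc.sequence is None:
                raise ValueError(f"scaffold {sc.scaffold_id!r} has no sequence to write")
            fh.write(f">{sc.scaffold_id}\n")
            for i in range(0, sc.length, width):
                fh.write(sc.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# bedgraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, dataset_id: str, scaffolds: ScaffoldSet) -> CoverageTrack:
    """Read a 4-column bedgraph (0-based half-open) into a CoverageTrack.

    Every interval is validated against the scaffold bounds; regions not
    listed are implicitly depth 0.
    """
    per_scaffold: dict[str, list[list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            sid, start, end, depth = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if sid not in scaffolds:
                raise ValueError(f"{path}:{lineno}: unknown scaffold {sid!r}")
            if start < 0 or end > scaffolds[sid].length:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside scaffold "
                    f"{sid!r} of length {scaffolds[sid].length}"
                )
            per_scaffold.setdefault(sid, []).append([start, end, depth])
    track = CoverageTrack(dataset_id)
    for sid, rows in per_scaffold.items():
        track.add(sid, np.asarray(rows))
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(track.intervals):
            for start, end, depth in track.intervals[sid]:
                d = int(depth) if float(depth).is_integer() else depth
                fh.write(f"{sid}\t{int(start)}\t{int(end)}\t{d}\n")


# ---------------------------------------------------------------------------
# tab-separated tables
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path, schema: Sequence[str] | None = None) -> None:
    """Write a DataFrame as a tab-separated table with a header row.

    Column order follows ``schema`` when given (all schema columns must be
    present).  String fields must be tab-free so the table round-trips.
    """
    df = records
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValueError(f"records missing schema columns {missing}")
        df = df[list(schema)]
    for col in df.columns:
        if df[col].dtype == object:
            values = df[col].dropna().astype(str)
            if values.str.contains("\t").any():
                raise ValueError(f"column {col!r} contains a tab character")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_scaffold_table(path: str | Path) -> ScaffoldSet:
    """Read a length-only scaffold table (columns scaffold_id, length)."""
    df = read_table(path)
    return ScaffoldSet(
        Scaffold(str(s), int(l)) for s, l in zip(df["scaffold_id"], df["length"])
    )


def write_scaffold_table(scaffolds: ScaffoldSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(sc.scaffold_id, sc.length) for sc in scaffolds],
        columns=["scaffold_id", "length"],
    )
    write_table(df, path)


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest TSV with columns dataset_id, clade, line_label."""
    df = read_table(path)
    line = df["line_label"] if "line_label" in df.columns else [""] * len(df)
    return DatasetManifest(
        Dataset(str(r), str(c), str(l))
        for r, c, l in zip(df["dataset_id"], df["clade"], line)
    )


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [(d.dataset_id, d.clade, d.line_label) for d in manifest.datasets],
        columns=["dataset_id", "clade", "line_label"],
    )
    write_table(df, path)


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to standard error."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
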