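"""LTR retrotransposon insertion dating and family clustering.

An intact LTR retrotransposon carries two terminal repeats that were
identical at insertion; their present-day divergence dates the element.
Divergence K is estimated under the Kimura two-parameter model,

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q),

where P and Q are the transition and transversion proportions over comparable
sites, and the insertion time is T = K / (2r) with r the substitution rate
per site per year (default 1.3e-8).  Saturated pairs (1 - 2P - Q <= 0 or
1 - 2Q <= 0) are flagged undefined rather than clamped, so they cannot
silently bias the age distribution.

Gap and ambiguous (non-ACGT) columns are excluded from the comparison
(pairwise deletion).  Unequal-length pairs are first aligned by a bundled
global aligner (match +1, mismatch -1, gap open -2, gap extend -0.5);
pre-aligned input of equal length bypasses it.

Families are connected components of the reciprocal-similarity graph built
from an all-vs-all search edge table filtered at e-value <= 1e-5; only edges
present in both directions are kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    compared_sites: int
    K: float          # NaN when undefined
    defined: bool


@dataclass(frozen=True)
class LTRPair:
    element_id: str
    five_prime_seq: str
    three_prime_seq: str
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if not self.five_prime_seq or not self.three_prime_seq:
            raise ValueError(f"element {self.element_id!r}: empty LTR sequence")


def read_ltr_pairs(path: str) -> list[LTRPair]:
    """Read paired LTR FASTA where ids are suffixed ``_5p`` / ``_3p``."""
    from Bio import SeqIO

    five: dict[str, str] = {}
    three: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id.endswith("_5p"):
            five[rec.id[:-3]] = str(rec.seq).upper()
        elif rec.id.endswith("_3p"):
            three[rec.id[:-3]] = str(rec.seq).upper()
        else:
            raise ValueError(f"LTR record id {rec.id!r} lacks a _5p/_3p suffix")
    odd = set(five) ^ set(three)
    if odd:
        raise ValueError(f"unpaired LTR elements: {sorted(odd)[:5]}")
    return [LTRPair(eid, five[eid], three[eid]) for eid in sorted(five)]


def write_ltr_pairs(pairs: list[LTRPair], path: str) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f">{p.element_id}_5p\n{p.five_prime_seq}\n")
            fh.write(f">{p.element_id}_3p\n{p.three_prime_seq}\n")


def align_global(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment; returns the two gapped sequences."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-0.5,
    )
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def k2p_divergence(a: str, b: str) -> K2PResult:
    """Kimura two-parameter divergence between two sequences.

    Equal-length input is treated as already aligned; otherwise the bundled
    global aligner is applied first.  Columns with a gap or non-ACGT base in
    either sequence are excluded (pairwise deletion).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        a, b = align_global(a, b)
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P, Q, n, float("nan"), False)
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P, Q, n, K, True)


AGE_COLUMNS = ["element_id", "K", "P", "Q", "compared_sites", "defined", "r", "T_years"]


def insertion_age(k2p: K2PResult, r: float) -> float:
    """Insertion time T = K / (2r) in years; NaN when K is undefined."""
    if r <= 0:
        raise ValueError("substitution rate r must be positive")
    if not k2p.defined:
        return float("nan")
    return k2p.K / (2.0 * r)


def date_pairs(pairs: list[LTRPair], r: float = 1.3e-8) -> pd.DataFrame:
    """K2P divergence and insertion age for every LTR pair."""
    rows = []
    for pair in pairs:
        res = k2p_divergence(pair.five_prime_seq, pair.three_prime_seq)
        rows.append(
            (pair.element_id, res.K, res.P, res.Q, res.compared_sites,
             res.defined, r, insertion_age(res, r))
        )
    df = pd.DataFrame(rows, columns=AGE_COLUMNS)
    if pairs and all(p.subgenome is not None for p in pairs):
        df["subgenome"] = [p.subgenome for p in pairs]
    return df


def age_distribution(
    ages: pd.DataFrame,
    bin_years: float = 5.0e5,
    group_column: str | None = "subgenome",
) -> pd.DataFrame:
    """Histogram of defined insertion ages per group, with the mode bin.

    Returns one row per (group, bin) with counts, plus ``is_mode`` marking
    each group's most populated bin.  Empty groups (all ages undefined) are
    flagged with a single NaN-bin row.
    """
    defined = ages[ages["defined"] & np.isfinite(ages["T_years"])]
    if defined.empty:
        raise ValueError("no defined insertion ages to bin")
    groups = (
        defined.groupby(group_column)
        if group_column and group_column in defined.columns
        else [("all", defined)]
    )
    rows = []
    for name, sub in groups:
        if sub.empty:
            rows.append((name, float("nan"), float("nan"), 0, False))
            continue
        idx = np.floor(sub["T_years"].to_numpy() / bin_years).astype(int)
        counts = pd.Series(idx).value_counts().sort_index()
        mode_bin = counts.idxmax()
        for b, c in counts.items():
            rows.append((name, b * bin_years, (b + 1) * bin_years, int(c), b == mode_bin))
    return pd.DataFrame(
        rows, columns=["group", "bin_start_years", "bin_end_years", "count", "is_mode"]
    )


# ---------------------------------------------------------------------------
# family clustering
# ---------------------------------------------------------------------------

def cluster_families(
    edges: pd.DataFrame, evalue_max: float = 1.0e-5
) -> pd.DataFrame:
    """Cluster elements into families from reciprocal similarity edges.

    ``edges`` columns: query, subject, evalue.  Self-edges are discarded and
    the e-value filter is re-applied defensively; only reciprocal pairs (an
    edge in both directions) connect elements.  Families are the connected
    components of the reciprocal graph, numbered deterministically by their
    smallest member id; elements appearing only in non-reciprocal edges stay
    singletons.
    """
    all_nodes = pd.concat([edges["query"], edges["subject"]]).unique()
    edges = edges[(edges["query"] != edges["subject"]) & (edges["evalue"] <= evalue_max)]
    pairs = set(zip(edges["query"], edges["subject"]))
    reciprocal = {(q, s) for q, s in pairs if (s, q) in pairs and q < s}

    graph = nx.Graph()
    graph.add_nodes_from(all_nodes)
    graph.add_edges_from(reciprocal)

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    rows = [
        (member, fam, comp[0], len(comp))
        for fam, comp in enumerate(components)
        for member in comp
    ]
    return pd.DataFrame(rows, columns=["element_id", "family", "family_rep", "family_size"])


def solo_intact_ratio(counts: pd.DataFrame) -> pd.DataFrame:
    """(solo + truncated) / intact per group; intact = 0 flags the ratio undefined.

    ``counts`` columns: group, solo, truncated, intact (non-negative ints).
    """
    for col in ("solo", "truncated", "intact"):
        if (counts[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    out = counts.copy()
    intact = counts["intact"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (counts["solo"] + counts["truncated"]).to_numpy(dtype=float) / intact
    out["ratio"] = np.where(intact > 0, ratio, np.nan)
    out["defined"] = intact > 0
    return out
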