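"""Synthetic allotetraploid generator with full ground truth.

Every downstream stage of the pipeline is exercisable without external data:
the generator emits (i) clade-structured coverage tracks over a scaffold set
with known At/Dt/ungrouped truth and optional hybrid scaffolds with recorded
junctions, (ii) LTR pairs diverged under a Kimura two-parameter process at
known ages, (iii) an FPKM matrix with planted tissue-specific homoeolog
bias, and (iv) a genetic map of 201 bp segments copied from known scaffold
offsets plus a multi-sample VCF with planted lineage-specific alleles.

Coverage is simulated directly as depth tracks rather than reads: the
classifier consumes coverage, and subgenome divergence is expressed through
clade-differential mappability (a progenitor's reads cover only its own
subgenome's scaffolds), not through sequence emission — actual bases are
generated only where they matter (marker segments, LTRs, VCF ref alleles).
Depth noise is negative binomial (mean/dispersion), with Poisson as the
dispersion -> infinity limit; overdispersion is the realistic stress for the
replicate t-test.  All outputs are deterministic under ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CoverageTrack, Dataset, DatasetManifest, Scaffold, ScaffoldSet,
    reverse_complement,
)
from .ltr import LTRPair

DEFAULT_TISSUES = ("root", "stem", "leaf", "petal", "ovule", "callus", "FE", "FS")

# decode table matching the A=0, G=1, C=2, T=3 encoding used for the
# transition XOR trick (code ^ 1 is the transition partner)
_BASES = "AGCT"


@dataclass(frozen=True)
class SimulationParams:
    """Study-shaped defaults for every simulator.

    The coverage defaults (200 scaffolds, half At among grouped, 10%
    ungrouped, 3 A + 3 D replicate lines at 20x, negative-binomial noise
    with dispersion 10) are the package's standard evaluation conditions;
    the LTR, expression and map defaults mirror the published operating
    point (ages around the 1-3 Myr amplification bursts at r = 1.3e-8,
    8-tissue FPKM panel with FE/FS stages, 201 bp segments).
    """

    # --- tetraploid coverage ---
    n_scaffolds: int = 200
    at_fraction: float = 0.5            # At share of the grouped scaffolds
    ungrouped_fraction: float = 0.10    # share of non-hybrid scaffolds
    scaffold_length: tuple[int, int] = (30_000, 80_000)
    n_replicates_A: int = 3
    n_replicates_D: int = 3
    n_replicates_AD: int = 1
    depth_mean: float = 20.0
    depth_noise: str = "negbin"         # "negbin" | "poisson" | "none"
    dispersion: float = 10.0
    noise_bin: int = 1_000
    cross_coverage_fraction: float = 0.05   # other-clade residual mappability
    cross_depth: float = 1.0
    ungrouped_coverage_fraction: float = 0.20
    n_hybrids: int = 0
    hybrid_flank_min: int = 52_000      # junction kept this far from both ends

    # --- LTR pairs ---
    ltr_true_ages: tuple[float, ...] = (1.0e6, 2.0e6, 3.0e6)
    ltr_pairs_per_age: int = 200
    ltr_length: int = 1_000
    ltr_ts_tv_ratio: float = 2.0
    substitution_rate_r: float = 1.3e-8
    ltr_age_groups: tuple[tuple[str, float], ...] = ()  # optional (label, age)

    # --- homoeolog expression ---
    n_pairs: int = 1_000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    bias_tissue: str = "FE"
    at_bias_fraction: float = 0.30
    dt_bias_fraction: float = 0.20
    bias_effect_size: float = 4.0
    expression_sigma: float = 0.15      # per-gene lognormal noise (natural log)
    focal_meanlog: float = math.log(20.0)
    focal_sdlog: float = 0.5
    background_meanlog: float = math.log(5.0)
    background_sdlog: float = 1.0

    # --- genetic map and VCF ---
    n_chromosomes: int = 5
    markers_per_chromosome: int = 200
    marker_spacing: int = 1_000
    scaffolds_per_chromosome: int = 20
    unmatchable_fraction: float = 0.02  # markers mutated at 6 positions
    duplicated_fraction: float = 0.02   # markers with a planted second copy
    reverse_fraction: float = 0.30      # shredded scaffolds stored revcomp
    n_lineage_sites: int = 1_000
    n_shared_sites: int = 1_000
    site_depth: int = 20

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("at_fraction", "ungrouped_fraction", "cross_coverage_fraction",
                     "ungrouped_coverage_fraction", "unmatchable_fraction",
                     "duplicated_fraction", "reverse_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.at_bias_fraction + self.dt_bias_fraction > 1:
            raise ValueError("bias fractions must sum to <= 1")
        if self.n_hybrids > self.n_scaffolds:
            raise ValueError("n_hybrids cannot exceed n_scaffolds")
        if self.depth_noise not in ("negbin", "poisson", "none"):
            raise ValueError("depth_noise must be 'negbin', 'poisson' or 'none'")
        if self.ltr_length < 50:
            raise ValueError("ltr_length must be >= 50")

    def replace(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth records; each simulator fills only its own fields."""

    scaffold_subgenome: dict[str, str] = field(default_factory=dict)
    junctions: pd.DataFrame | None = None
    marker_truth: pd.DataFrame | None = None
    scaffold_origin: pd.DataFrame | None = None
    ltr_ages: dict[str, float] = field(default_factory=dict)
    bias_truth: pd.DataFrame | None = None
    lineage_snp_truth: pd.DataFrame | None = None


def default_manifest(params: SimulationParams) -> DatasetManifest:
    datasets = (
        [Dataset(f"A{i + 1}", "A", f"A-line-{i + 1}") for i in range(params.n_replicates_A)]
        + [Dataset(f"D{i + 1}", "D", f"D-line-{i + 1}") for i in range(params.n_replicates_D)]
        + [Dataset(f"AD{i + 1}", "AD", f"AD-line-{i + 1}") for i in range(params.n_replicates_AD)]
    )
    return DatasetManifest(datasets)


# ---------------------------------------------------------------------------
# clade-structured coverage
# ---------------------------------------------------------------------------

def _noisy_intervals(
    start: int, end: int, mean: float, params: SimulationParams, rng: np.random.Generator
) -> list[list[float]]:
    """Depth intervals for one covered region under the configured noise model."""
    if params.depth_noise == "none" or mean == 0:
        return [[start, end, mean]] if mean > 0 else []
    edges = list(range(start, end, params.noise_bin)) + [end]
    n = len(edges) - 1
    if params.depth_noise == "poisson":
        depths = rng.poisson(mean, size=n)
    else:
        k = params.dispersion
        depths = rng.negative_binomial(k, k / (k + mean), size=n)
    return [
        [edges[i], edges[i + 1], float(d)] for i, d in enumerate(depths) if d > 0
    ]


def simulate_tetraploid(
    params: SimulationParams | None = None,
) -> tuple[ScaffoldSet, list[CoverageTrack], DatasetManifest, SyntheticTruth]:
    """Generate a scaffold set with clade-structured coverage tracks.

    At-truth scaffolds are fully covered by A-clade and AD-clade tracks and
    nearly uncovered by D-clade tracks (a small ``cross_coverage_fraction``
    at low depth mimics residual cross-mappability), and vice versa.
    Ungrouped-truth scaffolds are covered over only
    ``ungrouped_coverage_fraction`` of their bases in every clade, failing
    the covered-fraction criterion.  Hybrid scaffolds switch clade signal at
    a recorded junction.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng([params.rng_seed, 101])
    manifest = default_manifest(params)

    n_rest = params.n_scaffolds - params.n_hybrids
    n_ug = round(params.ungrouped_fraction * n_rest)
    n_at = round(params.at_fraction * (n_rest - n_ug))
    n_dt = n_rest - n_ug - n_at
    labels = (
        ["hybrid"] * params.n_hybrids + ["At"] * n_at + ["Dt"] * n_dt
        + ["ungrouped"] * n_ug
    )
    labels = [labels[i] for i in rng.permutation(len(labels))]

    lo, hi = params.scaffold_length
    lengths = rng.integers(lo, hi + 1, size=params.n_scaffolds)
    scaffolds = ScaffoldSet(
        Scaffold(f"scf{i:04d}", int(lengths[i])) for i in range(params.n_scaffolds)
    )

    truth = SyntheticTruth()
    junction_rows = []
    for sid, lab, length in zip(scaffolds.ids, labels, lengths):
        if lab == "hybrid":
            if length < 2 * params.hybrid_flank_min:
                raise ValueError(
                    "hybrid scaffolds need length >= 2 * hybrid_flank_min"
                )
            pos = int(rng.integers(params.hybrid_flank_min,
                                   length - params.hybrid_flank_min + 1))
            left, right = ("At", "Dt") if rng.random() < 0.5 else ("Dt", "At")
            junction_rows.append((sid, pos, left, right))
            truth.scaffold_subgenome[sid] = "ungrouped"  # fails whole-scaffold criteria
        else:
            truth.scaffold_subgenome[sid] = lab
    truth.junctions = pd.DataFrame(
        junction_rows, columns=["scaffold_id", "position", "left_label", "right_label"]
    )
    junction_of = {r[0]: r[1:] for r in junction_rows}

    tracks = []
    for ds in manifest.datasets:
        track = CoverageTrack(ds.dataset_id)
        for sid, lab, length in zip(scaffolds.ids, labels, lengths):
            length = int(length)
            regions: list[tuple[int, int, float]] = []  # (start, end, mean depth)
            if lab == "hybrid":
                pos, left, right = junction_of[sid]
                for (start, end, part) in ((0, pos, left), (pos, length, right)):
                    own = (part == "At" and ds.clade == "A") or (
                        part == "Dt" and ds.clade == "D") or ds.clade == "AD"
                    if own:
                        regions.append((start, end, params.depth_mean))
                    elif params.cross_coverage_fraction > 0:
                        span = int(params.cross_coverage_fraction * (end - start))
                        if span > 0:
                            regions.append((start, start + span, params.cross_depth))
            elif lab == "ungrouped":
                span = int(params.ungrouped_coverage_fraction * length)
                if span > 0:
                    regions.append((0, span, params.depth_mean))
            else:
                own = (lab == "At" and ds.clade == "A") or (
                    lab == "Dt" and ds.clade == "D") or ds.clade == "AD"
                if own:
                    regions.append((0, length, params.depth_mean))
                elif params.cross_coverage_fraction > 0:
                    span = int(params.cross_coverage_fraction * length)
                    if span > 0:
                        regions.append((0, span, params.cross_depth))
            rows: list[list[float]] = []
            for start, end, mean in regions:
                rows.extend(_noisy_intervals(start, end, mean, params, rng))
            if rows:
                track.add(sid, np.asarray(rows))
        tracks.append(track)
    return scaffolds, tracks, manifest, truth


# ---------------------------------------------------------------------------
# LTR pairs under a Kimura two-parameter process
# ---------------------------------------------------------------------------

def _k2p_branch_probs(t_years: float, r: float, ts_tv: float) -> tuple[float, float]:
    """(transition, per-transversion-type) substitution probabilities after
    evolving one branch for ``t_years`` at total rate ``r`` per site per year."""
    alpha = r * ts_tv / (ts_tv + 1.0)       # transition rate
    beta = r / (2.0 * (ts_tv + 1.0))        # each of the two transversion rates
    e4b = math.exp(-4.0 * beta * t_years)
    e2ab = math.exp(-2.0 * (alpha + beta) * t_years)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv_each = 0.25 - 0.25 * e4b
    return p_ts, p_tv_each


def _evolve(codes: np.ndarray, t_years: float, params: SimulationParams,
            rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k2p_branch_probs(t_years, params.substitution_rate_r,
                                   params.ltr_ts_tv_ratio)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = codes[ts_mask] ^ 1            # A<->G, C<->T
    out[tv1_mask] = (codes[tv1_mask] + 2) % 4
    out[tv2_mask] = ((codes[tv2_mask] ^ 1) + 2) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def simulate_ltr_pairs(
    params: SimulationParams | None = None,
) -> tuple[list[LTRPair], SyntheticTruth]:
    """Generate LTR pairs whose copies diverged at known ages.

    Each element starts as two identical terminal repeats; both copies then
    evolve independently for the element's true age under a K2P process with
    total substitution rate ``substitution_rate_r`` and
    transition:transversion ratio ``ltr_ts_tv_ratio``, so the expected
    divergence is K = 2 r T.  ``ltr_age_groups`` optionally attaches a
    subgenome label per age (e.g. Dt at 1.9 Myr, At at 3.1 Myr).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng([params.rng_seed, 202])
    schedule: list[tuple[str | None, float]] = (
        [(label, age) for label, age in params.ltr_age_groups]
        if params.ltr_age_groups
        else [(None, age) for age in params.ltr_true_ages]
    )
    pairs: list[LTRPair] = []
    truth = SyntheticTruth()
    idx = 0
    for label, age in schedule:
        for _ in range(params.ltr_pairs_per_age):
            ancestor = rng.integers(0, 4, size=params.ltr_length).astype(np.uint8)
            five = _evolve(ancestor, age, params, rng)
            three = _evolve(ancestor, age, params, rng)
            eid = f"ltr{idx:05d}"
            pairs.append(LTRPair(eid, _decode(five), _decode(three), label))
            truth.ltr_ages[eid] = age
            idx += 1
    return pairs, truth


# ---------------------------------------------------------------------------
# homoeolog expression with planted bias
# ---------------------------------------------------------------------------

def simulate_expression(
    params: SimulationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """FPKM matrix and homoeolog pairs with planted tissue-specific bias.

    Unbiased pairs draw both genes from a shared per-pair, per-tissue
    lognormal mean with small per-gene noise; biased pairs additionally
    multiply the favoured gene by ``bias_effect_size`` in the focal tissue,
    where their shared mean is drawn at the higher "focal" level so planted
    bias acts on well-expressed pairs.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng([params.rng_seed, 303])
    n = params.n_pairs
    tissues = list(params.tissues)
    if params.bias_tissue not in tissues:
        raise ValueError(f"bias_tissue {params.bias_tissue!r} not in tissue panel")
    focal = tissues.index(params.bias_tissue)

    n_at = round(params.at_bias_fraction * n)
    n_dt = round(params.dt_bias_fraction * n)
    labels = np.array(
        ["At-biased"] * n_at + ["Dt-biased"] * n_dt + ["unbiased"] * (n - n_at - n_dt)
    )
    labels = labels[rng.permutation(n)]

    shared = rng.lognormal(params.background_meanlog, params.background_sdlog,
                           size=(n, len(tissues)))
    biased = labels != "unbiased"
    shared[biased, focal] = rng.lognormal(params.focal_meanlog, params.focal_sdlog,
                                          size=int(biased.sum()))
    noise_at = rng.lognormal(0.0, params.expression_sigma, size=shared.shape)
    noise_dt = rng.lognormal(0.0, params.expression_sigma, size=shared.shape)
    at = shared * noise_at
    dt = shared * noise_dt
    at[labels == "At-biased", focal] *= params.bias_effect_size
    dt[labels == "Dt-biased", focal] *= params.bias_effect_size

    at_genes = [f"GbAt{i:05d}" for i in range(n)]
    dt_genes = [f"GbDt{i:05d}" for i in range(n)]
    matrix = pd.DataFrame(
        np.vstack([at, dt]), index=at_genes + dt_genes, columns=tissues
    )
    pairs = pd.DataFrame(
        {"pair_id": [f"pair{i:05d}" for i in range(n)],
         "at_gene": at_genes, "dt_gene": dt_genes}
    )
    truth = SyntheticTruth()
    truth.bias_truth = pd.DataFrame(
        {"pair_id": pairs["pair_id"], "tissue": params.bias_tissue, "label": labels}
    )
    return matrix, pairs, truth


# ---------------------------------------------------------------------------
# genetic map and multi-lineage VCF
# ---------------------------------------------------------------------------

def simulate_map_and_vcf(
    params: SimulationParams | None = None,
) -> tuple[pd.DataFrame, ScaffoldSet, DatasetManifest, str, SyntheticTruth]:
    """Chromosomes shredded into scaffolds, a marker table and a VCF.

    Markers carry 201 bp segments copied verbatim from known scaffold
    offsets; a fraction are mutated at 6 positions (unmatchable at the
    196/201 rule) and a fraction get an exact second copy planted in a dead
    zone of another chromosome (dropped by the uniqueness rule).  Shredded
    scaffolds are reverse-complemented with probability
    ``reverse_fraction``.  The VCF carries planted lineage-specific alleles
    (samples named after the manifest datasets).  Returns
    (markers, scaffolds, manifest, vcf_text, truth).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng([params.rng_seed, 404])
    manifest = default_manifest(params)
    seg_len, flank = 201, 100

    n_markers = params.n_chromosomes * params.markers_per_chromosome
    n_dup_total = round(params.duplicated_fraction * n_markers)
    dead_zone = 500 + 210 * max(1, n_dup_total)
    body = params.markers_per_chromosome * params.marker_spacing
    chrom_len = body + dead_zone
    piece = chrom_len // params.scaffolds_per_chromosome

    chrom_codes = [
        rng.integers(0, 4, size=chrom_len).astype(np.uint8)
        for _ in range(params.n_chromosomes)
    ]
    statuses = rng.random(n_markers)
    dup_cursor = [body + 250] * params.n_chromosomes

    marker_rows, truth_rows = [], []
    scaffold_bounds = []  # (chrom_idx, scaffold_id, start, end, reversed)
    for c in range(params.n_chromosomes):
        for k in range(params.scaffolds_per_chromosome):
            start = k * piece
            end = chrom_len if k == params.scaffolds_per_chromosome - 1 else (k + 1) * piece
            rev = bool(rng.random() < params.reverse_fraction)
            scaffold_bounds.append((c, f"c{c:02d}s{k:02d}", start, end, rev))

    bounds_by_chrom: dict[int, list] = {}
    for b in scaffold_bounds:
        bounds_by_chrom.setdefault(b[0], []).append(b)

    for c in range(params.n_chromosomes):
        seq = chrom_codes[c]
        for i in range(params.markers_per_chromosome):
            gidx = c * params.markers_per_chromosome + i
            p = i * params.marker_spacing + params.marker_spacing // 2
            # keep the whole segment inside one scaffold
            _, sid, s_start, s_end, rev = next(
                b for b in bounds_by_chrom[c] if b[2] <= p < b[3]
            )
            p = min(max(p, s_start + flank), s_end - flank - 1)
            seg_codes = seq[p - flank : p + flank + 1].copy()
            status = "clean"
            if statuses[gidx] < params.unmatchable_fraction:
                status = "unmatchable"
                bad_pos = rng.choice(seg_len, size=6, replace=False)
                seg_codes[bad_pos] = (seg_codes[bad_pos] + rng.integers(1, 4, size=6)) % 4
            elif statuses[gidx] < params.unmatchable_fraction + params.duplicated_fraction:
                status = "duplicated"
                other = (c + 1) % params.n_chromosomes
                at = dup_cursor[other]
                chrom_codes[other][at : at + seg_len] = seg_codes
                dup_cursor[other] = at + seg_len + 9
            marker_id = f"m{gidx:05d}"
            segment = _decode(seg_codes)
            cm = i * 0.5
            s0 = p - flank - s_start
            s_len = s_end - s_start
            exp_start = s_len - (s0 + seg_len) if rev else s0
            exp_strand = "-" if rev else "+"
            marker_rows.append((marker_id, f"chr{c + 1:02d}", cm, segment))
            truth_rows.append(
                (marker_id, f"chr{c + 1:02d}", i, cm, sid, exp_start, exp_strand, status)
            )

    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "chromosome", "cM", "segment"]
    )
    truth = SyntheticTruth()
    truth.marker_truth = pd.DataFrame(
        truth_rows,
        columns=["marker_id", "chromosome", "order", "cM", "scaffold_id",
                 "scaffold_pos", "strand", "status"],
    )

    scaffold_records = []
    origin_rows = []
    for c, sid, start, end, rev in scaffold_bounds:
        codes = chrom_codes[c][start:end]
        seq = _decode(codes)
        if rev:
            seq = reverse_complement(seq)
        scaffold_records.append(Scaffold(sid, end - start, seq))
        origin_rows.append((sid, f"chr{c + 1:02d}", start, end, "-" if rev else "+"))
    scaffolds = ScaffoldSet(scaffold_records)
    truth.scaffold_origin = pd.DataFrame(
        origin_rows, columns=["scaffold_id", "chromosome", "start", "end", "orientation"]
    )

    vcf_text = _simulate_vcf(params, scaffolds, manifest, truth, rng)
    return markers, scaffolds, manifest, vcf_text, truth


_ALT_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _simulate_vcf(
    params: SimulationParams,
    scaffolds: ScaffoldSet,
    manifest: DatasetManifest,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> str:
    sids = scaffolds.ids
    n_sites = params.n_lineage_sites + params.n_shared_sites
    used: set[tuple[str, int]] = set()
    sites: list[tuple[str, int, str]] = []  # (contig, pos0, lineage)
    kinds = (
        ["A"] * (params.n_lineage_sites // 2)
        + ["D"] * (params.n_lineage_sites - params.n_lineage_sites // 2)
        + ["shared"] * params.n_shared_sites
    )
    while len(sites) < n_sites:
        sid = sids[int(rng.integers(len(sids)))]
        pos0 = int(rng.integers(scaffolds[sid].length))
        if (sid, pos0) in used:
            continue
        used.add((sid, pos0))
        sites.append((sid, pos0, kinds[len(sites)]))
    sites.sort(key=lambda s: (s[0], s[1]))

    dataset_ids = manifest.dataset_ids
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for sid in sids:
        lines.append(f"##contig=<ID={sid},length={scaffolds[sid].length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset_ids)
    )
    dp = params.site_depth
    for contig, pos0, lineage in sites:
        ref = scaffolds[contig].sequence[pos0]
        alt = _ALT_OF.get(ref, "A")
        calls = []
        for did in dataset_ids:
            clade = manifest.clade_of(did)
            has_alt = lineage == "shared" or clade == lineage
            calls.append(f"{'1/1' if has_alt else '0/0'}:{dp}")
        lines.append(
            f"{contig}\t{pos0 + 1}\t.\t{ref}\t{alt}\t100\tPASS\t.\tGT:DP\t"
            + "\t".join(calls)
        )
    truth.lineage_snp_truth = pd.DataFrame(
        sites, columns=["contig", "pos0", "lineage"]
    )
    return "\n".join(lines) + "\n"


def write_vcf(vcf_text: str, path: str | Path) -> None:
    Path(path).write_text(vcf_text)
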