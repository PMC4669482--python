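"""Ground-truth recovery benchmarks on the bundled synthetic tetraploid.

Each function regenerates its inputs from the synthetic-data module under a
caller-supplied seed, runs the corresponding pipeline stage, and measures
recovery against the planted truth.  Where an independent oracle is called
for (the textbook two-sample t statistic, the brute-force all-positions
segment scan), it is implemented here from first principles rather than
routed through the pipeline's own code path.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .anchoring import anchor_scaffolds, encode, map_order, match_segments
from .assignment import assign, assign_scaffolds
from .config import PipelineConfig
from .expression import call_bias, kmeans_cluster, normalize_profiles
from .hybrids import call_all_hybrids, window_classify
from .io import reverse_complement
from .ltr import date_pairs, k2p_divergence
from .simulate import (
    SimulationParams, simulate_expression, simulate_ltr_pairs,
    simulate_map_and_vcf, simulate_tetraploid,
)
from .snps import partition_lineage_specific, read_vcf_presence


# ---------------------------------------------------------------------------
# subgenome assignment
# ---------------------------------------------------------------------------

def assignment_recovery(seed: int, noise_free: bool = False) -> dict:
    """Label accuracy on the standard 200-scaffold synthetic tetraploid
    (half At among grouped scaffolds, 10% ungrouped, 3 A + 3 D replicate
    tracks at 20x with negative-binomial noise of dispersion 10)."""
    params = SimulationParams(rng_seed=seed)
    if noise_free:
        params = params.replace(depth_noise="none")
    scaffolds, tracks, manifest, truth = simulate_tetraploid(params)
    result = assign(tracks, manifest, scaffolds)
    predicted = dict(zip(result["scaffold_id"], result["label"]))
    correct = sum(
        predicted[sid] == label for sid, label in truth.scaffold_subgenome.items()
    )
    return {"accuracy": correct / len(scaffolds), "n": len(scaffolds)}


def _student_t_closed_form(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample t and p from the textbook formulas."""
    na, nb = len(a), len(b)
    va = float(np.sum((a - a.mean()) ** 2)) / (na - 1)
    vb = float(np.sum((b - b.mean()) ** 2)) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def ttest_oracle_agreement(seed: int, n_cases: int = 100) -> dict:
    """Max |difference| between the pipeline's t/p and the closed form."""
    rng = np.random.default_rng(seed)
    from .assignment import CoverageSummary

    worst_t = worst_p = 0.0
    for _ in range(n_cases):
        a = rng.gamma(2.0, 1.0, size=int(rng.integers(2, 7)))
        b = rng.gamma(2.0, 1.0, size=int(rng.integers(2, 7)))
        summary = CoverageSummary(
            ["s"], [f"A{i}" for i in range(len(a))] + [f"D{i}" for i in range(len(b))],
            np.concatenate([a, b])[None, :], np.array([0.9]), np.array([0.9]),
            np.array([0.9]), ["A"] * len(a) + ["D"] * len(b),
        )
        row = assign_scaffolds(summary).iloc[0]
        t_exp, p_exp = _student_t_closed_form(a, b)
        worst_t = max(worst_t, abs(row["t_statistic"] - t_exp))
        worst_p = max(worst_p, abs(row["p_value"] - p_exp))
    return {"max_abs_t_diff": worst_t, "max_abs_p_diff": worst_p, "n": n_cases}


# ---------------------------------------------------------------------------
# hybrid scaffolds
# ---------------------------------------------------------------------------

def hybrid_detection(seed: int, window: int = 2_000) -> dict:
    """Junction recovery on 20 planted hybrids among 180 pure scaffolds,
    noise-free coverage, scanned at 2 kb windows."""
    params = SimulationParams(
        rng_seed=seed, n_scaffolds=200, n_hybrids=20, ungrouped_fraction=0.0,
        scaffold_length=(150_000, 160_000), depth_noise="none",
    )
    scaffolds, tracks, manifest, truth = simulate_tetraploid(params)
    config = PipelineConfig(hybrid_window=window)
    window_tracks = window_classify(tracks, manifest, scaffolds, config)
    calls = call_all_hybrids(window_tracks, config)
    true_pos = truth.junctions.set_index("scaffold_id")["position"]
    false_positives = int((~calls["scaffold_id"].isin(true_pos.index)).sum())
    within = 0
    found = set()
    for call in calls.itertuples():
        if call.scaffold_id not in true_pos.index:
            continue
        mid = (call.junction_start + call.junction_end) / 2.0
        if abs(mid - true_pos[call.scaffold_id]) <= window:
            within += 1
            found.add(call.scaffold_id)
    return {
        "n_true": len(true_pos),
        "recovered_within_one_window": len(found),
        "false_positives": false_positives,
        "extra_calls_on_hybrids": int(len(calls) - false_positives - within),
    }


# ---------------------------------------------------------------------------
# LTR dating
# ---------------------------------------------------------------------------

def ltr_age_recovery(seed: int) -> dict:
    """Mean estimated insertion age per planted age (1, 2, 3 Myr; 200 pairs
    of 1 kb LTRs per age at r = 1.3e-8, ts:tv 2)."""
    params = SimulationParams(rng_seed=seed)
    pairs, truth = simulate_ltr_pairs(params)
    ages = date_pairs(pairs, r=params.substitution_rate_r)
    ages["true_age"] = ages["element_id"].map(truth.ltr_ages)
    out: dict = {"n_per_age": params.ltr_pairs_per_age}
    for true_age, sub in ages.groupby("true_age"):
        myr = true_age / 1e6
        out[f"mean_age_{myr:.0f}myr_years"] = float(sub["T_years"].mean())
        out[f"rel_error_{myr:.0f}myr"] = float(
            abs(sub["T_years"].mean() - true_age) / true_age
        )
    return out


def k2p_worked_example() -> dict:
    """K for a constructed 100-site pair with 10 transitions, 5 transversions."""
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    res = k2p_divergence(a, b)
    return {"P": res.P, "Q": res.Q, "K": res.K, "n_sites": res.compared_sites}


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _brute_force_best_hits(markers: pd.DataFrame, scaffolds, max_mm: int = 5) -> pd.DataFrame:
    """All-positions Hamming scan oracle (both strands, best + uniqueness)."""
    rows = []
    encoded = [(sc.scaffold_id, encode(sc.sequence)) for sc in scaffolds]
    for rec in markers.itertuples():
        seg_f = encode(rec.segment)
        seg_r = encode(reverse_complement(rec.segment))
        L = len(seg_f)
        hits = []
        for sid, codes in encoded:
            if len(codes) < L:
                continue
            windows = sliding_window_view(codes, L)
            for strand, seg in (("+", seg_f), ("-", seg_r)):
                mm = ((windows != seg) | (windows >= 4) | (seg >= 4)).sum(axis=1)
                for pos in np.nonzero(mm <= max_mm)[0]:
                    hits.append((sid, int(pos), strand, L - int(mm[pos])))
        if not hits:
            continue
        best = max(h[3] for h in hits)
        best_hits = [h for h in hits if h[3] == best]
        for sid, pos, strand, matched in best_hits:
            rows.append((rec.marker_id, sid, pos, strand, matched, len(best_hits) == 1))
    return pd.DataFrame(
        rows, columns=["marker_id", "scaffold_id", "start", "strand", "matched", "unique"]
    )


def anchoring_recovery(seed: int, brute_force_markers: int = 20) -> dict:
    """Anchoring on 5 chromosomes / 1,000 markers / shredded scaffolds with
    planted 6-mismatch and duplicated markers, plus a brute-force cross-check
    of the matcher on a subset of markers over the ~1 Mb genome."""
    params = SimulationParams(rng_seed=seed)
    markers, scaffolds, _, _, truth = simulate_map_and_vcf(params)
    config = PipelineConfig()
    markers = map_order(markers)
    hits = match_segments(markers, scaffolds, config)
    anchored = anchor_scaffolds(hits, markers, config)

    marker_truth = truth.marker_truth.set_index("marker_id")
    bad_ids = set(marker_truth.index[marker_truth["status"] != "clean"])
    bad_unique = int(hits[hits["unique"] & hits["marker_id"].isin(bad_ids)].shape[0])

    # scaffolds carrying >= 5 clean markers consecutive in map order must anchor
    clean = marker_truth[marker_truth["status"] == "clean"].reset_index()
    must_anchor: set[str] = set()
    for _, sub in clean.groupby("chromosome"):
        sub = sub.sort_values("order")
        run, prev = 0, (None, None)
        for row in sub.itertuples():
            run = run + 1 if (row.scaffold_id, row.order - 1) == prev else 1
            prev = (row.scaffold_id, row.order)
            if run >= config.min_continuous_segments:
                must_anchor.add(row.scaffold_id)

    origin = truth.scaffold_origin.set_index("scaffold_id")
    merged = anchored.join(origin, on="scaffold_id", rsuffix="_true")
    correct_chrom = int((merged["chromosome"] == merged["chromosome_true"]).sum())
    anchored_ids = set(anchored["scaffold_id"])
    must_anchored_correct = all(
        sid in anchored_ids
        and merged.set_index("scaffold_id").loc[sid, "chromosome"]
        == origin.loc[sid, "chromosome"]
        for sid in must_anchor
    )

    chrom_rank = {c: i for i, c in enumerate(sorted(origin["chromosome"].unique()))}
    true_key = [
        chrom_rank[row.chromosome_true] * 10**9 + row.start
        for row in merged.itertuples()
    ]
    recovered_key = [
        chrom_rank[row.chromosome] * 10**9 + row.position
        for row in merged.itertuples()
    ]
    tau = float(stats.kendalltau(true_key, recovered_key).statistic)

    subset = markers.iloc[:: max(1, len(markers) // brute_force_markers)]
    brute = _brute_force_best_hits(subset, scaffolds, config.max_mismatches)
    fast_subset = hits[hits["marker_id"].isin(subset["marker_id"])]
    key = ["marker_id", "scaffold_id", "start", "strand"]
    brute_sorted = brute.sort_values(key).reset_index(drop=True)
    fast_sorted = fast_subset.sort_values(key).reset_index(drop=True)
    matcher_agrees = brute_sorted.equals(
        fast_sorted[brute_sorted.columns].astype(brute_sorted.dtypes.to_dict())
    )
    return {
        "n_markers": len(markers),
        "n_scaffolds": len(scaffolds),
        "genome_bp": scaffolds.total_length,
        "n_anchored": len(anchored),
        "correct_chromosome_fraction": correct_chrom / max(1, len(anchored)),
        "all_qualifying_scaffolds_anchored": bool(must_anchored_correct),
        "kendall_tau": tau,
        "bad_markers_with_unique_hits": bad_unique,
        "matcher_equals_brute_force": bool(matcher_agrees),
        "n_brute_force_markers": len(subset),
    }


# ---------------------------------------------------------------------------
# expression bias
# ---------------------------------------------------------------------------

def bias_recovery(seed: int) -> dict:
    """Recovered bias fractions and per-pair accuracy on 1,000 synthetic
    pairs with 30% At- and 20% Dt-biased planted at a 4x effect."""
    params = SimulationParams(rng_seed=seed)
    matrix, pairs, truth = simulate_expression(params)
    calls = call_bias(pairs, matrix, params.bias_tissue)
    merged = calls.merge(truth.bias_truth, on="pair_id")
    accuracy = float((merged["bias"] == merged["label"]).mean())

    profiles, _ = normalize_profiles(matrix)
    a = kmeans_cluster(profiles, k=8, seed=seed)
    b = kmeans_cluster(profiles, k=8, seed=seed)
    return {
        "n_pairs": len(pairs),
        "recovered_at_fraction": float((calls["bias"] == "At-biased").mean()),
        "recovered_dt_fraction": float((calls["bias"] == "Dt-biased").mean()),
        "planted_at_fraction": params.at_bias_fraction,
        "planted_dt_fraction": params.dt_bias_fraction,
        "accuracy": accuracy,
        "kmeans_deterministic": bool(a.equals(b)),
    }


# ---------------------------------------------------------------------------
# lineage-specific SNPs
# ---------------------------------------------------------------------------

def lineage_snp_recovery(seed: int) -> dict:
    """Precision/recall on a synthetic VCF with 1,000 planted lineage-specific
    sites and 1,000 shared sites, noise-free."""
    params = SimulationParams(rng_seed=seed)
    _, _, manifest, vcf_text, truth = simulate_map_and_vcf(params)
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "sites.vcf"
        path.write_text(vcf_text)
        presence = read_vcf_presence(path, manifest)
    predicted = partition_lineage_specific(presence, manifest)

    pred = set(map(tuple, predicted[["contig", "pos0", "lineage"]].itertuples(index=False)))
    planted = truth.lineage_snp_truth
    true = set(
        map(tuple, planted.loc[planted["lineage"] != "shared",
                               ["contig", "pos0", "lineage"]].itertuples(index=False))
    )
    tp = len(pred & true)
    disjoint = not predicted.duplicated(subset=["contig", "pos0"]).any()
    return {
        "n_planted_specific": len(true),
        "n_predicted": len(pred),
        "precision": tp / len(pred) if pred else float("nan"),
        "recall": tp / len(true) if true else float("nan"),
        "sets_disjoint": bool(disjoint),
    }


# ---------------------------------------------------------------------------
# density-scan null calibration
# ---------------------------------------------------------------------------

def density_null_calibration(
    seed: int, n_replicates: int = 100, n_sites: int = 10_000,
    genome_bp: int = 100_000_000, window: int = 1_000_000, z: float = 2.0,
) -> dict:
    """Low-flag rate of the density scan on uniform sites, averaged over
    seeded replicates, against the one-tailed normal expectation at z."""
    from .snps import density_scan

    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_replicates):
        pos = rng.integers(0, genome_bp, size=n_sites)
        sites = pd.DataFrame({"contig": "c", "pos0": pos})
        out = density_scan(sites, {"c": genome_bp}, window=window, z_threshold=z)
        rates.append(float((out["flag"] == "low").mean()))
    return {
        "mean_low_flag_rate": float(np.mean(rates)),
        "expected_one_tailed_rate": float(stats.norm.sf(z)),
        "n_replicates": n_replicates,
        "n_windows_per_replicate": genome_bp // window,
    }
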