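"""Segment extraction, the 196/201 unique matcher, run anchoring, chromosome build."""

import numpy as np
import pandas as pd
import pytest

from allotetra.anchoring import (
    anchor_scaffolds, build_pseudochromosomes, encode, extract_segments,
    map_order, match_segments, mismatch_count,
)
from allotetra.config import PipelineConfig
from allotetra.io import Scaffold, ScaffoldSet, reverse_complement

CFG = PipelineConfig()


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, seg, n_mut):
    seg = list(seg)
    for i in rng.choice(len(seg), size=n_mut, replace=False):
        seg[i] = rng.choice([b for b in "ACGT" if b != seg[i]])
    return "".join(seg)


def marker_frame(segments):
    return pd.DataFrame(
        {"marker_id": [f"m{i}" for i in range(len(segments))],
         "chromosome": "chr1", "cM": np.arange(len(segments), dtype=float),
         "segment": segments}
    )


def brute_force_hits(markers, scaffolds, max_mm=5):
    """All-positions Hamming scan on both strands; best-placement + uniqueness rule."""
    from numpy.lib.stride_tricks import sliding_window_view

    rows = []
    for rec in markers.itertuples():
        seg_f = encode(rec.segment)
        seg_r = encode(reverse_complement(rec.segment))
        L = len(seg_f)
        hits = []
        for sc in scaffolds:
            codes = encode(sc.sequence)
            if sc.length < L:
                continue
            windows = sliding_window_view(codes, L)
            for strand, seg in (("+", seg_f), ("-", seg_r)):
                mm = ((windows != seg) | (windows >= 4) | (seg >= 4)).sum(axis=1)
                for pos in np.nonzero(mm <= max_mm)[0]:
                    hits.append((sc.scaffold_id, int(pos), strand, L - int(mm[pos])))
        if not hits:
            continue
        best = max(h[3] for h in hits)
        best_hits = [h for h in hits if h[3] == best]
        for sid, pos, strand, matched in best_hits:
            rows.append((rec.marker_id, sid, pos, strand, matched, len(best_hits) == 1))
    return pd.DataFrame(
        rows, columns=["marker_id", "scaffold_id", "start", "strand", "matched", "unique"]
    )


class TestExtractSegments:
    REF = None

    @pytest.fixture(autouse=True)
    def _ref(self, rng):
        self.seq = random_seq(rng, 300)
        self.ref = ScaffoldSet([Scaffold("s1", 300, self.seq)])

    def snp_table(self, pos):
        return pd.DataFrame({"marker_id": ["m1"], "chromosome": ["chr1"],
                             "cM": [0.0], "contig": ["s1"], "pos": [pos]})

    def test_interior_snp_gives_201bp_segment(self):
        out = extract_segments(self.snp_table(150), self.ref, CFG)
        assert len(out) == 1
        assert out.loc[0, "segment"] == self.seq[49:250]  # 1-based bases 50..250

    def test_snp_too_close_to_end_skipped(self):
        out = extract_segments(self.snp_table(50), self.ref, CFG)
        assert out.empty

    def test_boundary_snp_at_101(self):
        out = extract_segments(self.snp_table(101), self.ref, CFG)
        assert out.loc[0, "segment"] == self.seq[0:201]

    def test_missing_reference_rejected(self):
        tab = self.snp_table(150)
        tab["contig"] = "nope"
        with pytest.raises(ValueError, match="absent"):
            extract_segments(tab, self.ref, CFG)


class TestMatchSegments:
    @pytest.fixture(autouse=True)
    def _genome(self, rng):
        self.rng = rng
        seq = random_seq(rng, 5000)
        self.scaffolds = ScaffoldSet([Scaffold("s1", 5000, seq)])
        self.seq = seq

    def test_verbatim_planted_segment_found(self):
        seg = self.seq[1000:1201]
        hits = match_segments(marker_frame([seg]), self.scaffolds, CFG)
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row["scaffold_id"], row["start"], row["strand"], row["matched"],
                row["unique"]) == ("s1", 1000, "+", 201, True)

    def test_reverse_strand_hit(self):
        seg = reverse_complement(self.seq[1000:1201])
        hits = match_segments(marker_frame([seg]), self.scaffolds, CFG)
        assert hits.iloc[0].strand == "-" and hits.iloc[0].start == 1000

    def test_five_mismatches_tolerated_six_rejected(self):
        seg = self.seq[2000:2201]
        hits5 = match_segments(marker_frame([mutate(self.rng, seg, 5)]),
                               self.scaffolds, CFG)
        hits6 = match_segments(marker_frame([mutate(self.rng, seg, 6)]),
                               self.scaffolds, CFG)
        assert len(hits5) == 1 and hits5.iloc[0].matched == 196
        assert hits6.empty

    def test_duplicated_segment_not_unique(self):
        seg = self.seq[100:301]
        dup_seq = self.seq[:3000] + seg + self.seq[3201:]
        scaffolds = ScaffoldSet([Scaffold("s1", 5000, dup_seq)])
        hits = match_segments(marker_frame([seg]), scaffolds, CFG)
        assert len(hits) == 2 and not hits["unique"].any()

    def test_equals_brute_force_scan(self, rng):
        # mixed clean / mutated / duplicated / absent markers on a small genome
        seqs = [random_seq(rng, 4000) for _ in range(2)]
        seg0 = seqs[0][500:701]
        seqs[1] = seqs[1][:2000] + seg0 + seqs[1][2201:]  # duplicate of seg0
        scaffolds = ScaffoldSet(
            [Scaffold(f"s{i}", len(s), s) for i, s in enumerate(seqs)]
        )
        segments = [
            seg0,                                   # duplicated -> tie
            seqs[0][1000:1201],                     # clean
            mutate(rng, seqs[0][1500:1701], 3),     # within budget
            mutate(rng, seqs[1][300:501], 6),       # over budget -> absent
            random_seq(rng, 201),                   # random -> absent
        ]
        markers = marker_frame(segments)
        fast = match_segments(markers, scaffolds, CFG)
        brute = brute_force_hits(markers, scaffolds)
        key = ["marker_id", "scaffold_id", "start", "strand"]
        pd.testing.assert_frame_equal(
            fast.sort_values(key).reset_index(drop=True),
            brute.sort_values(key).reset_index(drop=True),
        )

    def test_wrong_segment_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            match_segments(marker_frame(["ACGT"]), self.scaffolds, CFG)


def hits_frame(rows):
    return pd.DataFrame(
        rows, columns=["marker_id", "scaffold_id", "start", "strand", "matched", "unique"]
    )


def chr_markers(n, chrom="chr1"):
    return pd.DataFrame(
        {"marker_id": [f"{chrom}_m{i}" for i in range(n)], "chromosome": chrom,
         "cM": np.arange(n) * 0.5, "segment": ["N"] * n}
    )


class TestAnchorScaffolds:
    def test_five_consecutive_markers_anchor(self):
        markers = map_order(chr_markers(20))
        rows = [(f"chr1_m{i}", "sc1", 1000 * i, "+", 201, True) for i in range(10, 15)]
        out = anchor_scaffolds(hits_frame(rows), markers, CFG)
        assert out.iloc[0].scaffold_id == "sc1"
        assert out.iloc[0].chromosome == "chr1"
        assert out.iloc[0].orientation == "+"
        assert out.iloc[0].n_markers == 5

    def test_broken_run_not_anchored(self):
        # map-order hits 10,11,12,14,15: longest run is 3
        markers = map_order(chr_markers(20))
        rows = [(f"chr1_m{i}", "sc1", 1000 * i, "+", 201, True)
                for i in (10, 11, 12, 14, 15)]
        assert anchor_scaffolds(hits_frame(rows), markers, CFG).empty

    def test_gap_tolerance_configurable(self):
        markers = map_order(chr_markers(20))
        rows = [(f"chr1_m{i}", "sc1", 1000 * i, "+", 201, True)
                for i in (10, 11, 12, 14, 15)]
        out = anchor_scaffolds(hits_frame(rows), markers, CFG.replace(max_run_gap=1))
        assert len(out) == 1 and out.iloc[0].n_markers == 5

    def test_reverse_orientation_from_decreasing_coordinates(self):
        markers = map_order(chr_markers(20))
        rows = [(f"chr1_m{i}", "sc1", 1000 * (20 - i), "+", 201, True)
                for i in range(5, 11)]
        out = anchor_scaffolds(hits_frame(rows), markers, CFG)
        assert out.iloc[0].orientation == "-"

    def test_two_chromosome_conflict_rejected(self):
        markers = map_order(pd.concat([chr_markers(10, "chr1"),
                                       chr_markers(10, "chr2")], ignore_index=True))
        rows = [(f"chr1_m{i}", "sc1", 1000 * i, "+", 201, True) for i in range(5)]
        rows += [(f"chr2_m{i}", "sc1", 9000 + 1000 * i, "+", 201, True) for i in range(5)]
        assert anchor_scaffolds(hits_frame(rows), markers, CFG).empty

    def test_non_unique_hits_ignored(self):
        markers = map_order(chr_markers(20))
        rows = [(f"chr1_m{i}", "sc1", 1000 * i, "+", 201, False) for i in range(10, 15)]
        assert anchor_scaffolds(hits_frame(rows), markers, CFG).empty

    def test_ordering_by_median_cm(self):
        markers = map_order(chr_markers(30))
        rows = [(f"chr1_m{i}", "late", 100 * i, "+", 201, True) for i in range(20, 26)]
        rows += [(f"chr1_m{i}", "early", 100 * i, "+", 201, True) for i in range(0, 6)]
        out = anchor_scaffolds(hits_frame(rows), markers, CFG)
        assert out.sort_values("position")["scaffold_id"].tolist() == ["early", "late"]


class TestBuildPseudochromosomes:
    def test_concatenation_with_gap(self):
        scaffolds = ScaffoldSet([Scaffold("a", 100, "A" * 100),
                                 Scaffold("b", 100, "C" * 100)])
        anchored = pd.DataFrame(
            {"scaffold_id": ["a", "b"], "chromosome": "chr1", "position": [0, 1],
             "median_cM": [1.0, 2.0], "orientation": ["+", "+"],
             "n_markers": 5, "span_cM": 2.0}
        )
        chroms, layout = build_pseudochromosomes(anchored, scaffolds, gap_size=100)
        assert chroms["chr1"].length == 300
        assert chroms["chr1"].sequence[100:200] == "N" * 100
        assert layout["end"].tolist() == [100, 300]

    def test_reverse_complement_placement(self):
        scaffolds = ScaffoldSet([Scaffold("a", 4, "AAAC")])
        anchored = pd.DataFrame(
            {"scaffold_id": ["a"], "chromosome": "chr1", "position": [0],
             "median_cM": [1.0], "orientation": ["-"], "n_markers": 5, "span_cM": 0.0}
        )
        chroms, _ = build_pseudochromosomes(anchored, scaffolds)
        assert chroms["chr1"].sequence == "GTTT"

    def test_empty_input(self):
        chroms, layout = build_pseudochromosomes(
            pd.DataFrame(columns=["scaffold_id", "chromosome", "position",
                                  "median_cM", "orientation", "n_markers", "span_cM"]),
            ScaffoldSet([]),
        )
        assert len(chroms) == 0 and layout.empty

    def test_duplicate_placement_rejected(self):
        scaffolds = ScaffoldSet([Scaffold("a", 4, "AAAC")])
        anchored = pd.DataFrame(
            {"scaffold_id": ["a", "a"], "chromosome": ["chr1", "chr2"],
             "position": [0, 0], "median_cM": [1.0, 1.0], "orientation": ["+", "+"],
             "n_markers": 5, "span_cM": 0.0}
        )
        with pytest.raises(ValueError, match="placed more than once"):
            build_pseudochromosomes(anchored, scaffolds)


class TestMismatchCount:
    def test_n_counts_as_mismatch(self):
        assert mismatch_count(encode("ACGT"), encode("ACGN")) == 1
        assert mismatch_count(encode("NNNN"), encode("NNNN")) == 4
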