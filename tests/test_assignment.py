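"""Subgenome assignment: the three criteria, oracle equivalence, symmetries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allotetra.assignment import (
    CoverageSummary, assign, assign_scaffolds, assignment_report, n50,
    summarize_coverage,
)
from allotetra.config import PipelineConfig
from allotetra.io import (
    CoverageTrack, Dataset, DatasetManifest, Scaffold, ScaffoldSet,
)
from allotetra.simulate import SimulationParams, simulate_tetraploid


def student_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (independent of the pipeline)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = np.sum((a - a.mean()) ** 2) / (na - 1)
    vb = np.sum((b - b.mean()) ** 2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def make_summary(a_values, d_values, frac_union):
    """Build a single-scaffold CoverageSummary directly from clade depth values."""
    a_values, d_values = list(a_values), list(d_values)
    return CoverageSummary(
        scaffold_ids=["s"],
        dataset_ids=[f"A{i}" for i in range(len(a_values))]
        + [f"D{i}" for i in range(len(d_values))],
        depths=np.array([a_values + d_values]),
        frac_A=np.array([frac_union]),
        frac_D=np.array([frac_union]),
        frac_union=np.array([frac_union]),
        clades=["A"] * len(a_values) + ["D"] * len(d_values),
    )


class TestSummarizeCoverage:
    @pytest.fixture
    def setting(self):
        scaffolds = ScaffoldSet([Scaffold("s1", 100), Scaffold("s2", 100),
                                 Scaffold("s9", 50)])
        manifest = DatasetManifest(
            [Dataset("a1", "A"), Dataset("a2", "A"), Dataset("d1", "D")]
        )
        return scaffolds, manifest

    def test_library_size_normalization(self, setting):
        scaffolds, manifest = setting
        # a1: s1 at 20x, s2 uncovered -> genome mean (20*100)/250 = 8
        a1 = CoverageTrack("a1", {"s1": np.array([[0, 100, 20.0]])})
        a2 = CoverageTrack("a2", {"s1": np.array([[0, 100, 20.0]])})
        d1 = CoverageTrack("d1", {"s2": np.array([[0, 100, 10.0]])})
        summary = summarize_coverage([a1, a2, d1], manifest, scaffolds)
        df = summary.to_frame().set_index("scaffold_id")
        assert df.loc["s1", "a1"] == pytest.approx(20.0 / 8.0)
        assert df.loc["s1", "covered_fraction_A"] == pytest.approx(1.0)

    def test_absent_scaffold_gets_zeros(self, setting):
        scaffolds, manifest = setting
        tracks = [CoverageTrack("a1", {"s1": np.array([[0, 100, 5.0]])}),
                  CoverageTrack("a2"), CoverageTrack("d1")]
        summary = summarize_coverage(tracks, manifest, scaffolds)
        df = summary.to_frame().set_index("scaffold_id")
        assert df.loc["s9"].drop("covered_fraction_A").sum() == 0

    def test_union_rule_over_clade_tracks(self, setting):
        scaffolds, manifest = setting
        a1 = CoverageTrack("a1", {"s1": np.array([[0, 50, 2.0]])})
        a2 = CoverageTrack("a2", {"s1": np.array([[50, 100, 2.0]])})
        d1 = CoverageTrack("d1")
        summary = summarize_coverage([a1, a2, d1], manifest, scaffolds)
        assert summary.frac_A[summary.scaffold_ids.index("s1")] == pytest.approx(1.0)

    def test_missing_clade_rejected(self, setting):
        scaffolds, manifest = setting
        with pytest.raises(ValueError, match="D-clade"):
            summarize_coverage([CoverageTrack("a1")], manifest, scaffolds)


class TestAssignCriteria:
    def test_all_zero_coverage_is_ungrouped(self):
        res = assign_scaffolds(make_summary([0, 0], [0, 0], 0.0))
        assert res.loc[0, "label"] == "ungrouped"
        assert not res.loc[0, "criterion_coverage"]

    def test_clear_at_case_matches_oracle(self):
        a, d = (2.1, 1.9, 2.0), (0.10, 0.12, 0.08)
        res = assign_scaffolds(make_summary(a, d, 0.95))
        t_exp, p_exp = student_t_oracle(a, d)
        assert res.loc[0, "label"] == "At"
        assert res.loc[0, "log2_ratio"] == pytest.approx(
            math.log2((2.0 + 0.01) / (0.1 + 0.01)), abs=1e-12
        )
        assert res.loc[0, "t_statistic"] == pytest.approx(t_exp, abs=1e-10)
        assert res.loc[0, "p_value"] == pytest.approx(p_exp, abs=1e-10)

    def test_ratio_criterion_failure_is_ungrouped(self):
        res = assign_scaffolds(make_summary([1.0, 1.0], [0.9, 1.1], 0.95))
        assert res.loc[0, "label"] == "ungrouped"
        assert not res.loc[0, "criterion_ratio"]

    def test_dt_mirror_direction(self):
        res = assign_scaffolds(make_summary([0.1, 0.12, 0.08], [2.1, 1.9, 2.0], 0.95))
        assert res.loc[0, "label"] == "Dt"
        assert res.loc[0, "log2_ratio"] < -2

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            assign_scaffolds(make_summary([2.0], [0.1], 0.95))

    def test_oracle_equivalence_random_cases(self, rng):
        for _ in range(100):
            a = rng.gamma(2.0, 1.0, size=rng.integers(2, 6))
            b = rng.gamma(2.0, 1.0, size=rng.integers(2, 6))
            res = assign_scaffolds(make_summary(a, b, 0.9))
            t_exp, p_exp = student_t_oracle(a, b)
            assert res.loc[0, "t_statistic"] == pytest.approx(t_exp, abs=1e-10)
            assert res.loc[0, "p_value"] == pytest.approx(p_exp, abs=1e-10)


@pytest.fixture(scope="module")
def sim():
    return simulate_tetraploid(SimulationParams(rng_seed=11, n_scaffolds=60))


class TestProperties:

    def test_partition_every_scaffold_once(self, sim):
        scaffolds, tracks, manifest, _ = sim
        res = assign(tracks, manifest, scaffolds)
        assert len(res) == len(scaffolds)
        assert res["scaffold_id"].is_unique
        assert set(res["label"]) <= {"At", "Dt", "ungrouped"}
        report = assignment_report(res, scaffolds)
        per_label = report[report["label"] != "total"]
        assert per_label["total_length"].sum() == scaffolds.total_length
        assert per_label["n_scaffolds"].sum() == len(scaffolds)

    def test_swap_symmetry(self, sim):
        scaffolds, tracks, manifest, _ = sim
        res = assign(tracks, manifest, scaffolds)
        swapped = DatasetManifest(
            [Dataset(d.dataset_id, {"A": "D", "D": "A"}.get(d.clade, d.clade),
                     d.line_label) for d in manifest.datasets]
        )
        res_sw = assign(tracks, swapped, scaffolds)
        flip = {"At": "Dt", "Dt": "At", "ungrouped": "ungrouped"}
        assert res_sw["label"].tolist() == [flip[l] for l in res["label"]]
        np.testing.assert_allclose(res_sw["log2_ratio"], -res["log2_ratio"], atol=1e-9)

    def test_scaling_a_up_never_flips_at_to_dt(self, sim, rng):
        scaffolds, tracks, manifest, _ = sim
        summary = summarize_coverage(tracks, manifest, scaffolds,
                                     PipelineConfig(normalize_depths=False))
        before = assign_scaffolds(summary)
        boosted = CoverageSummary(
            summary.scaffold_ids, summary.dataset_ids,
            summary.depths * np.where(np.array(summary.clades) == "A", 3.0, 1.0),
            summary.frac_A, summary.frac_D, summary.frac_union, summary.clades,
        )
        after = assign_scaffolds(boosted)
        became_dt = (before["label"] == "At") & (after["label"] == "Dt")
        assert not became_dt.any()


class TestReport:
    def test_bookkeeping(self):
        scaffolds = ScaffoldSet([Scaffold("a", 10), Scaffold("b", 20), Scaffold("c", 30)])
        res = pd.DataFrame({"scaffold_id": ["a", "b", "c"],
                            "label": ["At", "Dt", "ungrouped"]})
        rep = assignment_report(res, scaffolds).set_index("label")
        assert rep.loc["At", "total_length"] == 10
        assert rep.loc["total", "total_length"] == 60

    def test_empty_input(self):
        rep = assignment_report(
            pd.DataFrame({"scaffold_id": [], "label": []}), ScaffoldSet([])
        )
        assert (rep[["n_scaffolds", "total_length", "n50"]].to_numpy() == 0).all()

    @pytest.mark.parametrize(
        "lengths,expected", [([8, 2], 8), ([5, 5, 5, 5], 5), ([1, 1, 1, 7], 7), ([], 0)]
    )
    def test_n50_against_enumeration(self, lengths, expected):
        assert n50(lengths) == expected
        if lengths:
            # brute-force definition: largest length whose descending prefix
            # (all pieces at least that long) reaches half the total
            total = sum(lengths)
            brute = 0
            for cand in sorted(set(lengths), reverse=True):
                if sum(l for l in lengths if l >= cand) >= total / 2:
                    brute = cand
                    break
            assert n50(lengths) == brute
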