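"""Duo consensus, robust-trio selection cascade, sensitivity scenarios."""

import pandas as pd
import pytest

from olivepedigree import intersect_duos, select_robust_trios
from olivepedigree.pipeline import (
    run_pipeline,
    run_sensitivity,
    validation_map_from_truth,
)
from olivepedigree.config import PipelineConfig, CalibrationSettings
from olivepedigree.trios import duo_counts


DUO_COLS = ["id_a", "id_b", "n_compared", "n_opposite_hom", "n_mismatch",
            "phi", "lod", "method", "passes"]


def duo_table(pairs, method, passes=True):
    rows = [
        {
            "id_a": a, "id_b": b, "n_compared": 96, "n_opposite_hom": 0,
            "n_mismatch": 0, "phi": 0.25, "lod": 10.0, "method": method,
            "passes": passes,
        }
        for a, b in pairs
    ]
    return pd.DataFrame(rows, columns=DUO_COLS)


def trio_rows(entries):
    """entries: (offspring, pa, pb, lod_pp, n_mismatch, passes)"""
    return pd.DataFrame(
        [
            {
                "offspring": o, "parent_a": a, "parent_b": b, "lod_pp": lod,
                "n_compared": 96, "n_mismatch": mm, "passes": ok,
                "confidence": "strict" if ok else "none",
            }
            for o, a, b, lod, mm, ok in entries
        ]
    )


class TestConsensus:
    def test_intersection_and_audit(self):
        k = duo_table([("a", "b"), ("a", "c")], "kinship")
        l = duo_table([("b", "a"), ("b", "d")], "likelihood")
        audit = intersect_duos(k, l)
        byp = audit.set_index(["id_a", "id_b"])
        # pair in both (order-normalized) -> consensus with both flags
        assert byp.loc[("a", "b"), "consensus"]
        assert byp.loc[("a", "b"), "kinship_pass"]
        assert byp.loc[("a", "b"), "likelihood_pass"]
        # one-method pairs kept in audit but not consensus
        assert not byp.loc[("a", "c"), "consensus"]
        assert not byp.loc[("b", "d"), "consensus"]
        assert len(audit) == 3

    def test_consensus_never_exceeds_either_method(self, small_dataset):
        from olivepedigree import sambar_duo_search, cervus_duo_search
        from olivepedigree.likelihood import ThresholdSet

        g = small_dataset.genotypes
        kin = sambar_duo_search(g)
        ts = ThresholdSet(5.0, 15.0, CalibrationSettings(), seed=0)
        lik = cervus_duo_search(g, g.allele_frequencies(), ts)
        audit = intersect_duos(kin, lik)
        n = int(audit["consensus"].sum())
        assert n <= int(kin["passes"].sum())
        assert n <= int(lik["passes"].sum())

    def test_duo_counts_ranking(self):
        k = duo_table([("hub", "x"), ("hub", "y"), ("x", "y")], "kinship")
        l = duo_table([("hub", "x"), ("hub", "y"), ("x", "y")], "likelihood")
        counts = duo_counts(intersect_duos(k, l))
        assert counts["hub"] == 2


class TestRobustSelection:
    def _audit(self, pairs):
        return intersect_duos(
            duo_table(pairs, "kinship"), duo_table(pairs, "likelihood")
        )

    def test_overloaded_offspring_gets_no_trio(self):
        entries = [
            ("kid", f"p{i}", f"q{i}", 20.0 + i, 0, True) for i in range(25)
        ]
        sel = select_robust_trios(trio_rows(entries), self._audit([]))
        assert sel.trios.empty
        assert sel.excluded.iloc[0]["reason"] == "acts_as_parent"
        assert sel.excluded.iloc[0]["n_supported_pairs"] == 25

    def test_tie_broken_by_fewest_mismatches(self):
        entries = [
            ("kid", "a", "b", 30.0, 1, True),
            ("kid", "c", "d", 30.0, 0, True),
        ]
        sel = select_robust_trios(trio_rows(entries), self._audit([]))
        row = sel.trios.iloc[0]
        assert {row["parent_a"], row["parent_b"]} == {"c", "d"}
        assert "i:fewest_mismatches" in row["selection_trace"]

    def test_tie_broken_by_duo_support(self):
        entries = [
            ("kid", "a", "b", 30.0, 0, True),
            ("kid", "c", "d", 30.0, 0, True),
        ]
        sel = select_robust_trios(
            trio_rows(entries), self._audit([("kid", "c"), ("kid", "d")])
        )
        row = sel.trios.iloc[0]
        assert {row["parent_a"], row["parent_b"]} == {"c", "d"}
        assert "ii:duo_supported_parents" in row["selection_trace"]

    def test_tie_broken_by_region_then_lexicographic(self):
        entries = [
            ("kid", "a", "b", 30.0, 0, True),
            ("kid", "c", "d", 30.0, 0, True),
        ]
        meta = pd.DataFrame({
            "id": ["kid", "a", "b", "c", "d"],
            "region": ["WM", "WM", "WM", "EM", "EM"],
        })
        sel = select_robust_trios(trio_rows(entries), self._audit([]), meta)
        row = sel.trios.iloc[0]
        assert {row["parent_a"], row["parent_b"]} == {"a", "b"}
        assert "iii:region_consistency" in row["selection_trace"]

        # without metadata the region rule is skipped; lexicographic decides
        sel2 = select_robust_trios(trio_rows(entries), self._audit([]))
        row2 = sel2.trios.iloc[0]
        assert {row2["parent_a"], row2["parent_b"]} == {"a", "b"}
        assert "lexicographic" in row2["selection_trace"]

    def test_direct_conflict_resolved_by_lod(self):
        # X offspring of (A, B) while X parent of A: keep the higher LOD_pp
        entries = [
            ("X", "A", "B", 20.0, 0, True),
            ("A", "X", "C", 35.0, 0, True),
        ]
        sel = select_robust_trios(trio_rows(entries), self._audit([]))
        assert list(sel.trios["offspring"]) == ["A"]
        assert sel.conflicts.iloc[0]["kind"] == "direct"
        assert (sel.excluded["reason"] == "cross_trio_conflict").any()

    def test_determinism(self):
        entries = [
            ("kid", "a", "b", 30.0, 0, True),
            ("kid", "c", "d", 30.0, 0, True),
            ("kid2", "a", "d", 25.0, 1, True),
        ]
        a = select_robust_trios(trio_rows(entries), self._audit([]))
        b = select_robust_trios(trio_rows(entries), self._audit([]))
        pd.testing.assert_frame_equal(a.trios, b.trios)

    def test_one_trio_per_offspring_and_mismatch_cap(self, small_dataset):
        cfg = PipelineConfig(calibration=CalibrationSettings(
            n_offspring=1500, n_candidate_parents=60, seed=5))
        res = run_pipeline(
            cfg, g=small_dataset.genotypes, metadata=small_dataset.metadata,
            truth=small_dataset.truth, write=False,
        )
        trios = res.selection.trios
        assert trios["offspring"].is_unique
        assert (trios["n_mismatch"] <= cfg.max_mismatch).all()
        assert (trios["n_duo_supported"] >= 0).all()


@pytest.fixture(scope="module")
def state(small_dataset):
    cfg = PipelineConfig(calibration=CalibrationSettings(
        n_offspring=1500, n_candidate_parents=60, seed=5))
    res = run_pipeline(
        cfg, g=small_dataset.genotypes, metadata=small_dataset.metadata,
        truth=small_dataset.truth, write=False,
    )
    vmap = validation_map_from_truth(small_dataset.truth)
    report = run_sensitivity(cfg, res, vmap, write=False)
    return small_dataset, res, vmap, report


class TestSensitivity:
    def test_baseline_recovers_true_pairs(self, state):
        ds, _, vmap, report = state
        s1 = report[report["scenario"] == 1]
        assert s1["matches_truth"].mean() >= 0.8

    def test_scenario3_collapses(self, state):
        _, _, _, report = state
        s3 = report[report["scenario"] == 3]
        assert (s3["status"] == "collapsed").all()

    def test_scenario2_collapses_or_weakens(self, state):
        _, _, _, report = state
        s1 = report[report["scenario"] == 1].set_index("offspring")
        s2 = report[report["scenario"] == 2].set_index("offspring")
        for o in s2.index:
            if s2.loc[o, "status"] == "trio" and s1.loc[o, "status"] == "trio":
                assert s2.loc[o, "lod_pp"] < s1.loc[o, "lod_pp"]

    def test_unknown_validation_id_skipped(self, state):
        ds, res, _, _ = state
        cfg = PipelineConfig(calibration=CalibrationSettings(
            n_offspring=1500, n_candidate_parents=60, seed=5))
        report = run_sensitivity(
            cfg, res, {"GHOST": ("F0001", "F0002")}, write=False
        )
        assert (report["status"] == "skipped").all()
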