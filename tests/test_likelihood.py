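"""LOD likelihood engine: transition probabilities, scores, calibration.

The brute-force oracle used here enumerates transmitted alleles explicitly
(and, for the single-parent case, the population draw of the untransmitted
allele) and never touches the vectorized table machinery it checks.
"""

import math

import numpy as np
import pytest

from olivepedigree import (
    ErrorModel,
    calibrate_thresholds,
    cervus_duo_search,
    duo_lod,
    transition_prob,
    trio_lod,
    trio_search,
)
from olivepedigree.config import CalibrationSettings, ConfigurationError
from olivepedigree.likelihood import (
    DegenerateFrequencyError,
    ThresholdSet,
    TransitionTables,
)

from conftest import matrix_from_rows


# --- independent oracle (allele enumeration, e = 0) ------------------------


def _alleles(g):
    return [1] * g + [0] * (2 - g)


def oracle_duo_prob(go, gp, p):
    """P(offspring | one parent) by enumerating transmitted + population
    alleles."""
    total = 0.0
    for a in _alleles(gp):  # transmitted parental allele, each w.p. 1/2
        for b, pb in ((1, p), (0, 1 - p)):  # untransmitted from population
            if a + b == go:
                total += 0.5 * pb
    return total


def oracle_trio_prob(go, ga, gb):
    total = 0.0
    for x in _alleles(ga):
        for y in _alleles(gb):
            if x + y == go:
                total += 0.25
    return total


def hwe(g, p):
    return {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p * p}[g]


def oracle_duo_lod(offs, par, ps):
    tot = 0.0
    for go, gp, p in zip(offs, par, ps):
        num = oracle_duo_prob(go, gp, p)
        tot += math.log(num / hwe(go, p)) if num > 0 else -math.inf
    return tot


def oracle_trio_lod(offs, pa, pb, ps):
    tot = 0.0
    for go, ga, gb, p in zip(offs, pa, pb, ps):
        num = oracle_trio_prob(go, ga, gb)
        tot += math.log(num / hwe(go, p)) if num > 0 else -math.inf
    return tot


# --- hand-computed transition values ----------------------------------------


class TestTransitionProb:
    def test_het_offspring_from_hom_parent(self):
        # offspring Aa from parent AA at p=0.5: transmits A, other allele a
        t = transition_prob(1, 2, None, 0.5, ErrorModel(0.0))
        assert t == pytest.approx(0.5)
        # per-locus LOD ln(t / 2pq) = ln(1) = 0
        assert math.log(t / 0.5) == pytest.approx(0.0)

    def test_hom_offspring_from_hom_parent(self):
        t = transition_prob(2, 2, None, 0.5, ErrorModel(0.0))
        assert t == pytest.approx(0.5)
        assert math.log(t / 0.25) == pytest.approx(math.log(2))

    def test_forced_homozygous_cross(self):
        assert transition_prob(2, 2, 2, 0.5, ErrorModel(0.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("e", [0.0, 0.01, 0.2])
    @pytest.mark.parametrize("p", [0.1, 0.38, 0.5, 0.9])
    def test_normalization_over_offspring(self, e, p):
        """Sum over offspring genotypes is 1 for every parent configuration."""
        model = ErrorModel(e)
        for gp in (0, 1, 2):
            total = sum(transition_prob(go, gp, None, p, model) for go in (0, 1, 2))
            assert total == pytest.approx(1.0, abs=1e-12)
            for gq in (0, 1, 2):
                total = sum(
                    transition_prob(go, gp, gq, p, model) for go in (0, 1, 2)
                )
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(DegenerateFrequencyError):
            transition_prob(1, 1, None, 1.0)

    def test_matches_oracle_at_zero_error(self):
        for p in (0.2, 0.5, 0.7):
            for gp in (0, 1, 2):
                for go in (0, 1, 2):
                    assert transition_prob(go, gp, None, p, ErrorModel(0.0)) == \
                        pytest.approx(oracle_duo_prob(go, gp, p), abs=1e-12)


class TestLodScores:
    def _thresholds(self):
        return ThresholdSet(0.0, 0.0, CalibrationSettings(), seed=0)

    def test_duo_lod_equals_sum_of_per_locus_terms(self):
        # identical homozygous-ref genotypes at p=0.5 contribute ln 2 each
        g = matrix_from_rows({"o": [2, 2, 2], "p": [2, 2, 2]})
        r = duo_lod(g, np.full(3, 0.5), "o", "p", ErrorModel(0.0))
        assert r.lod == pytest.approx(3 * math.log(2), abs=1e-12)
        assert r.n_loci_compared == 3

    def test_three_opposite_hom_loci_fail_mismatch_criterion(self):
        g = matrix_from_rows({"o": [0, 0, 0, 1], "p": [2, 2, 2, 1]})
        r = duo_lod(g, np.full(4, 0.5), "o", "p", ErrorModel(0.01))
        assert r.n_mismatch == 3
        assert r.n_mismatch > 2  # exceeds the two-locus cap

    def test_error_model_keeps_lod_finite(self):
        g = matrix_from_rows({"o": [0], "p": [2]})
        r = duo_lod(g, np.array([0.5]), "o", "p", ErrorModel(0.01))
        assert np.isfinite(r.lod) and r.lod < 0

    def test_self_comparison_rejected(self):
        g = matrix_from_rows({"o": [1], "p": [1]})
        with pytest.raises(ValueError, match="self-comparison"):
            duo_lod(g, np.array([0.5]), "o", "o")
        with pytest.raises(ValueError):
            trio_lod(g, np.array([0.5]), "o", "o", "p")

    def test_oracle_equivalence_small_instances(self):
        """Vectorized LOD equals allele-enumeration brute force at e=0."""
        rng = np.random.default_rng(4)
        model = ErrorModel(0.0)
        for _ in range(60):
            L = int(rng.integers(1, 4))
            ps = rng.uniform(0.1, 0.9, size=L)
            offs = rng.integers(0, 3, size=L)
            pa = rng.integers(0, 3, size=L)
            pb = rng.integers(0, 3, size=L)
            g = matrix_from_rows({
                "o": offs.tolist(), "a": pa.tolist(), "b": pb.tolist()
            })
            want = oracle_duo_lod(offs, pa, ps)
            got = duo_lod(g, ps, "o", "a", model).lod
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)
            want = oracle_trio_lod(offs, pa, pb, ps)
            got = trio_lod(g, ps, "o", "a", "b", model).lod
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_expected_per_locus_lod_nonnegative_with_true_parent(self):
        """Under the true-parent hypothesis the expected per-locus LOD
        contribution is a KL-type divergence, hence >= 0 at every locus."""
        for p in (0.1, 0.25, 0.38, 0.5):
            tables = TransitionTables(np.array([p]), ErrorModel(0.0))
            f = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
            expectation = 0.0
            for gp in (0, 1, 2):
                for go in (0, 1, 2):
                    joint = f[gp] * oracle_duo_prob(go, gp, p)
                    if joint > 0:
                        expectation += joint * tables.duo_lod[0, gp, go]
            assert expectation >= -1e-12


class TestSearches:
    def test_duo_search_symmetric_and_excludes_self(self, clean_dataset):
        g = clean_dataset.clean.subset(clean_dataset.clean.ids[:30])
        freqs = g.allele_frequencies()
        ts = ThresholdSet(4.0, 12.0, CalibrationSettings(), seed=0)
        table = cervus_duo_search(g, freqs, ts)
        assert (table["id_a"] != table["id_b"]).all()
        # role symmetry of the duo LOD: recompute one pair reversed
        row = table.iloc[0]
        a = duo_lod(g, freqs, row["id_a"], row["id_b"], ErrorModel(0.01)).lod
        b = duo_lod(g, freqs, row["id_b"], row["id_a"], ErrorModel(0.01)).lod
        assert a == pytest.approx(b, abs=1e-9)

    def test_true_trio_found_error_free(self, clean_dataset):
        ds = clean_dataset
        g = ds.clean
        freqs = g.allele_frequencies()
        ts = ThresholdSet(2.0, 8.0, CalibrationSettings(error_rate=0.0), seed=0)
        duos = cervus_duo_search(g, freqs, ts, ErrorModel(0.01))
        kid = ds.truth[ds.truth["generation"] == 1].iloc[0]
        trios = trio_search(
            g, freqs, ts, duos, ErrorModel(0.01), offspring_ids=[kid["id"]]
        )
        hit = trios[
            trios["passes"]
            & trios[["parent_a", "parent_b"]].apply(
                lambda r: {r["parent_a"], r["parent_b"]}
                == {kid["mother"], kid["father"]},
                axis=1,
            )
        ]
        assert len(hit) == 1


class TestCalibration:
    def test_zero_offspring_rejected(self):
        with pytest.raises(ConfigurationError):
            CalibrationSettings(n_offspring=0).validate()

    def test_more_loci_give_higher_pair_threshold(self, fast_calibration):
        """Pair LOD separation grows with panel size, so the calibrated
        LOD_pp cutoff does too; the duo cutoff instead tracks the shrinking
        contamination tail and is not monotone in loci."""
        rng = np.random.default_rng(6)
        p96 = rng.uniform(0.1, 0.5, size=96)
        t96 = calibrate_thresholds(p96, fast_calibration)
        t24 = calibrate_thresholds(p96[:24], fast_calibration)
        assert t96.lod_pp_strict >= t24.lod_pp_strict
        assert t96.quality["duo_separable"] and t96.quality["trio_separable"]
        assert np.isfinite(t96.lod_p_strict) and np.isfinite(t24.lod_p_strict)

    def test_repeat_seed_stability(self, fast_calibration):
        p = np.full(96, 0.5)
        s1 = CalibrationSettings(
            n_offspring=4000, n_candidate_parents=60, seed=21
        )
        s2 = CalibrationSettings(
            n_offspring=4000, n_candidate_parents=60, seed=22
        )
        a = calibrate_thresholds(p, s1)
        b = calibrate_thresholds(p, s2)
        assert abs(a.lod_p_strict - b.lod_p_strict) < 1.5
        assert abs(a.lod_pp_strict - b.lod_pp_strict) < 2.5

    def test_same_seed_reproduces_exactly(self, fast_calibration):
        p = np.linspace(0.2, 0.5, 96)
        a = calibrate_thresholds(p, fast_calibration)
        b = calibrate_thresholds(p, fast_calibration)
        assert a.lod_p_strict == b.lod_p_strict
        assert a.lod_pp_strict == b.lod_pp_strict
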