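"""Biological validation and deduction rules on robust trios."""

import numpy as np
import pandas as pd
import pytest

from olivepedigree import assign_clusters, deduce_attributes, duo_cluster_crosstab, validate_trio
from olivepedigree.containers import ValidationError


def meta(rows):
    df = pd.DataFrame(rows)
    for col in ("region", "chlorotype", "si_group", "andro_sterile",
                "q_A", "q_B", "q_C"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def trio(o, a, b):
    return pd.DataFrame([{"offspring": o, "parent_a": a, "parent_b": b}])


class TestValidateTrio:
    def test_same_si_group_is_violation(self):
        m = meta([
            {"id": "o"}, {"id": "a", "si_group": "G1"},
            {"id": "b", "si_group": "G1"},
        ])
        ann = validate_trio(trio("o", "a", "b").iloc[0], m)
        assert ann.consistency == "inconsistent"
        assert any("SI" in v for v in ann.violations)

    def test_maternal_chlorotype_consistency_and_roles(self):
        m = meta([
            {"id": "o", "chlorotype": "E1.1"},
            {"id": "a", "chlorotype": "E1.1"},
            {"id": "b", "chlorotype": "E1.2"},
        ])
        ann = validate_trio(trio("o", "a", "b").iloc[0], m)
        assert ann.consistency != "inconsistent"
        anns, _ = deduce_attributes(trio("o", "a", "b"), m)
        assert anns[0].mother == "a" and anns[0].father == "b"

    def test_offspring_chlorotype_matching_neither_parent(self):
        m = meta([
            {"id": "o", "chlorotype": "E2"},
            {"id": "a", "chlorotype": "E1.1"},
            {"id": "b", "chlorotype": "E1.2"},
        ])
        ann = validate_trio(trio("o", "a", "b").iloc[0], m)
        assert ann.consistency == "inconsistent"

    def test_all_unknown_is_incomplete(self):
        m = meta([{"id": "o"}, {"id": "a"}, {"id": "b"}])
        ann = validate_trio(trio("o", "a", "b").iloc[0], m)
        assert ann.consistency == "incomplete"
        assert not ann.violations


class TestDeduction:
    def test_si_complement(self):
        m = meta([{"id": "o"}, {"id": "a", "si_group": "G1"}, {"id": "b"}])
        _, deduced = deduce_attributes(trio("o", "a", "b"), m)
        row = deduced[(deduced["id"] == "b") & (deduced["attribute"] == "si_group")]
        assert row["value"].iloc[0] == "G2"
        assert row["provenance"].iloc[0] == "DED-a"

    def test_offspring_chlorotype_from_agreeing_parents(self):
        m = meta([
            {"id": "o"},
            {"id": "a", "chlorotype": "E1.1"},
            {"id": "b", "chlorotype": "E1.1"},
        ])
        _, deduced = deduce_attributes(trio("o", "a", "b"), m)
        row = deduced[(deduced["id"] == "o") & (deduced["attribute"] == "chlorotype")]
        assert row["value"].iloc[0] == "E1.1"
        assert row["provenance"].iloc[0] == "DED-b"

    def test_sterile_parent_becomes_mother_and_propagates_chlorotype(self):
        m = meta([
            {"id": "o"},
            {"id": "a", "chlorotype": "E3.1", "andro_sterile": True},
            {"id": "b", "chlorotype": "E1.1", "andro_sterile": False},
        ])
        anns, deduced = deduce_attributes(trio("o", "a", "b"), m)
        assert anns[0].mother == "a"
        assert anns[0].provenance["role.a"] == "DED-d"
        row = deduced[(deduced["id"] == "o") & (deduced["attribute"] == "chlorotype")]
        assert row["value"].iloc[0] == "E3.1"

    def test_observation_never_overwritten(self):
        m = meta([
            {"id": "o", "chlorotype": "E2"},  # observed, contradicts deduction
            {"id": "a", "chlorotype": "E1.1"},
            {"id": "b", "chlorotype": "E1.1"},
        ])
        anns, deduced = deduce_attributes(trio("o", "a", "b"), m)
        assert deduced[(deduced["id"] == "o")].empty
        assert anns[0].consistency == "inconsistent"

    def test_conflicting_deductions_freeze_attribute(self):
        # two trios imply different chlorotypes for the same offspring
        trios = pd.DataFrame([
            {"offspring": "o", "parent_a": "a1", "parent_b": "a2"},
            {"offspring": "o", "parent_a": "b1", "parent_b": "b2"},
        ])
        m = meta([
            {"id": "o"},
            {"id": "a1", "chlorotype": "E1.1"}, {"id": "a2", "chlorotype": "E1.1"},
            {"id": "b1", "chlorotype": "E2"}, {"id": "b2", "chlorotype": "E2"},
        ])
        _, deduced = deduce_attributes(trios, m)
        row = deduced[(deduced["id"] == "o") & (deduced["attribute"] == "chlorotype")]
        assert row["value"].iloc[0] == "__conflict__"

    def test_roles_indeterminate_when_parents_share_offspring_chlorotype(self):
        m = meta([
            {"id": "o", "chlorotype": "E1.1"},
            {"id": "a", "chlorotype": "E1.1"},
            {"id": "b", "chlorotype": "E1.1"},
        ])
        anns, _ = deduce_attributes(trio("o", "a", "b"), m)
        assert anns[0].mother is None and anns[0].father is None

    def test_soundness_against_simulation_truth(self, clean_dataset):
        """With true trios and partially blanked metadata, every deduction
        agrees with the simulated truth."""
        truth = clean_dataset.truth
        kids = truth[truth["mother"].notna() & truth["father"].notna()]
        trios_df = pd.DataFrame({
            "offspring": kids["id"],
            "parent_a": kids["mother"],
            "parent_b": kids["father"],
        })
        blanked = clean_dataset.metadata.copy()
        rng = np.random.default_rng(8)
        hide = rng.random(len(blanked)) < 0.4
        blanked.loc[hide, ["chlorotype", "si_group"]] = np.nan
        _, deduced = deduce_attributes(trios_df, blanked)
        tix = truth.set_index("id")
        checked = 0
        for _, row in deduced.iterrows():
            if row["value"] == "__conflict__":
                continue
            true_val = tix.loc[row["id"], row["attribute"]]
            assert str(row["value"]) == str(true_val), row.to_dict()
            checked += 1
        assert checked > 0


class TestClusters:
    def test_threshold_rule(self):
        m = meta([
            {"id": "a", "q_A": 0.80, "q_B": 0.15, "q_C": 0.05},
            {"id": "b", "q_A": 0.50, "q_B": 0.30, "q_C": 0.20},
            {"id": "c", "q_A": 0.75, "q_B": 0.15, "q_C": 0.10},
            {"id": "d"},
        ])
        out = assign_clusters(m)
        got = dict(zip(out["id"], out["cluster"]))
        assert got == {"a": "A", "b": "admixed", "c": "admixed", "d": "unknown"}

    def test_bad_q_vector_raises_with_name(self):
        m = meta([{"id": "bad", "q_A": 0.9, "q_B": 0.9, "q_C": 0.9}])
        with pytest.raises(ValidationError, match="bad"):
            assign_clusters(m)

    def test_crosstab_rows_sum_to_100(self):
        duos = pd.DataFrame({
            "id_a": ["a", "a", "b"],
            "id_b": ["b", "c", "c"],
            "consensus": [True, True, True],
        })
        m = meta([
            {"id": "a", "q_A": 0.9, "q_B": 0.05, "q_C": 0.05},
            {"id": "b", "q_A": 0.05, "q_B": 0.9, "q_C": 0.05},
            {"id": "c", "q_A": 0.2, "q_B": 0.3, "q_C": 0.5},
        ])
        tab = duo_cluster_crosstab(duos, m)
        sums = tab.sum(axis=1)
        for label in ("A", "B"):
            assert sums[label] == pytest.approx(100.0)
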