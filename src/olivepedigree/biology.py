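"""Validation and logical deduction on robust trios from side information.

Three independent biological systems constrain a parent-parent-offspring
trio: the diallelic self-incompatibility system (a cross requires parents
from opposite stigmatic groups G1/G2), maternal inheritance of the
chloroplast haplotype (the offspring carries its mother's chlorotype), and
andro-sterility (a male-sterile tree cannot be the pollen donor). When trio
metadata is complete these act as validation filters; when partial, the same
rules run in the deductive direction and propagate to a fixpoint across the
trio set, filling in stigmatic groups, chlorotypes, and parental roles with
per-deduction provenance.

Provenance codes: OBS observed; DED-a SI complement across a parental pair;
DED-b offspring chlorotype from two agreeing parents; DED-c maternal
chlorotype inheritance once roles are known (either direction); DED-d
andro-sterile parent assigned the mother role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import validate_metadata

logger = logging.getLogger(__name__)

CLUSTERS = ("A", "B", "C")
_CONFLICT = "__conflict__"


@dataclass
class TrioAnnotation:
    """Validation and deduction record for one robust trio."""

    offspring: str
    parent_a: str
    parent_b: str
    consistency: str = "incomplete"  # consistent | inconsistent | incomplete
    violations: list[str] = field(default_factory=list)
    mother: str | None = None
    father: str | None = None
    deduced: dict[str, str] = field(default_factory=dict)   # "<id>.<attr>" -> value
    provenance: dict[str, str] = field(default_factory=dict)


class _Attrs:
    """Attribute store with observation-wins semantics and conflict freeze."""

    def __init__(self, metadata: pd.DataFrame | None):
        self.values: dict[tuple[str, str], str] = {}
        self.sources: dict[tuple[str, str], str] = {}
        if metadata is None:
            return
        meta = metadata.set_index("id")
        for ind in meta.index:
            row = meta.loc[ind]
            chloro = row.get("chlorotype")
            if isinstance(chloro, str) and chloro:
                self._put(ind, "chlorotype", chloro, "OBS")
            si = row.get("si_group")
            if isinstance(si, str) and si in ("G1", "G2"):
                self._put(ind, "si_group", si, "OBS")
            st = row.get("andro_sterile")
            if st is True or st is False or st in ("True", "False"):
                self._put(ind, "andro_sterile", str(bool(st in (True, "True"))), "OBS")

    def _put(self, ind: str, attr: str, value: str, source: str) -> None:
        self.values[(ind, attr)] = value
        self.sources[(ind, attr)] = source

    def get(self, ind: str, attr: str) -> str | None:
        v = self.values.get((ind, attr))
        return None if v == _CONFLICT else v

    def observed(self, ind: str, attr: str) -> bool:
        return self.sources.get((ind, attr)) == "OBS"

    def deduce(self, ind: str, attr: str, value: str, source: str) -> bool:
        """Record a deduction; returns True when the store changed.

        Observed values are never overwritten; a deduction contradicting an
        observation is discarded (the caller flags the trio); contradictory
        deductions freeze the attribute and log both sources.
        """
        key = (ind, attr)
        current = self.values.get(key)
        if current is None:
            self._put(ind, attr, value, source)
            return True
        if current == _CONFLICT or current == value:
            return False
        if self.sources[key] == "OBS":
            return False
        logger.warning(
            "conflicting deductions for %s.%s: %s (%s) vs %s (%s); frozen",
            ind, attr, current, self.sources[key], value, source,
        )
        self._put(ind, attr, _CONFLICT, f"{self.sources[key]}|{source}")
        return True


def validate_trio(
    trio, metadata: pd.DataFrame | None, attrs: _Attrs | None = None
) -> TrioAnnotation:
    """Check one trio against chlorotype, SI, and andro-sterility data.

    ``trio`` needs ``offspring``, ``parent_a``, ``parent_b`` fields (a
    DataFrame row or mapping). Incompleteness is a status, never an error.
    """
    if attrs is None:
        attrs = _Attrs(metadata)
    o, a, b = trio["offspring"], trio["parent_a"], trio["parent_b"]
    ann = TrioAnnotation(o, a, b)

    si_a, si_b = attrs.get(a, "si_group"), attrs.get(b, "si_group")
    if si_a is not None and si_b is not None and si_a == si_b:
        ann.violations.append("SI complementarity: both parents " + si_a)

    st_a, st_b = attrs.get(a, "andro_sterile"), attrs.get(b, "andro_sterile")
    if st_a == "True" and st_b == "True":
        ann.violations.append("both parents andro-sterile")

    ch_o = attrs.get(o, "chlorotype")
    ch_a, ch_b = attrs.get(a, "chlorotype"), attrs.get(b, "chlorotype")
    if ch_o is not None and ch_a is not None and ch_b is not None:
        if ch_o not in (ch_a, ch_b):
            ann.violations.append(
                f"chlorotype maternal inheritance: offspring {ch_o} "
                f"matches neither parent ({ch_a}, {ch_b})"
            )

    known = [si_a, si_b, st_a, st_b, ch_o, ch_a, ch_b]
    if ann.violations:
        ann.consistency = "inconsistent"
    elif any(v is None for v in known):
        ann.consistency = "incomplete"
    else:
        ann.consistency = "consistent"
    return ann


def _deduce_in_trio(ann: TrioAnnotation, attrs: _Attrs) -> bool:
    """One deduction sweep inside a single trio; returns True on change."""
    changed = False
    o, a, b = ann.offspring, ann.parent_a, ann.parent_b

    def record(ind, attr, value, code):
        nonlocal changed
        if attrs.deduce(ind, attr, value, code):
            changed = True
        if attrs.get(ind, attr) == value and not attrs.observed(ind, attr):
            ann.deduced[f"{ind}.{attr}"] = value
            ann.provenance[f"{ind}.{attr}"] = code

    # (a) SI complement across the parental pair. Attempts are idempotent;
    # a contradictory attempt lets the store freeze the attribute.
    si_a, si_b = attrs.get(a, "si_group"), attrs.get(b, "si_group")
    if si_a in ("G1", "G2"):
        record(b, "si_group", "G2" if si_a == "G1" else "G1", "DED-a")
    if si_b in ("G1", "G2"):
        record(a, "si_group", "G2" if si_b == "G1" else "G1", "DED-a")

    # (b) Offspring chlorotype from two agreeing parents.
    ch_a, ch_b = attrs.get(a, "chlorotype"), attrs.get(b, "chlorotype")
    ch_o = attrs.get(o, "chlorotype")
    if ch_a is not None and ch_a == ch_b:
        record(o, "chlorotype", ch_a, "DED-b")
        ch_o = attrs.get(o, "chlorotype")

    # (d) An andro-sterile parent is the mother.
    st_a, st_b = attrs.get(a, "andro_sterile"), attrs.get(b, "andro_sterile")
    if ann.mother is None:
        if st_a == "True" and st_b != "True":
            ann.mother, ann.father = a, b
            ann.provenance[f"role.{a}"] = "DED-d"
            changed = True
        elif st_b == "True" and st_a != "True":
            ann.mother, ann.father = b, a
            ann.provenance[f"role.{b}"] = "DED-d"
            changed = True

    # (c) Parent chlorotype vs offspring chlorotype orients the roles; once
    # the mother is known, maternal inheritance fills missing chlorotypes.
    if ann.mother is None and ch_o is not None:
        match_a = ch_a == ch_o if ch_a is not None else None
        match_b = ch_b == ch_o if ch_b is not None else None
        if match_a is True and match_b is False:
            ann.mother, ann.father = a, b
            ann.provenance[f"role.{a}"] = "DED-c"
            changed = True
        elif match_b is True and match_a is False:
            ann.mother, ann.father = b, a
            ann.provenance[f"role.{b}"] = "DED-c"
            changed = True
        elif match_a is False and ch_b is None:
            # the differing parent must be the father
            ann.mother, ann.father = b, a
            ann.provenance[f"role.{b}"] = "DED-c"
            changed = True
        elif match_b is False and ch_a is None:
            ann.mother, ann.father = a, b
            ann.provenance[f"role.{a}"] = "DED-c"
            changed = True
        # both parents matching: role indeterminate, left unknown

    if ann.mother is not None:
        ch_m = attrs.get(ann.mother, "chlorotype")
        ch_o = attrs.get(o, "chlorotype")
        if ch_m is not None:
            record(o, "chlorotype", ch_m, "DED-c")
        elif ch_o is not None:
            record(ann.mother, "chlorotype", ch_o, "DED-c")
    return changed


def deduce_attributes(
    trios: pd.DataFrame, metadata: pd.DataFrame | None
) -> tuple[list[TrioAnnotation], pd.DataFrame]:
    """Validate all trios and propagate deductions to a fixpoint.

    Sweeps trios in lexicographic (offspring, parent_a, parent_b) order;
    attribute states only move unknown -> known (or frozen on conflict), so
    iteration terminates. Returns the annotations and a table of deduced
    attributes (individual, attribute, value, provenance).
    """
    attrs = _Attrs(metadata)
    order = trios.sort_values(
        ["offspring", "parent_a", "parent_b"]
    ).reset_index(drop=True)
    anns = [
        TrioAnnotation(r["offspring"], r["parent_a"], r["parent_b"])
        for _, r in order.iterrows()
    ]
    for _ in range(max(1, len(anns)) * 4):
        changed = False
        for ann in anns:
            if _deduce_in_trio(ann, attrs):
                changed = True
        if not changed:
            break

    for ann in anns:
        check = validate_trio(
            {"offspring": ann.offspring, "parent_a": ann.parent_a,
             "parent_b": ann.parent_b},
            None,
            attrs=attrs,
        )
        ann.violations = check.violations
        ann.consistency = check.consistency

    rows = [
        {
            "id": ind,
            "attribute": attr,
            "value": attrs.values[(ind, attr)],
            "provenance": attrs.sources[(ind, attr)],
        }
        for (ind, attr) in sorted(attrs.values)
        if attrs.sources[(ind, attr)] != "OBS"
    ]
    deduced = pd.DataFrame(rows, columns=["id", "attribute", "value", "provenance"])
    return anns, deduced


def annotations_frame(anns: list[TrioAnnotation]) -> pd.DataFrame:
    """Serialize annotations for the CSV artifact."""
    return pd.DataFrame([
        {
            "offspring": a.offspring,
            "parent_a": a.parent_a,
            "parent_b": a.parent_b,
            "consistency": a.consistency,
            "violations": ";".join(a.violations),
            "mother": a.mother or "",
            "father": a.father or "",
            "deductions": ";".join(
                f"{k}={v}[{a.provenance.get(k, '')}]" for k, v in sorted(a.deduced.items())
            ),
        }
        for a in anns
    ])


# ---------------------------------------------------------------------------
# Admixture clusters


def assign_clusters(
    metadata: pd.DataFrame, q_threshold: float = 0.75
) -> pd.DataFrame:
    """Assign each cultivar to cluster A/B/C when its max Q strictly exceeds
    the threshold, else ``admixed``; individuals without a Q-vector are
    ``unknown``. Malformed Q-vectors raise a validation error naming the
    individual."""
    validate_metadata(metadata)
    out = metadata.copy()
    qcols = ["q_A", "q_B", "q_C"]
    clusters = []
    for _, row in out.iterrows():
        q = row[qcols].to_numpy(dtype=float)
        if np.isnan(q).any():
            clusters.append("unknown")
            continue
        k = int(np.argmax(q))
        clusters.append(CLUSTERS[k] if q[k] > q_threshold else "admixed")
    out["cluster"] = clusters
    return out


def duo_cluster_crosstab(
    duos: pd.DataFrame, metadata: pd.DataFrame, q_threshold: float = 0.75
) -> pd.DataFrame:
    """Percentage distribution of consensus duos by cluster assignment.

    Duos are unordered, so each duo contributes both orientations; rows are
    the cluster of one member, columns the cluster of its partner, and rows
    are normalized to percentages.
    """
    meta = assign_clusters(metadata, q_threshold)
    cluster_of = dict(zip(meta["id"], meta["cluster"]))
    cats = list(CLUSTERS) + ["admixed", "unknown"]
    counts = pd.DataFrame(0, index=cats, columns=cats, dtype=float)
    table = duos[duos["consensus"]] if "consensus" in duos.columns else duos
    for x, y in zip(table["id_a"], table["id_b"]):
        cx = cluster_of.get(x, "unknown")
        cy = cluster_of.get(y, "unknown")
        counts.loc[cx, cy] += 1
        counts.loc[cy, cx] += 1
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(row_sums, axis=0) * 100.0
    return pct.fillna(0.0)
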