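"""Consensus of the two duo approaches, robust-trio selection, and
sensitivity scenarios.

Robust-trio selection keeps at most one trio per offspring: candidate pairs
are ranked by parent-pair LOD; exact ties cascade through (i) fewest trio
mismatching loci, (ii) most parents supported in the consensus duo analysis,
(iii) consistency of parental regions with the offspring's region, and
finally lexicographic parent-pair order so the selection is total and
deterministic. Offspring with more than a configurable number of supported
parental pairs (default 20) receive no trio: that pattern marks an individual
acting predominantly as a parent. Cross-trio contradictions (the same
cultivar offspring in one trio and parent of one of its own parents in
another) are resolved by retaining the higher-LOD trio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import likelihood

logger = logging.getLogger(__name__)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def intersect_duos(
    kinship_duos: pd.DataFrame, likelihood_duos: pd.DataFrame
) -> pd.DataFrame:
    """Unordered-pair consensus of the two duo approaches.

    Returns the full audit table (union of pairs appearing in either passing
    set) with per-method support flags; the consensus duos are the rows with
    ``consensus == True``. Kinship statistics (phi, opposite homozygotes) and
    likelihood statistics (LOD) are carried along when available.
    """
    k = kinship_duos[kinship_duos["passes"]]
    l = likelihood_duos[likelihood_duos["passes"]]
    kset = {
        _pair_key(r.id_a, r.id_b): r for r in k.itertuples(index=False)
    }
    lset = {
        _pair_key(r.id_a, r.id_b): r for r in l.itertuples(index=False)
    }
    rows = []
    for pair in sorted(set(kset) | set(lset)):
        kr = kset.get(pair)
        lr = lset.get(pair)
        rows.append({
            "id_a": pair[0],
            "id_b": pair[1],
            "kinship_pass": kr is not None,
            "likelihood_pass": lr is not None,
            "consensus": kr is not None and lr is not None,
            "phi": float(kr.phi) if kr is not None else np.nan,
            "n_opposite_hom": int(kr.n_opposite_hom) if kr is not None else -1,
            "lod": float(lr.lod) if lr is not None else np.nan,
            "n_mismatch": int(lr.n_mismatch) if lr is not None else -1,
        })
    cols = ["id_a", "id_b", "kinship_pass", "likelihood_pass", "consensus",
            "phi", "n_opposite_hom", "lod", "n_mismatch"]
    return pd.DataFrame(rows, columns=cols).astype(
        {"kinship_pass": bool, "likelihood_pass": bool, "consensus": bool}
    )


def duo_counts(duo_audit: pd.DataFrame, consensus_only: bool = True) -> pd.Series:
    """Per-individual number of duos (founder-importance ranking input)."""
    table = duo_audit[duo_audit["consensus"]] if consensus_only else duo_audit
    counts = pd.concat([table["id_a"], table["id_b"]]).value_counts()
    counts.name = "n_duos"
    return counts


@dataclass
class RobustTrioSelection:
    """Result of robust-trio selection."""

    trios: pd.DataFrame      # one row per offspring that received a trio
    excluded: pd.DataFrame   # offspring excluded with a reason
    conflicts: pd.DataFrame  # cross-trio contradictions and their resolution


def _partner_sets(duo_audit: pd.DataFrame) -> dict[str, set]:
    partners: dict[str, set] = {}
    cons = duo_audit[duo_audit["consensus"]]
    for a, b in zip(cons["id_a"], cons["id_b"]):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return partners


def select_robust_trios(
    trios: pd.DataFrame,
    duo_audit: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    max_supported_pairs: int = 20,
) -> RobustTrioSelection:
    """Pick at most one robust trio per offspring from passing candidates.

    ``trios`` is the scored candidate table (``passes`` marks pairs meeting
    the LOD and mismatch criteria); ``duo_audit`` is the consensus table from
    :func:`intersect_duos` (used for tie-break (ii)); ``metadata`` supplies
    regions for tie-break (iii) and is optional — when absent that rule is
    skipped with a logged notice.
    """
    passing = trios[trios["passes"]].copy()
    partners = _partner_sets(duo_audit)

    regions: dict[str, str] = {}
    if metadata is not None and "region" in metadata.columns:
        for i, r in zip(metadata["id"], metadata["region"]):
            if isinstance(r, str) and r:
                regions[i] = r

    selected: dict[str, dict] = {}
    excluded_rows = []

    for offspring, group in passing.groupby("offspring", sort=True):
        if len(group) > max_supported_pairs:
            excluded_rows.append({
                "offspring": offspring,
                "n_supported_pairs": len(group),
                "reason": "acts_as_parent",
            })
            continue
        cands = group.copy()
        cons = partners.get(offspring, set())
        cands["n_duo_supported"] = [
            int(a in cons) + int(b in cons)
            for a, b in zip(cands["parent_a"], cands["parent_b"])
        ]
        trace = ["lod_pp"]
        best = cands[cands["lod_pp"] == cands["lod_pp"].max()]
        if len(best) > 1:
            trace.append("i:fewest_mismatches")
            best = best[best["n_mismatch"] == best["n_mismatch"].min()]
        if len(best) > 1:
            trace.append("ii:duo_supported_parents")
            best = best[best["n_duo_supported"] == best["n_duo_supported"].max()]
        if len(best) > 1:
            o_region = regions.get(offspring)
            if o_region is None:
                logger.info(
                    "tie-break (iii) skipped for %s: region unknown", offspring
                )
            else:
                trace.append("iii:region_consistency")
                score = np.array([
                    int(regions.get(a) == o_region) + int(regions.get(b) == o_region)
                    for a, b in zip(best["parent_a"], best["parent_b"])
                ])
                best = best[score == score.max()]
        if len(best) > 1:
            trace.append("lexicographic")
            keys = [
                _pair_key(a, b)
                for a, b in zip(best["parent_a"], best["parent_b"])
            ]
            best = best.iloc[[int(np.argmin(np.array(keys, dtype=object)))]]
        row = best.iloc[0].to_dict()
        pa, pb = _pair_key(row["parent_a"], row["parent_b"])
        o_region = regions.get(offspring)
        region_consistent = (
            regions.get(pa) == o_region and regions.get(pb) == o_region
            if o_region is not None else None
        )
        selected[offspring] = {
            "offspring": offspring,
            "parent_a": pa,
            "parent_b": pb,
            "lod_pp": float(row["lod_pp"]),
            "n_compared": int(row["n_compared"]),
            "n_mismatch": int(row["n_mismatch"]),
            "n_duo_supported": int(row["n_duo_supported"]),
            "region_consistency": region_consistent,
            "selection_trace": ";".join(trace),
        }

    conflict_rows = []
    # Direct contradictions: X offspring of (A, B) while X parent of A.
    changed = True
    while changed:
        changed = False
        for x, trio in list(selected.items()):
            for parent in (trio["parent_a"], trio["parent_b"]):
                other = selected.get(parent)
                if other and x in (other["parent_a"], other["parent_b"]):
                    loser = x if trio["lod_pp"] < other["lod_pp"] else parent
                    winner = parent if loser == x else x
                    conflict_rows.append({
                        "kind": "direct",
                        "kept_offspring": winner,
                        "dropped_offspring": loser,
                        "lod_kept": selected[winner]["lod_pp"],
                        "lod_dropped": selected[loser]["lod_pp"],
                    })
                    del selected[loser]
                    excluded_rows.append({
                        "offspring": loser,
                        "n_supported_pairs": -1,
                        "reason": "cross_trio_conflict",
                    })
                    changed = True
                    break
            if changed:
                break

    # Longer cycles in the parent -> offspring graph: drop lowest-LOD trio.
    while True:
        graph = nx.DiGraph()
        for x, trio in selected.items():
            graph.add_edge(trio["parent_a"], x)
            graph.add_edge(trio["parent_b"], x)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            break
        members = {v for edge in cycle for v in edge[:2]}
        in_cycle = [x for x in selected if x in members]
        loser = min(in_cycle, key=lambda x: (selected[x]["lod_pp"], x))
        conflict_rows.append({
            "kind": "cycle",
            "kept_offspring": "",
            "dropped_offspring": loser,
            "lod_kept": np.nan,
            "lod_dropped": selected[loser]["lod_pp"],
        })
        del selected[loser]
        excluded_rows.append({
            "offspring": loser,
            "n_supported_pairs": -1,
            "reason": "pedigree_cycle",
        })

    trio_cols = ["offspring", "parent_a", "parent_b", "lod_pp", "n_compared",
                 "n_mismatch", "n_duo_supported", "region_consistency",
                 "selection_trace"]
    trios_df = pd.DataFrame(
        [selected[o] for o in sorted(selected)], columns=trio_cols
    )
    excluded_df = pd.DataFrame(
        excluded_rows, columns=["offspring", "n_supported_pairs", "reason"]
    )
    conflicts_df = pd.DataFrame(
        conflict_rows,
        columns=["kind", "kept_offspring", "dropped_offspring", "lod_kept",
                 "lod_dropped"],
    )
    return RobustTrioSelection(trios_df, excluded_df, conflicts_df)


def sensitivity_scenarios(
    g,
    freqs: np.ndarray,
    thresholds,
    duos_union: pd.DataFrame,
    duo_audit: pd.DataFrame,
    metadata: pd.DataFrame | None,
    validation: dict[str, tuple[str | None, str | None]],
    model=None,
    max_mismatch: int = 2,
    max_supported_pairs: int = 20,
) -> pd.DataFrame:
    """Re-run trio inference for validation offspring under three scenarios.

    ``validation`` maps each validation offspring to its known (mother,
    father). Scenario 1 is the unmodified baseline; scenario 2 removes one
    known parent (the father when known, else the mother) from that
    offspring's candidate set; scenario 3 removes both. Offspring absent
    from the genotype matrix are listed as skipped.

    Returns one row per (offspring, scenario) with the selected trio (if
    any), its LOD_pp, mismatches and whether it matches the known parents.
    """
    present = [o for o in validation if o in g._index]
    skipped = [o for o in validation if o not in g._index]
    rows = []
    for o in skipped:
        for scen in (1, 2, 3):
            rows.append({
                "offspring": o, "scenario": scen, "status": "skipped",
                "parent_a": None, "parent_b": None, "lod_pp": np.nan,
                "n_mismatch": -1, "matches_truth": False,
            })

    for scen in (1, 2, 3):
        excluded: dict[str, set] = {}
        if scen >= 2:
            for o in present:
                mother, father = validation[o]
                if scen == 2:
                    drop = father if father else mother
                    excluded[o] = {d for d in (drop,) if d}
                else:
                    excluded[o] = {d for d in (mother, father) if d}
        cand = likelihood.trio_search(
            g, freqs, thresholds, duos_union, model=model,
            max_mismatch=max_mismatch, excluded_parents=excluded or None,
            offspring_ids=present,
        )
        sel = select_robust_trios(
            cand, duo_audit, metadata, max_supported_pairs=max_supported_pairs
        )
        chosen = sel.trios.set_index("offspring") if not sel.trios.empty else None
        for o in present:
            mother, father = validation[o]
            truth_pair = _pair_key(mother, father) if mother and father else None
            if chosen is not None and o in chosen.index:
                r = chosen.loc[o]
                pair = (r["parent_a"], r["parent_b"])
                rows.append({
                    "offspring": o, "scenario": scen, "status": "trio",
                    "parent_a": pair[0], "parent_b": pair[1],
                    "lod_pp": float(r["lod_pp"]),
                    "n_mismatch": int(r["n_mismatch"]),
                    "matches_truth": truth_pair is not None and pair == truth_pair,
                })
            else:
                rows.append({
                    "offspring": o, "scenario": scen, "status": "collapsed",
                    "parent_a": None, "parent_b": None, "lod_pp": np.nan,
                    "n_mismatch": -1, "matches_truth": False,
                })
    out = pd.DataFrame(rows, columns=[
        "offspring", "scenario", "status", "parent_a", "parent_b", "lod_pp",
        "n_mismatch", "matches_truth",
    ])
    return out.sort_values(["offspring", "scenario"]).reset_index(drop=True)
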