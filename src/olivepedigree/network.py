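"""Pedigree network construction, founder ranking, and graph export.

Robust trios become a directed graph with two parent -> offspring edges per
trio. Node roles follow edge incidence: ``offspring`` (in-edges only),
``genitor`` (out-edges only), ``both``. Edges stay directed parent ->
offspring even when the mother/father roles are unknown; a deduced role is
an edge attribute, not a structural difference.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

EDGE_CSV_COLUMNS = ["parent", "offspring", "lod_pp", "trio_id"]


class NetworkStructureError(RuntimeError):
    """Raised when the robust-trio input violates its structural invariants."""


def build_network(
    robust_trios: pd.DataFrame, metadata: pd.DataFrame | None = None
) -> nx.DiGraph:
    """Directed pedigree graph from the robust-trio table.

    Each trio contributes exactly two edges annotated with the trio id and
    LOD_pp. Node attributes: role, and (when metadata is supplied) region,
    cluster, chlorotype, si_group. Weakly connected components are labelled
    on the nodes as ``component`` (0 = largest).
    """
    if robust_trios["offspring"].duplicated().any():
        dup = robust_trios.loc[
            robust_trios["offspring"].duplicated(), "offspring"
        ].iloc[0]
        raise NetworkStructureError(
            f"duplicate robust trio for offspring {dup!r}"
        )
    g = nx.DiGraph()
    for _, row in robust_trios.iterrows():
        trio_id = f"trio:{row['offspring']}"
        for parent in (row["parent_a"], row["parent_b"]):
            g.add_edge(
                parent, row["offspring"],
                lod_pp=float(row["lod_pp"]), trio_id=trio_id,
            )
    for node in g.nodes:
        has_in = g.in_degree(node) > 0
        has_out = g.out_degree(node) > 0
        g.nodes[node]["role"] = (
            "both" if has_in and has_out else "offspring" if has_in else "genitor"
        )
    if metadata is not None:
        meta = metadata.set_index("id")
        for node in g.nodes:
            if node in meta.index:
                row = meta.loc[node]
                for attr in ("region", "cluster", "chlorotype", "si_group"):
                    val = row.get(attr)
                    if isinstance(val, str) and val:
                        g.nodes[node][attr] = val
    components = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    for label, comp in enumerate(components):
        for node in comp:
            g.nodes[node]["component"] = label
    return g


def component_summary(g: nx.DiGraph) -> dict:
    """Size of the main continuous network and count of smaller subnetworks."""
    comps = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    return {
        "n_components": len(comps),
        "main_component_size": len(comps[0]) if comps else 0,
        "n_subnetworks": max(0, len(comps) - 1),
    }


def founder_ranking(
    g: nx.DiGraph,
    duo_audit: pd.DataFrame | None = None,
    highlight_duo_degree: int = 45,
    highlight_connections: int = 10,
) -> pd.DataFrame:
    """Rank cultivars by connectivity.

    Columns per cultivar: consensus-duo degree, trio out-degree (offspring
    parented), number of distinct parental pairs it belongs to, number of
    distinct co-parents, and highlight flags at the configured thresholds
    (defaults 45 duo relationships / 10 network connections). Sorted by duo
    degree then out-degree, descending.
    """
    nodes = set(g.nodes)
    duo_degree: dict[str, int] = {}
    if duo_audit is not None:
        cons = duo_audit[duo_audit["consensus"]] if "consensus" in duo_audit.columns \
            else duo_audit
        for a, b in zip(cons["id_a"], cons["id_b"]):
            duo_degree[a] = duo_degree.get(a, 0) + 1
            duo_degree[b] = duo_degree.get(b, 0) + 1
            nodes.update((a, b))

    pairs_of: dict[str, set] = {}
    for _, offspring, data in g.edges(data=True):
        parents = tuple(sorted(p for p, o in g.in_edges(offspring)))
        for p in parents:
            pairs_of.setdefault(p, set()).add(parents)

    rows = []
    for node in sorted(nodes):
        out_deg = g.out_degree(node) if node in g else 0
        pairs = pairs_of.get(node, set())
        coparents = {q for pair in pairs for q in pair if q != node}
        total_connections = (
            (g.degree(node) if node in g else 0)
        )
        rows.append({
            "id": node,
            "duo_degree": duo_degree.get(node, 0),
            "trio_out_degree": out_deg,
            "n_parental_pairs": len(pairs),
            "n_coparents": len(coparents),
            "highlight_founder": duo_degree.get(node, 0) > highlight_duo_degree,
            "highlight_connected": total_connections > highlight_connections,
        })
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["duo_degree", "trio_out_degree", "id"], ascending=[False, False, True]
    ).reset_index(drop=True)


def export_network(g: nx.DiGraph, path: str | Path, format: str | None = None) -> None:
    """Serialize the network as GraphML, DOT, or a CSV edge list.

    ``format`` defaults from the suffix (.graphml/.dot/.csv). The CSV edge
    list round-trips through :func:`read_edge_csv`.
    """
    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".dot": "dot", ".csv": "csv"}.get(
            path.suffix.lower(), ""
        )
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        _write_dot(g, path)
    elif format == "csv":
        rows = [
            {
                "parent": u,
                "offspring": v,
                "lod_pp": data.get("lod_pp", float("nan")),
                "trio_id": data.get("trio_id", ""),
            }
            for u, v, data in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=EDGE_CSV_COLUMNS).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported network format {format!r}")


def _quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    """Minimal Graphviz digraph writer (node roles as shape attributes)."""
    shapes = {"offspring": "ellipse", "genitor": "circle", "both": "diamond"}
    with open(path, "w") as fh:
        fh.write("digraph pedigree {\n")
        for node, data in sorted(g.nodes(data=True)):
            shape = shapes.get(data.get("role", ""), "ellipse")
            fh.write(f"  {_quote(node)} [shape={shape}];\n")
        for u, v, data in sorted(g.edges(data=True)):
            lod = data.get("lod_pp")
            attr = f' [label="{lod:.2f}"]' if lod is not None else ""
            fh.write(f"  {_quote(u)} -> {_quote(v)}{attr};\n")
        fh.write("}\n")


def read_edge_csv(path: str | Path) -> pd.DataFrame:
    """Read back a CSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path)
    missing = set(EDGE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"edge CSV missing columns {sorted(missing)}")
    if df.empty:
        return df[EDGE_CSV_COLUMNS]
    return df[EDGE_CSV_COLUMNS]
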