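"""Stage-by-stage orchestration of the parentage atlas.

Stage order: marker stats -> kinship duos -> threshold calibration ->
likelihood duos -> consensus -> trio candidates -> robust selection ->
biology annotation -> network -> reports. Every stage writes a CSV artifact
and logs its input/output counts; re-running with identical configuration
and seeds reproduces identical artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import biology, io, kinship, likelihood, network, simulate, trios
from .config import PipelineConfig
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineResult:
    """In-memory results of a full run (artifacts also written to disk)."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame | None
    truth: pd.DataFrame | None
    stats: io.MarkerStats
    kinship_duos: pd.DataFrame
    thresholds: likelihood.ThresholdSet
    likelihood_duos: pd.DataFrame
    duo_audit: pd.DataFrame
    trio_candidates: pd.DataFrame
    selection: trios.RobustTrioSelection
    annotations: list
    deductions: pd.DataFrame
    graph: object
    ranking: pd.DataFrame
    counts: dict = field(default_factory=dict)


def union_duos(
    kinship_duos: pd.DataFrame, likelihood_duos: pd.DataFrame
) -> pd.DataFrame:
    """Pairs passing at least one approach, as a minimal duo table."""
    k = kinship_duos.loc[kinship_duos["passes"], ["id_a", "id_b"]]
    l = likelihood_duos.loc[likelihood_duos["passes"], ["id_a", "id_b"]]
    pairs = {trios._pair_key(a, b) for a, b in zip(k["id_a"], k["id_b"])}
    pairs |= {trios._pair_key(a, b) for a, b in zip(l["id_a"], l["id_b"])}
    out = pd.DataFrame(sorted(pairs), columns=["id_a", "id_b"])
    out["passes"] = True
    return out


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineStageError(name, type(exc).__name__, str(exc)) from exc
        return inner
    return wrap


def load_inputs(
    config: PipelineConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame | None, pd.DataFrame | None]:
    """Read genotypes/metadata from disk, or simulate when configured."""
    if config.genotypes:
        g = io.read_genotypes(config.genotypes)
        meta = io.read_metadata(config.metadata) if config.metadata else None
        return g, meta, None
    if config.simulation is not None:
        ds = simulate.simulate_dataset(config.simulation)
        return ds.genotypes, ds.metadata, ds.truth
    raise PipelineStageError(
        "inputs", "no_input", "config must provide genotypes or a simulation block"
    )


def run_pipeline(
    config: PipelineConfig,
    g: GenotypeMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    truth: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute all stages; returns the in-memory result.

    Inputs may be passed directly (overriding config paths). Artifacts are
    written under ``out_dir`` unless ``write=False``.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        if write:
            df.to_csv(out / name, index=False)

    if g is None:
        g, metadata, truth = _stage("inputs")(load_inputs)(config)
    logger.info("inputs: %d individuals x %d loci", g.n_individuals, g.n_loci)

    g = _stage("locus_filter")(io.filter_loci_by_missingness)(
        g, config.max_missing_rate_per_locus
    )

    regions = None
    if metadata is not None and "region" in metadata.columns:
        regions = dict(zip(metadata["id"], metadata["region"]))
    stats = _stage("marker_stats")(io.marker_summary)(g, regions)
    save(stats.per_locus, "stats_per_locus.csv")
    for region, table in stats.per_region.items():
        save(table, f"stats_per_locus_{region}.csv")
    logger.info("marker_stats: %d loci summarized", len(stats.per_locus))

    kin = _stage("kinship_duos")(kinship.sambar_duo_search)(
        g, lo=config.kinship_lo, hi=config.kinship_hi,
        min_compared=config.min_compared_loci,
    )
    save(kin, "duos_kinship.csv")
    logger.info("kinship_duos: %d pairs scored, %d pass", len(kin),
                int(kin["passes"].sum()))

    freqs = g.allele_frequencies()
    thresholds = _stage("calibration")(likelihood.calibrate_thresholds)(
        freqs, config.calibration
    )
    if write:
        (out / "thresholds.txt").write_text(thresholds.report())
    logger.info(
        "calibration: LOD_p > %.3f, LOD_pp > %.3f",
        thresholds.lod_p_strict, thresholds.lod_pp_strict,
    )

    lik = _stage("likelihood_duos")(likelihood.cervus_duo_search)(
        g, freqs, thresholds, max_mismatch=config.max_mismatch
    )
    save(lik, "duos_likelihood.csv")
    logger.info("likelihood_duos: %d pairs scored, %d pass", len(lik),
                int(lik["passes"].sum()))

    audit = _stage("consensus")(trios.intersect_duos)(kin, lik)
    save(audit, "duos_consensus.csv")
    counts_series = trios.duo_counts(audit)
    if write:
        counts_series.rename_axis("id").reset_index().to_csv(
            out / "duo_counts.csv", index=False
        )
    n_consensus = int(audit["consensus"].sum())
    logger.info("consensus: %d duos validated by both approaches", n_consensus)

    duos_u = union_duos(kin, lik)
    cand = _stage("trio_candidates")(likelihood.trio_search)(
        g, freqs, thresholds, duos_u, max_mismatch=config.max_mismatch
    )
    save(cand, "trios_candidates.csv")
    logger.info("trio_candidates: %d scored, %d pass", len(cand),
                int(cand["passes"].sum()) if len(cand) else 0)

    selection = _stage("robust_selection")(trios.select_robust_trios)(
        cand, audit, metadata, max_supported_pairs=config.max_supported_pairs
    )
    save(selection.trios, "trios_robust.csv")
    save(selection.excluded, "trios_excluded.csv")
    save(selection.conflicts, "trios_conflicts.csv")
    logger.info("robust_selection: %d robust trios, %d offspring excluded",
                len(selection.trios), len(selection.excluded))

    anns, deductions = _stage("biology")(biology.deduce_attributes)(
        selection.trios, metadata
    )
    save(biology.annotations_frame(anns), "trio_annotations.csv")
    save(deductions, "deductions.csv")
    meta_clustered = metadata
    if metadata is not None:
        meta_clustered = _stage("biology")(biology.assign_clusters)(
            metadata, config.q_threshold
        )
        save(meta_clustered, "metadata_clusters.csv")
        crosstab = _stage("biology")(biology.duo_cluster_crosstab)(
            audit, metadata, config.q_threshold
        )
        if write:
            crosstab.to_csv(out / "duo_cluster_crosstab.csv")
    logger.info("biology: %d trios annotated, %d deductions", len(anns),
                len(deductions))

    graph = _stage("network")(network.build_network)(
        selection.trios, meta_clustered
    )
    ranking = _stage("network")(network.founder_ranking)(graph, audit)
    if write:
        network.export_network(graph, out / "network.graphml")
        network.export_network(graph, out / "network_edges.csv")
        network.export_network(graph, out / "network.dot")
    save(ranking, "founder_ranking.csv")
    comp = network.component_summary(graph)
    logger.info("network: %d nodes, %d edges, main component %d",
                graph.number_of_nodes(), graph.number_of_edges(),
                comp["main_component_size"])

    counts = {
        "n_individuals": g.n_individuals,
        "n_loci": g.n_loci,
        "n_kinship_duos": int(kin["passes"].sum()),
        "n_likelihood_duos": int(lik["passes"].sum()),
        "n_consensus_duos": n_consensus,
        "n_trio_candidates_passing": int(cand["passes"].sum()) if len(cand) else 0,
        "n_robust_trios": len(selection.trios),
        "n_excluded_offspring": len(selection.excluded),
        "lod_p_strict": thresholds.lod_p_strict,
        "lod_pp_strict": thresholds.lod_pp_strict,
        **comp,
    }
    if write:
        with open(out / "report.json", "w") as fh:
            json.dump(counts, fh, indent=2)

    return PipelineResult(
        genotypes=g, metadata=meta_clustered, truth=truth, stats=stats,
        kinship_duos=kin, thresholds=thresholds, likelihood_duos=lik,
        duo_audit=audit, trio_candidates=cand, selection=selection,
        annotations=anns, deductions=deductions, graph=graph, ranking=ranking,
        counts=counts,
    )


def run_sensitivity(
    config: PipelineConfig,
    result: PipelineResult,
    validation: dict[str, tuple[str | None, str | None]],
    out_dir: str | Path | None = None,
    write: bool = True,
) -> pd.DataFrame:
    """Sensitivity scenarios 1-3 for validation offspring, using the state
    of a completed pipeline run."""
    duos_u = union_duos(result.kinship_duos, result.likelihood_duos)
    report = trios.sensitivity_scenarios(
        result.genotypes,
        result.genotypes.allele_frequencies(),
        result.thresholds,
        duos_u,
        result.duo_audit,
        result.metadata,
        validation,
        max_mismatch=config.max_mismatch,
        max_supported_pairs=config.max_supported_pairs,
    )
    if write:
        out = Path(out_dir if out_dir is not None else config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "sensitivity.csv", index=False)
    return report


def validation_map_from_truth(truth: pd.DataFrame) -> dict:
    """Known (mother, father) for validation seedlings in a truth table."""
    val = truth[truth["id"].astype(str).str.startswith("VAL")]
    return {
        r["id"]: (r["mother"], r["father"]) for _, r in val.iterrows()
    }
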