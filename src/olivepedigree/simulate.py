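"""Synthetic cultivar-panel generator with known truth.

Generates founder genotypes under Hardy-Weinberg equilibrium, multi-generation
pedigrees whose crosses respect the diallelic self-incompatibility system
(G1 x G2 only) and exclude andro-sterile pollen donors, maternal chlorotype
inheritance with cytoplasmic male sterility co-segregating with one chlorotype
lineage, and per-call genotyping noise (missing calls and mistyped calls).
Every run emits complete truth tables so downstream parentage inference can be
scored against the planted pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .containers import REGIONS, GenotypeMatrix

TRUTH_COLUMNS = [
    "id", "mother", "father", "generation",
    "chlorotype", "si_group", "andro_sterile", "open_pollination",
]

_REGION_CLUSTER = {"EM": 0, "CM": 1, "WM": 2}  # region -> dominant Q component


class SimulationError(RuntimeError):
    """Raised when the pedigree constraints cannot be satisfied."""


@dataclass
class SyntheticDataset:
    """A simulated panel: noisy genotypes plus full truth tables."""

    genotypes: GenotypeMatrix          # observed (noisy) matrix
    clean: GenotypeMatrix              # error-free matrix
    truth: pd.DataFrame                # TRUTH_COLUMNS, one row per individual
    metadata: pd.DataFrame             # cultivar metadata (id, region, ...)
    error_mask: np.ndarray             # cells where a mistyping was applied
    missing_mask: np.ndarray           # cells set to missing
    allele_freqs: np.ndarray           # founding allele frequencies per locus
    config: SimulationConfig

    @property
    def validation_ids(self) -> list[str]:
        return [s for s in self.truth["id"] if s.startswith("VAL")]


def _draw_allele_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Reference-allele frequency per locus from the configured MAF spectrum."""
    spec = config.maf_spectrum
    if spec.kind == "fixed":
        maf = np.full(config.n_loci, spec.lo)
    else:
        maf = rng.uniform(spec.lo, spec.hi, size=config.n_loci)
    # Randomly let the reference allele be the minor or the major one.
    flip = rng.random(config.n_loci) < 0.5
    return np.where(flip, maf, 1.0 - maf)


def _founder_q(regions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet Q-vectors concentrated on the region-matched cluster."""
    q = np.empty((len(regions), 3))
    for k, region in enumerate(regions):
        alpha = np.ones(3) * 1.5
        alpha[_REGION_CLUSTER[region]] = 12.0
        q[k] = rng.dirichlet(alpha)
    return q


def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw founder genotypes and metadata.

    Returns ``(genotypes, truth, metadata, allele_freqs)``; genotypes are
    noise-free Hardy-Weinberg draws at per-locus frequencies from the
    configured MAF spectrum.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    p = _draw_allele_freqs(config, rng)
    n = config.n_founders
    ids = [f"F{k:04d}" for k in range(1, n + 1)]
    loci = [f"SNP{j:03d}" for j in range(1, config.n_loci + 1)]
    data = rng.binomial(2, p[None, :], size=(n, config.n_loci)).astype(np.int8)
    g = GenotypeMatrix(ids, loci, data)

    si = np.where(rng.random(n) < config.si_group_assignment, "G1", "G2")
    labels = list(config.chlorotype_labels)
    freqs = np.array([config.chlorotype_labels[l] for l in labels])
    chloro = rng.choice(labels, size=n, p=freqs)
    sterile = chloro == config.cms_chlorotype
    regions = rng.choice(REGIONS, size=n)
    q = _founder_q(regions, rng)

    truth = pd.DataFrame({
        "id": ids, "mother": None, "father": None, "generation": 0,
        "chlorotype": chloro, "si_group": si, "andro_sterile": sterile,
        "open_pollination": False,
    })
    metadata = pd.DataFrame({
        "id": ids, "region": regions, "chlorotype": chloro, "si_group": si,
        "andro_sterile": sterile,
        "q_A": q[:, 0], "q_B": q[:, 1], "q_C": q[:, 2],
    })
    return g, truth, metadata, p


def _mendelian_offspring(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One random allele per parent per locus (dosages in {0,1,2})."""
    a = rng.random(mother.shape) < mother / 2.0
    b = rng.random(father.shape) < father / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


def _pick_cross(
    truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[str, str]:
    """Sample a compatible (mother, father) pair from the current panel.

    Mothers may be any individual; fathers must be male-fertile and belong to
    the SI group opposite the mother's.
    """
    ids = truth["id"].to_numpy()
    si = truth["si_group"].to_numpy()
    sterile = truth["andro_sterile"].to_numpy(dtype=bool)
    candidates_mother = rng.permutation(len(ids))
    for mi in candidates_mother:
        other = "G2" if si[mi] == "G1" else "G1"
        fathers = np.flatnonzero((si == other) & ~sterile)
        fathers = fathers[fathers != mi]
        if fathers.size:
            return ids[mi], ids[rng.choice(fathers)]
    raise SimulationError(
        "no compatible parent pair: crosses require opposite SI groups "
        "(G1 x G2) and a male-fertile (non andro-sterile) father"
    )


def simulate_pedigree(
    founders: GenotypeMatrix,
    founder_truth: pd.DataFrame,
    founder_metadata: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    allele_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Breed ``n_generations`` of SI-constrained crosses on top of founders.

    Offspring genotypes are Mendelian draws from the parents' noise-free
    genotypes; chlorotype (and hence andro-sterility) follows the mother; the
    SI group of an offspring is drawn uniformly, since only parental
    complementarity is consumed downstream. With probability
    ``open_pollination_fraction`` a cross uses an external pollen donor drawn
    from Hardy-Weinberg (recorded with father=None in the truth table).

    Returns the combined ``(genotypes, truth, metadata)`` for founders plus
    all offspring.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if not (founder_truth["si_group"] == "G1").any() or not (
        founder_truth["si_group"] == "G2"
    ).any():
        raise SimulationError("founders must include both SI groups")
    if allele_freqs is None:
        allele_freqs = founders.allele_frequencies()

    data = [founders.data]
    ids = list(founders.ids)
    truth_rows = [founder_truth.copy()]
    meta_rows = [founder_metadata.copy()]
    geno_of = {s: founders.data[k] for k, s in enumerate(founders.ids)}
    meta_of = founder_metadata.set_index("id")
    truth_all = founder_truth.copy()

    counter = 0
    for gen in range(1, config.n_generations + 1):
        new_rows, new_meta, new_genos = [], [], []
        for _ in range(config.crosses_per_generation):
            mother_id, father_id = _pick_cross(truth_all, rng)
            external = rng.random() < config.open_pollination_fraction
            mg = geno_of[mother_id]
            if external:
                fg = rng.binomial(2, allele_freqs).astype(np.int8)
                father_rec = None
            else:
                fg = geno_of[father_id]
                father_rec = father_id
            mom_meta = meta_of.loc[mother_id]
            if father_rec is None:
                q = (mom_meta[["q_A", "q_B", "q_C"]].to_numpy(dtype=float)
                     + np.ones(3) / 3.0) / 2.0
            else:
                dad_meta = meta_of.loc[father_id]
                q = (mom_meta[["q_A", "q_B", "q_C"]].to_numpy(dtype=float)
                     + dad_meta[["q_A", "q_B", "q_C"]].to_numpy(dtype=float)) / 2.0
            for _ in range(config.offspring_per_cross):
                counter += 1
                child = f"G{gen}_{counter:04d}"
                cg = _mendelian_offspring(mg, fg, rng)
                chloro = mom_meta["chlorotype"]
                sterile = chloro == config.cms_chlorotype
                si = "G1" if rng.random() < 0.5 else "G2"
                new_rows.append({
                    "id": child, "mother": mother_id, "father": father_rec,
                    "generation": gen, "chlorotype": chloro, "si_group": si,
                    "andro_sterile": sterile, "open_pollination": external,
                })
                new_meta.append({
                    "id": child, "region": mom_meta["region"],
                    "chlorotype": chloro, "si_group": si,
                    "andro_sterile": sterile,
                    "q_A": q[0], "q_B": q[1], "q_C": q[2],
                })
                new_genos.append(cg)
                geno_of[child] = cg
                ids.append(child)
        gen_truth = pd.DataFrame(new_rows)
        gen_meta = pd.DataFrame(new_meta)
        truth_rows.append(gen_truth)
        meta_rows.append(gen_meta)
        data.append(np.vstack(new_genos))
        truth_all = pd.concat([truth_all, gen_truth], ignore_index=True)
        meta_of = pd.concat([meta_of, gen_meta.set_index("id")])

    g = GenotypeMatrix(ids, list(founders.loci), np.vstack(data))
    truth = pd.concat(truth_rows, ignore_index=True)[TRUTH_COLUMNS]
    metadata = pd.concat(meta_rows, ignore_index=True)
    return g, truth, metadata


def add_validation_seedlings(
    g: GenotypeMatrix,
    truth: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    n_seedlings: int = 13,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Append validation seedlings bred from known compatible parent pairs.

    Emulates breeding-program controls: ``n_seedlings - 1`` seedlings from
    fully documented crosses plus one from an open-pollination cross whose
    pollen donor is nevertheless present in the panel (so full-pipeline
    recovery remains possible). Truth rows carry the real parents; the
    ``open_pollination`` flag marks the seedling whose father was undocumented.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    founders = truth[truth["generation"] == 0]
    rows, metas, genos, ids = [], [], [], []
    for k in range(1, n_seedlings + 1):
        mother_id, father_id = _pick_cross(founders, rng)
        sid = f"VAL{k:02d}"
        cg = _mendelian_offspring(g.row(mother_id), g.row(father_id), rng)
        mom = metadata.set_index("id").loc[mother_id]
        chloro = mom["chlorotype"]
        rows.append({
            "id": sid, "mother": mother_id, "father": father_id,
            "generation": int(truth["generation"].max()) + 1,
            "chlorotype": chloro, "si_group": "G1" if rng.random() < 0.5 else "G2",
            "andro_sterile": chloro == config.cms_chlorotype,
            "open_pollination": k == n_seedlings,
        })
        metas.append({
            "id": sid, "region": mom["region"], "chlorotype": chloro,
            "si_group": rows[-1]["si_group"],
            "andro_sterile": rows[-1]["andro_sterile"],
            "q_A": np.nan, "q_B": np.nan, "q_C": np.nan,
        })
        genos.append(cg)
        ids.append(sid)
    g2 = GenotypeMatrix(
        list(g.ids) + ids, list(g.loci), np.vstack([g.data, np.vstack(genos)])
    )
    truth2 = pd.concat([truth, pd.DataFrame(rows)], ignore_index=True)
    meta2 = pd.concat([metadata, pd.DataFrame(metas)], ignore_index=True)
    return g2, truth2, meta2


def apply_noise(
    clean: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    allele_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Apply missingness and genotyping error to a clean matrix.

    Each call is independently set to missing with ``missing_rate``; each
    surviving call is, with probability ``error_rate``, replaced by a random
    genotype drawn from the locus's Hardy-Weinberg frequencies (the same error
    model the likelihood engine assumes). Returns
    ``(noisy, error_mask, missing_mask)`` where ``error_mask`` marks every
    cell a redraw was applied to, whether or not the redraw coincided with the
    original call.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    if allele_freqs is None:
        allele_freqs = clean.allele_frequencies()
    p = np.nan_to_num(allele_freqs, nan=0.5)

    missing_mask = rng.random(clean.data.shape) < config.missing_rate
    error_mask = (rng.random(clean.data.shape) < config.error_rate) & ~missing_mask
    redraws = rng.binomial(2, p[None, :], size=clean.data.shape).astype(np.int8)

    noisy = clean.data.copy()
    noisy[error_mask] = redraws[error_mask]
    noisy[missing_mask] = -1
    return (
        GenotypeMatrix(list(clean.ids), list(clean.loci), noisy),
        error_mask,
        missing_mask,
    )


def simulate_dataset(
    config: SimulationConfig, n_validation: int = 0
) -> SyntheticDataset:
    """Full generator: founders -> pedigree -> validation seedlings -> noise."""
    rng = np.random.default_rng(config.seed)
    founders, ftruth, fmeta, p = simulate_founders(config, rng)
    g, truth, metadata = simulate_pedigree(
        founders, ftruth, fmeta, config, rng, allele_freqs=p
    )
    if n_validation:
        g, truth, metadata = add_validation_seedlings(
            g, truth, metadata, config, n_seedlings=n_validation, rng=rng
        )
    noisy, err, miss = apply_noise(g, config, rng, allele_freqs=p)
    return SyntheticDataset(
        genotypes=noisy, clean=g, truth=truth, metadata=metadata,
        error_mask=err, missing_mask=miss, allele_freqs=p, config=config,
    )
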