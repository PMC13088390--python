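"""Likelihood-based parentage: transition probabilities, LOD scores, and
simulation-based confidence calibration.

The parentage hypothesis is scored against unrelatedness with a summed
log-likelihood ratio (LOD) over jointly typed loci. Per locus, the related
likelihood is the probability of the observed offspring genotype given the
observed genotype(s) of the candidate parent(s) under Mendelian transmission
(the untransmitted allele drawn from population frequencies in the
single-parent case); the unrelated likelihood is the Hardy-Weinberg
probability of the observed offspring genotype. Genotyping error is modelled
per individual: with probability ``e`` the observed genotype is an
independent Hardy-Weinberg draw, else the true genotype. This keeps every
likelihood finite and regularizes Mendelian-impossible configurations.

Confidence thresholds are calibrated by Monte-Carlo simulation of parentage
analysis: simulated offspring are scored against candidate sets in which
each true parent is present with a set probability, and the strict LOD cutoff
is the lowest value such that at least 95% of assignments strictly above it
identify a true parent (pair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CalibrationSettings, ConfigurationError
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9  # frequency clip for uninformative-locus handling


class DegenerateFrequencyError(ValueError):
    """Raised when an allele frequency of 0 or 1 is used in a likelihood."""


@dataclass
class ErrorModel:
    """Per-genotype mistyping probability."""

    e: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.e < 1.0):
            raise ConfigurationError(f"error rate e={self.e} outside [0, 1)")


@dataclass
class LodResult:
    """LOD score of one duo or trio."""

    offspring: str
    parent: str
    parent_b: str | None
    lod: float
    n_loci_compared: int
    n_mismatch: int
    confidence: str  # strict | none | uncalibrated


@dataclass
class ThresholdSet:
    """Calibrated strict LOD cutoffs with the settings that produced them."""

    lod_p_strict: float
    lod_pp_strict: float
    settings: CalibrationSettings
    seed: int
    duo_success_rate: float = float("nan")
    trio_success_rate: float = float("nan")
    quality: dict = field(default_factory=dict)

    def report(self) -> str:
        s = self.settings
        lines = [
            "[calibration]",
            f"seed = {self.seed}",
            f"n_offspring = {s.n_offspring}",
            f"n_candidate_parents = {s.n_candidate_parents}",
            f"prop_sampled = {s.prop_sampled}",
            f"prop_loci_typed = {s.prop_loci_typed}",
            f"error_rate = {s.error_rate}",
            f"confidence = {s.confidence}",
            "[thresholds]",
            f"lod_p_strict = {self.lod_p_strict:.6f}",
            f"lod_pp_strict = {self.lod_pp_strict:.6f}",
            f"duo_success_rate = {self.duo_success_rate:.4f}",
            f"trio_success_rate = {self.trio_success_rate:.4f}",
        ]
        for k, v in self.quality.items():
            lines.append(f"quality.{k} = {v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Per-locus probability machinery


def _hwe(p: np.ndarray) -> np.ndarray:
    """Genotype frequencies [q^2, 2pq, p^2], shape (..., 3)."""
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def _mendel_single(p: np.ndarray) -> np.ndarray:
    """P(true offspring | true parent), untransmitted allele from HWE.

    Shape (L, 3, 3) indexed [locus, parent, offspring].
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    t = np.array([0.0, 0.5, 1.0])  # P(transmit ref | parent dosage)
    out = np.empty(p.shape + (3, 3))
    out[..., :, 0] = (1.0 - t)[None, :] * q[..., None]
    out[..., :, 2] = t[None, :] * p[..., None]
    out[..., :, 1] = t[None, :] * q[..., None] + (1.0 - t)[None, :] * p[..., None]
    return out


_T = np.array([0.0, 0.5, 1.0])
#: P(true offspring | true parents), shape (3, 3, 3) [pa, pb, offspring];
#: purely Mendelian, frequency-free.
MENDEL_PAIR = np.empty((3, 3, 3))
MENDEL_PAIR[:, :, 0] = np.outer(1 - _T, 1 - _T)
MENDEL_PAIR[:, :, 2] = np.outer(_T, _T)
MENDEL_PAIR[:, :, 1] = 1.0 - MENDEL_PAIR[:, :, 0] - MENDEL_PAIR[:, :, 2]

#: Duo Mendelian impossibility at e=0: opposite homozygotes.
DUO_MISMATCH = np.zeros((3, 3), dtype=bool)
DUO_MISMATCH[0, 2] = DUO_MISMATCH[2, 0] = True

#: Trio Mendelian impossibility at e=0 (offspring impossible given the pair).
TRIO_MISMATCH = MENDEL_PAIR == 0.0


def _error_matrix(p: np.ndarray, e: float) -> np.ndarray:
    """P(observed | true) per locus, shape (L, 3, 3) [locus, true, obs]."""
    f = _hwe(p)
    eye = np.eye(3)
    return (1.0 - e) * eye[None, :, :] + e * f[:, None, :]


def _posterior_true(p: np.ndarray, e: float) -> np.ndarray:
    """P(true | observed) per locus, shape (L, 3, 3) [locus, obs, true].

    Marginal P(observed) equals HWE for every e, so the posterior is
    E[t, g] * f[t] / f[g] transposed to [g, t].
    """
    f = _hwe(p)
    E = _error_matrix(p, e)
    joint = E * f[:, :, None]          # [l, t, g]
    return np.swapaxes(joint, 1, 2) / f[:, None, :].swapaxes(1, 2)


class TransitionTables:
    """Precomputed per-locus LOD, mismatch, and comparability tables.

    Genotypes are encoded on 4 states (0, 1, 2 dosage; 3 = missing). Missing
    states contribute zero LOD, zero mismatch, and are not counted as
    compared. Loci with degenerate (0/1) or undefined allele frequencies are
    uninformative: their LOD contribution is zero, but Mendelian-impossible
    configurations at such loci still count as mismatches.
    """

    def __init__(self, freqs: np.ndarray, model: ErrorModel):
        p = np.asarray(freqs, dtype=float)
        self.n_loci = p.size
        self.model = model
        informative = np.isfinite(p) & (p > 0.0) & (p < 1.0)
        self.informative = informative
        pc = np.clip(np.nan_to_num(p, nan=0.5), _EPS, 1.0 - _EPS)

        f = _hwe(pc)
        post = _posterior_true(pc, model.e)          # [l, g_obs, t]
        E = _error_matrix(pc, model.e)               # [l, t, g_obs]
        m1 = _mendel_single(pc)                      # [l, t_p, t_o]

        # Observed-level duo transition: [l, g_p, g_o]
        t1 = np.einsum("lpt,lto,loq->lpq", post, m1, E)
        with np.errstate(divide="ignore"):
            duo = np.log(t1 / f[:, None, :])
        duo[~informative] = 0.0

        # Observed-level trio transition: [l, g_a, g_b, g_o]
        t2 = np.einsum("lat,lbu,tuo,loq->labq", post, post, MENDEL_PAIR, E)
        with np.errstate(divide="ignore"):
            trio = np.log(t2 / f[:, None, None, :])
        trio[~informative] = 0.0

        # Embed into 4-state tables (state 3 = missing -> zero everywhere).
        self.duo_lod = np.zeros((self.n_loci, 4, 4))
        self.duo_lod[:, :3, :3] = duo
        self.trio_lod = np.zeros((self.n_loci, 4, 4, 4))
        self.trio_lod[:, :3, :3, :3] = trio

        self.duo_mismatch = np.zeros((self.n_loci, 4, 4))
        self.duo_mismatch[:, :3, :3] = DUO_MISMATCH[None, :, :]
        self.trio_mismatch = np.zeros((self.n_loci, 4, 4, 4))
        self.trio_mismatch[:, :3, :3, :3] = TRIO_MISMATCH[None, :, :, :]

        self.duo_compared = np.zeros((self.n_loci, 4, 4))
        self.duo_compared[:, :3, :3] = 1.0
        self.trio_compared = np.zeros((self.n_loci, 4, 4, 4))
        self.trio_compared[:, :3, :3, :3] = 1.0

        self._arange = np.arange(self.n_loci)

    # -- scoring helpers ----------------------------------------------------

    def duo_scores(self, ga: np.ndarray, gb: np.ndarray):
        """LOD, mismatch count, compared count for one (parent, offspring)."""
        idx = (self._arange, ga, gb)
        return (
            float(self.duo_lod[idx].sum()),
            int(self.duo_mismatch[idx].sum()),
            int(self.duo_compared[idx].sum()),
        )

    def trio_scores(self, ga: np.ndarray, gb: np.ndarray, go: np.ndarray):
        idx = (self._arange, ga, gb, go)
        return (
            float(self.trio_lod[idx].sum()),
            int(self.trio_mismatch[idx].sum()),
            int(self.trio_compared[idx].sum()),
        )

    def duo_matrix(self, G: np.ndarray, H: np.ndarray | None = None):
        """All-pairs duo LOD/mismatch/compared between row sets G and H.

        ``G``, ``H`` are 4-state encoded (n, L) arrays; returns three
        (len(G), len(H)) matrices. The duo LOD is symmetric in the two roles.
        """
        if H is None:
            H = G
        Xg = _one_hot(G)
        Xh = _one_hot(H)

        def contract(tab):
            y = np.einsum("lpq,nlq->nlp", tab, Xg)
            return np.einsum("nlp,mlp->nm", y, Xh)

        return (
            contract(np.swapaxes(self.duo_lod, 1, 2)),
            contract(np.swapaxes(self.duo_mismatch, 1, 2)),
            contract(np.swapaxes(self.duo_compared, 1, 2)),
        )


def _one_hot(G: np.ndarray) -> np.ndarray:
    """(n, L) 4-state codes -> (n, L, 4) one-hot floats."""
    n, L = G.shape
    X = np.zeros((n, L, 4))
    np.put_along_axis(X, G[:, :, None].astype(np.intp), 1.0, axis=2)
    return X


def encode(data: np.ndarray) -> np.ndarray:
    """Dosage matrix with -1 missing -> 4-state codes (missing = 3)."""
    return np.where(data < 0, 3, data).astype(np.intp)


# ---------------------------------------------------------------------------
# Public per-call operations


def transition_prob(
    offspring_geno: int,
    parent_geno: int,
    second_parent_geno: int | None = None,
    p: float = 0.5,
    model: ErrorModel | None = None,
) -> float:
    """Probability of the observed offspring genotype given observed parent(s).

    Single-parent: Mendelian transmission from the named parent, the
    untransmitted allele drawn from population frequency ``p``. Pair:
    Mendelian transmission from both parents. Under the error model the
    observed genotypes are, independently with probability ``e``, random
    Hardy-Weinberg draws. The result is a proper conditional distribution:
    it sums to 1 over the three offspring genotypes.
    """
    if model is None:
        model = ErrorModel(0.0)
    if not (0.0 < p < 1.0):
        raise DegenerateFrequencyError(f"allele frequency p={p} is degenerate")
    for gname, gval in (("offspring", offspring_geno), ("parent", parent_geno)):
        if gval not in (0, 1, 2):
            raise ValueError(f"{gname} genotype {gval} not in {{0,1,2}}")
    pv = np.array([p])
    post = _posterior_true(pv, model.e)[0]
    E = _error_matrix(pv, model.e)[0]
    if second_parent_geno is None:
        m1 = _mendel_single(pv)[0]
        t1 = np.einsum("t,to,oq->q", post[parent_geno], m1, E)
        return float(t1[offspring_geno])
    if second_parent_geno not in (0, 1, 2):
        raise ValueError(f"second parent genotype {second_parent_geno} not in {{0,1,2}}")
    t2 = np.einsum(
        "t,u,tuo,oq->q", post[parent_geno], post[second_parent_geno], MENDEL_PAIR, E
    )
    return float(t2[offspring_geno])


def _confidence(lod: float, threshold: float | None) -> str:
    if threshold is None:
        return "uncalibrated"
    return "strict" if lod > threshold else "none"


def duo_lod(
    g: GenotypeMatrix,
    freqs: np.ndarray,
    offspring: str,
    candidate: str,
    model: ErrorModel | None = None,
    thresholds: ThresholdSet | None = None,
    tables: TransitionTables | None = None,
) -> LodResult:
    """Single-parent LOD for one (offspring, candidate parent) duo."""
    if offspring == candidate:
        raise ValueError(f"self-comparison rejected: {offspring!r}")
    if tables is None:
        tables = TransitionTables(freqs, model or ErrorModel())
    go = encode(g.row(offspring)[None, :])[0]
    gp = encode(g.row(candidate)[None, :])[0]
    lod, mism, comp = tables.duo_scores(gp, go)
    thr = thresholds.lod_p_strict if thresholds else None
    return LodResult(offspring, candidate, None, lod, comp, mism, _confidence(lod, thr))


def trio_lod(
    g: GenotypeMatrix,
    freqs: np.ndarray,
    offspring: str,
    parent_a: str,
    parent_b: str,
    model: ErrorModel | None = None,
    thresholds: ThresholdSet | None = None,
    tables: TransitionTables | None = None,
) -> LodResult:
    """Parent-pair LOD for one (offspring, parentA, parentB) trio."""
    if offspring in (parent_a, parent_b) or parent_a == parent_b:
        raise ValueError("offspring and the two parents must be distinct")
    if tables is None:
        tables = TransitionTables(freqs, model or ErrorModel())
    go = encode(g.row(offspring)[None, :])[0]
    ga = encode(g.row(parent_a)[None, :])[0]
    gb = encode(g.row(parent_b)[None, :])[0]
    lod, mism, comp = tables.trio_scores(ga, gb, go)
    thr = thresholds.lod_pp_strict if thresholds else None
    return LodResult(
        offspring, parent_a, parent_b, lod, comp, mism, _confidence(lod, thr)
    )


# ---------------------------------------------------------------------------
# Searches


def cervus_duo_search(
    g: GenotypeMatrix,
    freqs: np.ndarray,
    thresholds: ThresholdSet,
    model: ErrorModel | None = None,
    max_mismatch: int = 2,
) -> pd.DataFrame:
    """Likelihood-approach duo table over all unordered pairs.

    A pair passes when its duo LOD exceeds the calibrated strict cutoff and
    at most ``max_mismatch`` loci are Mendelian-incompatible (opposite
    homozygotes). The duo LOD is role-symmetric, so unordered pairs suffice.
    """
    if model is None:
        model = ErrorModel(thresholds.settings.error_rate)
    tables = TransitionTables(freqs, model)
    G = encode(g.data)
    lod, mism, comp = tables.duo_matrix(G)
    iu, ju = np.triu_indices(g.n_individuals, k=1)
    ids = np.asarray(g.ids)
    table = pd.DataFrame({
        "id_a": ids[iu],
        "id_b": ids[ju],
        "n_compared": comp[iu, ju].round().astype(int),
        "n_mismatch": mism[iu, ju].round().astype(int),
        "lod": lod[iu, ju],
        "method": "likelihood",
    })
    table["passes"] = (
        (table["lod"] > thresholds.lod_p_strict)
        & (table["n_mismatch"] <= max_mismatch)
    )
    return table


def trio_search(
    g: GenotypeMatrix,
    freqs: np.ndarray,
    thresholds: ThresholdSet,
    duos: pd.DataFrame,
    model: ErrorModel | None = None,
    max_mismatch: int = 2,
    excluded_parents: dict[str, set] | None = None,
    offspring_ids: list[str] | None = None,
    top_m: int = 20,
) -> pd.DataFrame:
    """Score candidate parent pairs for every offspring with duo support.

    The pair search runs over the individuals inferred in at least one
    passing duo (either approach): every such individual is an eligible
    candidate parent for every duo-supported offspring. For tractability the
    pairs actually scored for an offspring are those among its ``top_m``
    candidates by single-parent LOD; relatives dominate that ranking, so the
    pruning does not lose plausible pairs. Pairs pass when LOD_pp exceeds
    the strict cutoff and at most ``max_mismatch`` loci are
    Mendelian-impossible under the pair. ``excluded_parents`` removes named
    candidates per offspring (sensitivity scenarios).

    Returns all scored trios with a ``passes`` flag; downstream selection
    keeps at most one robust trio per offspring.
    """
    if model is None:
        model = ErrorModel(thresholds.settings.error_rate)
    tables = TransitionTables(freqs, model)
    G = encode(g.data)

    members: set[str] = set()
    sup = duos[duos["passes"]]
    for a, b in zip(sup["id_a"], sup["id_b"]):
        members.add(a)
        members.add(b)
    pool = sorted(m for m in members if m in g._index)
    pool_idx = np.array([g.index_of(c) for c in pool], dtype=int)

    rows = []
    arange = tables._arange
    offspring_set = offspring_ids if offspring_ids is not None else g.ids
    for offspring in offspring_set:
        if offspring not in members or offspring not in g._index:
            continue
        cand = pool
        cidx = pool_idx
        drop = {offspring}
        if excluded_parents and offspring in excluded_parents:
            drop |= set(excluded_parents[offspring])
        keep = [k for k, c in enumerate(cand) if c not in drop]
        cand = [cand[k] for k in keep]
        cidx = cidx[keep]
        if len(cand) < 2:
            continue
        go = G[g.index_of(offspring)]
        if len(cand) > top_m:
            duo_lods = tables.duo_lod[arange[None, :], G[cidx], go[None, :]].sum(axis=1)
            order = np.argsort(-duo_lods, kind="stable")[:top_m]
            order = np.sort(order)
            cand = [cand[k] for k in order]
            cidx = cidx[order]
        sub = tables.trio_lod[arange, :, :, go]        # (L, 4, 4)
        sub_m = tables.trio_mismatch[arange, :, :, go]
        sub_c = tables.trio_compared[arange, :, :, go]
        ia, ib = np.triu_indices(len(cand), k=1)
        gA = G[cidx[ia]]                                # (P, L)
        gB = G[cidx[ib]]
        lods = sub[arange[None, :], gA, gB].sum(axis=1)
        misms = sub_m[arange[None, :], gA, gB].sum(axis=1)
        comps = sub_c[arange[None, :], gA, gB].sum(axis=1)
        for k in range(len(ia)):
            rows.append((
                offspring, cand[ia[k]], cand[ib[k]],
                float(lods[k]), int(round(comps[k])), int(round(misms[k])),
            ))
    table = pd.DataFrame(
        rows,
        columns=["offspring", "parent_a", "parent_b", "lod_pp", "n_compared",
                 "n_mismatch"],
    )
    if table.empty:
        table["passes"] = pd.Series(dtype=bool)
        table["confidence"] = pd.Series(dtype=object)
        return table
    table["passes"] = (
        (table["lod_pp"] > thresholds.lod_pp_strict)
        & (table["n_mismatch"] <= max_mismatch)
    )
    table["confidence"] = np.where(table["passes"], "strict", "none")
    return table


# ---------------------------------------------------------------------------
# Confidence calibration


def _strict_threshold(scores: np.ndarray, correct: np.ndarray, confidence: float):
    """Lowest cutoff with >= ``confidence`` purity strictly above it.

    Scans the assignments sorted by score and returns the most permissive
    cutoff whose exceeding set is at least ``confidence`` correct, together
    with the fraction of assignments retained.
    """
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    c = correct[order].astype(float)
    purity = np.cumsum(c) / np.arange(1, len(c) + 1)
    ok = np.flatnonzero(purity >= confidence)
    if ok.size == 0:
        return float(s[0]), 0.0, False
    k = int(ok[-1])  # 0-based index of last admissible rank
    if k == len(s) - 1:
        thr = float(s[-1]) - 1.0
    elif s[k + 1] < s[k]:
        thr = float(0.5 * (s[k] + s[k + 1]))
    else:
        thr = float(np.nextafter(s[k], -np.inf))
    return thr, (k + 1) / len(s), True


def _observe(true_g: np.ndarray, p: np.ndarray, settings: CalibrationSettings,
             rng: np.random.Generator) -> np.ndarray:
    """Apply typing rate and mistyping to true genotypes; 4-state codes."""
    shape = true_g.shape
    obs = true_g.copy()
    err = rng.random(shape) < settings.error_rate
    redraw = _sample_hwe(p, shape[0], rng)
    obs[err] = redraw[err]
    untyped = rng.random(shape) >= settings.prop_loci_typed
    obs[untyped] = 3
    return obs


def _sample_hwe(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.binomial(2, p[None, :], size=(n, p.size)).astype(np.intp)


def _mendel_draw(m: np.ndarray, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random(m.shape) < m / 2.0).astype(np.intp)
    b = (rng.random(f.shape) < f / 2.0).astype(np.intp)
    return a + b


def calibrate_thresholds(
    freqs: np.ndarray,
    settings: CalibrationSettings | None = None,
    seed: int | None = None,
) -> ThresholdSet:
    """Calibrate strict LOD_p and LOD_pp cutoffs by simulated parentage.

    Families (mother, father, offspring) are simulated at the supplied allele
    frequencies; each parent is present in the candidate set with probability
    ``prop_sampled``, alongside ``n_candidate_parents`` unrelated candidates;
    typing rate and mistyping are applied to everyone. Duo assignments take
    the top-LOD candidate; pair assignments take the top-LOD_pp pair among
    the ``top_m_pair_candidates`` best single-parent candidates. The strict
    cutoffs are the lowest values for which the assignments exceeding them
    are at least 95% correct (configurable confidence).
    """
    if settings is None:
        settings = CalibrationSettings()
    settings.validate()
    if seed is None:
        seed = settings.seed
    rng = np.random.default_rng(seed)

    p = np.asarray(freqs, dtype=float)
    informative = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if informative.sum() < 2:
        raise ConfigurationError("calibration requires >= 2 informative loci")
    p = np.clip(np.nan_to_num(p, nan=0.5), _EPS, 1.0 - _EPS)

    model = ErrorModel(settings.error_rate)
    tables = TransitionTables(p, model)

    B = settings.n_offspring
    nc = settings.n_candidate_parents
    mothers = _sample_hwe(p, B, rng)
    fathers = _sample_hwe(p, B, rng)
    offspring = _mendel_draw(mothers, fathers, rng)
    pool = _sample_hwe(p, nc, rng)

    obs_o = _observe(offspring, p, settings, rng)
    obs_m = _observe(mothers, p, settings, rng)
    obs_f = _observe(fathers, p, settings, rng)
    obs_pool = _observe(pool, p, settings, rng)

    sampled_m = rng.random(B) < settings.prop_sampled
    sampled_f = rng.random(B) < settings.prop_sampled

    # Duo LODs: offspring x pool, plus offspring vs own parents.
    lod_pool, _, _ = tables.duo_matrix(obs_o, obs_pool)   # (B, nc)
    arange = tables._arange
    lod_m = tables.duo_lod[arange[None, :], obs_m, obs_o].sum(axis=1)
    lod_f = tables.duo_lod[arange[None, :], obs_f, obs_o].sum(axis=1)

    neg = -np.inf
    parent_scores = np.stack(
        [np.where(sampled_m, lod_m, neg), np.where(sampled_f, lod_f, neg)], axis=1
    )
    best_parent = parent_scores.max(axis=1)
    best_pool = lod_pool.max(axis=1)
    duo_score = np.maximum(best_parent, best_pool)
    duo_correct = best_parent > best_pool

    lod_p, duo_frac, duo_ok = _strict_threshold(
        duo_score, duo_correct, settings.confidence
    )

    # Trio: top-m single-parent candidates per offspring, all pairs among them.
    m_top = min(settings.top_m_pair_candidates, nc + 2)
    pair_score = np.empty(B)
    pair_correct = np.zeros(B, dtype=bool)
    for b in range(B):
        cand_g = [obs_pool]
        cand_lod = [lod_pool[b]]
        if sampled_m[b]:
            cand_g.append(obs_m[b][None, :])
            cand_lod.append(np.array([lod_m[b]]))
        if sampled_f[b]:
            cand_g.append(obs_f[b][None, :])
            cand_lod.append(np.array([lod_f[b]]))
        Gc = np.vstack(cand_g)
        Lc = np.concatenate(cand_lod)
        true_set = set(range(nc, len(Lc)))  # appended true parents
        top = np.argsort(-Lc, kind="stable")[:m_top]
        sub = tables.trio_lod[arange, :, :, obs_o[b]]   # (L, 4, 4)
        ia, ib = np.triu_indices(len(top), k=1)
        gA = Gc[top[ia]]
        gB = Gc[top[ib]]
        lods = sub[arange[None, :], gA, gB].sum(axis=1)
        kbest = int(np.argmax(lods))
        pair_score[b] = lods[kbest]
        chosen = {int(top[ia[kbest]]), int(top[ib[kbest]])}
        pair_correct[b] = (
            sampled_m[b] and sampled_f[b] and chosen == true_set and len(true_set) == 2
        )

    lod_pp, trio_frac, trio_ok = _strict_threshold(
        pair_score, pair_correct, settings.confidence
    )

    quality = {
        "duo_separable": duo_ok,
        "trio_separable": trio_ok,
        "n_informative_loci": int(informative.sum()),
    }
    if not (duo_ok and trio_ok):
        logger.warning(
            "calibration could not reach %.0f%% confidence; thresholds carry "
            "a quality flag", 100 * settings.confidence,
        )
    ts = ThresholdSet(
        lod_p_strict=lod_p,
        lod_pp_strict=lod_pp,
        settings=settings,
        seed=seed,
        duo_success_rate=duo_frac,
        trio_success_rate=trio_frac,
        quality=quality,
    )
    logger.info(
        "calibrated thresholds: LOD_p > %.3f, LOD_pp > %.3f", lod_p, lod_pp
    )
    return ts
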