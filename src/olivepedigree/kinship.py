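"""Allele-frequency-free duo search via the KING-robust kinship estimator.

For a pair of individuals the estimator uses only heterozygote and
opposite-homozygote counts over jointly typed loci:

    phi = (N_het,het - 2 * N_opp_hom) / (N_het(i) + N_het(j))

A pair is retained as a putative parent-offspring duo when no locus shows
opposite homozygotes (the zero identity-by-state condition, R0 = 0) and phi
falls strictly inside the parent-offspring window (0.177, 0.354).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

DUO_COLUMNS = ["id_a", "id_b", "n_compared", "n_opposite_hom", "phi", "method", "passes"]


@dataclass
class KinshipResult:
    """Pairwise kinship summary for one unordered pair."""

    id_i: str
    id_j: str
    n_compared: int
    n_opposite_hom: int
    phi: float            # NaN when undefined (no shared loci / no hets)
    passes_po_window: bool

    @property
    def r0(self) -> float:
        """Opposite-homozygote fraction over compared loci (NaN if none)."""
        if self.n_compared == 0:
            return float("nan")
        return self.n_opposite_hom / self.n_compared


def _pairwise_counts(g: GenotypeMatrix):
    """Count matrices for all pairs via indicator matrix products."""
    het = (g.data == 1).astype(np.float64)
    hom0 = (g.data == 0).astype(np.float64)
    hom2 = (g.data == 2).astype(np.float64)
    typed = g.typed_mask().astype(np.float64)

    n_hh = het @ het.T                      # loci heterozygous in both
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T   # opposite homozygotes
    het_i = het @ typed.T                   # het loci of i jointly typed with j
    n_cmp = typed @ typed.T
    return n_hh, n_opp, het_i, n_cmp


def pairwise_kinship(g: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust phi and opposite-homozygote counts for all unordered pairs.

    Columns: id_a, id_b, n_compared, n_opposite_hom, phi. ``phi`` is NaN when
    the pair shares no typed loci or neither member is heterozygous at any
    jointly typed locus.
    """
    n_hh, n_opp, het_i, n_cmp = _pairwise_counts(g)
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hh - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    phi[n_cmp == 0] = np.nan

    iu, ju = np.triu_indices(g.n_individuals, k=1)
    ids = np.asarray(g.ids)
    return pd.DataFrame({
        "id_a": ids[iu],
        "id_b": ids[ju],
        "n_compared": n_cmp[iu, ju].astype(int),
        "n_opposite_hom": n_opp[iu, ju].astype(int),
        "phi": phi[iu, ju],
    })


def king_robust(g: GenotypeMatrix, i: str, j: str,
                lo: float = 0.177, hi: float = 0.354) -> KinshipResult:
    """KING-robust kinship for one pair of individuals.

    The estimator is symmetric in (i, j) and uses jointly typed loci only.
    """
    gi, gj = g.row(i), g.row(j)
    both = (gi >= 0) & (gj >= 0)
    n_cmp = int(both.sum())
    n_hh = int(((gi == 1) & (gj == 1) & both).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    denom = int(((gi == 1) & both).sum() + ((gj == 1) & both).sum())
    phi = (n_hh - 2.0 * n_opp) / denom if (denom > 0 and n_cmp > 0) else float("nan")
    passes = bool(n_opp == 0 and np.isfinite(phi) and lo < phi < hi)
    return KinshipResult(i, j, n_cmp, n_opp, phi, passes)


def sambar_duo_search(
    g: GenotypeMatrix,
    lo: float = 0.177,
    hi: float = 0.354,
    min_compared: int = 20,
) -> pd.DataFrame:
    """Kinship-approach duo table over all unordered pairs.

    A pair passes when it has no opposite-homozygous locus, phi lies strictly
    inside ``(lo, hi)``, and at least ``min_compared`` loci were jointly typed
    (pairs below the floor are low-confidence and never pass). The window
    cannot orient the duo; direction is resolved downstream.
    """
    table = pairwise_kinship(g)
    table["method"] = "kinship"
    table["passes"] = (
        (table["n_opposite_hom"] == 0)
        & table["phi"].gt(lo)
        & table["phi"].lt(hi)
        & (table["n_compared"] >= min_compared)
    )
    return table[DUO_COLUMNS]
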