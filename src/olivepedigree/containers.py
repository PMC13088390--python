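"""Core in-memory containers for genotype and metadata tables.

Genotypes are diploid biallelic SNP calls stored as reference-allele dosage
(0, 1, 2) with ``-1`` for missing, in an ``(n_individuals, n_loci)`` int8
array. Individual and locus identifiers are unique strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: Columns of a metadata table; all optional per cultivar (empty -> unknown).
METADATA_COLUMNS = [
    "id",
    "region",
    "chlorotype",
    "si_group",
    "andro_sterile",
    "q_A",
    "q_B",
    "q_C",
]

REGIONS = ("EM", "CM", "WM")
SI_GROUPS = ("G1", "G2")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """N x L dosage matrix with individual and locus identifiers.

    Parameters
    ----------
    ids : list of str
        Unique individual identifiers (rows).
    loci : list of str
        Unique locus identifiers (columns).
    data : ndarray of int8
        Dosages in {0, 1, 2} with -1 marking missing calls.
    """

    ids: list[str]
    loci: list[str]
    data: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValidationError("genotype data must be 2-dimensional")
        n, l = self.data.shape
        if n != len(self.ids) or l != len(self.loci):
            raise ValidationError(
                f"shape {self.data.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.loci)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus ids")
        bad = ~np.isin(self.data, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid dosage {self.data[i, j]} for individual "
                f"{self.ids[i]!r} at locus {self.loci[j]!r}"
            )
        self._index = {s: k for k, s in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual: str) -> np.ndarray:
        """Dosage vector for one individual."""
        try:
            return self.data[self._index[individual]]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def index_of(self, individual: str) -> int:
        try:
            return self._index[individual]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def typed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.data >= 0

    def subset(self, ids: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``ids`` (order preserved)."""
        idx = [self.index_of(s) for s in ids]
        return GenotypeMatrix(list(ids), list(self.loci), self.data[idx].copy())

    def drop_individuals(self, ids) -> "GenotypeMatrix":
        drop = set(ids)
        keep = [s for s in self.ids if s not in drop]
        return self.subset(keep)

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus reference-allele frequency over typed calls (NaN if none)."""
        typed = self.typed_mask()
        dose = np.where(typed, self.data, 0).astype(float)
        n_typed = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = dose.sum(axis=0) / (2.0 * n_typed)
        p[n_typed == 0] = np.nan
        return p

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), list(self.loci), self.data.copy())


def empty_metadata(ids: list[str]) -> pd.DataFrame:
    """Metadata table with every attribute unknown."""
    df = pd.DataFrame({"id": list(ids)})
    for col in METADATA_COLUMNS[1:]:
        df[col] = np.nan
    return df


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check metadata invariants; returns the frame indexed by id.

    Q-vectors, when present, must sum to 1 within 1e-6.
    """
    if "id" not in meta.columns:
        raise ValidationError("metadata requires an 'id' column")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise ValidationError(f"duplicate metadata id {dup!r}")
    qcols = ["q_A", "q_B", "q_C"]
    if all(c in meta.columns for c in qcols):
        q = meta[qcols].astype(float)
        present = q.notna().all(axis=1)
        bad = present & (np.abs(q.sum(axis=1) - 1.0) > 1e-6)
        if bad.any():
            who = meta.loc[bad, "id"].iloc[0]
            raise ValidationError(f"q_vector of {who!r} does not sum to 1")
    return meta.set_index("id", drop=False)
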