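"""Reading and writing genotype matrices, metadata, and marker statistics.

The native genotype format is a CSV with header ``id,<locus1>,<locus2>,...``
and cells ``0|1|2|NA`` (reference-allele dosage). Biallelic SNPs can also be
imported from VCF v4.x (via pysam); multi-allelic records are skipped with a
warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    METADATA_COLUMNS,
    GenotypeMatrix,
    ValidationError,
    validate_metadata,
)

logger = logging.getLogger(__name__)

_CSV_NA = {"", "NA", "NaN", "nan", "na", "."}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF.

    ``format`` is inferred from the file suffix when omitted (``.vcf`` ->
    VCF, otherwise CSV).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unsupported genotype format {format!r}")


def _read_csv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file (line 1)")
        cols = header.split(",")
        if cols[0].strip().lower() != "id":
            raise ParseError(f"{path}: first header column must be 'id' (line 1)")
        loci = [c.strip() for c in cols[1:]]
        ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}: expected {len(cols)} fields, got "
                    f"{len(fields)} (line {lineno})"
                )
            ids.append(fields[0].strip())
            row = []
            for val in fields[1:]:
                val = val.strip()
                if val in _CSV_NA:
                    row.append(-1)
                elif val in ("0", "1", "2"):
                    row.append(int(val))
                else:
                    raise ParseError(
                        f"{path}: invalid dosage {val!r} (line {lineno}); "
                        "cells must be 0, 1, 2 or NA"
                    )
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    try:
        return GenotypeMatrix(ids, loci, np.array(rows, dtype=np.int8))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        ids = list(vcf.header.samples)
        loci: list[str] = []
        rows: list[np.ndarray] = []
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"{path}: skipping non-biallelic record "
                    f"{rec.chrom}:{rec.pos}",
                    stacklevel=2,
                )
                continue
            name = rec.id or f"{rec.chrom}:{rec.pos}"
            col = np.full(len(ids), -1, dtype=np.int8)
            for k, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                # dosage counts the REF allele; unphased and phased alike
                col[k] = sum(1 for a in gt if a == 0)
            loci.append(name)
            rows.append(col)
    if not rows:
        raise ParseError(f"{path}: no biallelic records")
    return GenotypeMatrix(ids, loci, np.column_stack(rows))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the native genotype CSV dialect."""
    with open(path, "w") as fh:
        fh.write("id," + ",".join(g.loci) + "\n")
        for k, ind in enumerate(g.ids):
            cells = ["NA" if v < 0 else str(int(v)) for v in g.data[k]]
            fh.write(ind + "," + ",".join(cells) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cultivar metadata CSV (missing fields allowed)."""
    df = pd.read_csv(path, dtype={"id": str})
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df["andro_sterile"].notna().any():
        df["andro_sterile"] = df["andro_sterile"].map(
            lambda v: v if pd.isna(v) else str(v).strip().lower() in ("true", "1", "yes")
        )
    validate_metadata(df)
    return df[METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    meta[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Marker descriptive statistics


@dataclass
class MarkerStats:
    """Per-locus descriptive statistics, optionally replicated per region.

    ``per_locus`` columns: locus, n_typed, missing_rate, p (reference-allele
    frequency), maf, he (expected heterozygosity), pic (polymorphic
    information content), defined (False when the locus is fully missing).
    """

    per_locus: pd.DataFrame
    per_region: dict[str, pd.DataFrame]

    def means(self) -> dict[str, float]:
        ok = self.per_locus[self.per_locus["defined"]]
        return {
            "mean_maf": float(ok["maf"].mean()),
            "mean_he": float(ok["he"].mean()),
            "mean_pic": float(ok["pic"].mean()),
            "mean_missing_rate": float(self.per_locus["missing_rate"].mean()),
        }


def _locus_table(g: GenotypeMatrix) -> pd.DataFrame:
    typed = g.typed_mask()
    n = g.n_individuals
    n_typed = typed.sum(axis=0)
    dose = np.where(typed, g.data, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dose.sum(axis=0) / (2.0 * n_typed)
    defined = n_typed > 0
    p = np.where(defined, p, np.nan)
    q = 1.0 - p
    he = 2.0 * p * q
    pic = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return pd.DataFrame({
        "locus": g.loci,
        "n_typed": n_typed,
        "missing_rate": 1.0 - n_typed / n,
        "p": p,
        "maf": np.minimum(p, q),
        "he": he,
        "pic": pic,
        "defined": defined,
    })


def marker_summary(
    g: GenotypeMatrix, regions: dict[str, str] | pd.Series | None = None
) -> MarkerStats:
    """Compute MAF, He, PIC and missingness per locus.

    For a biallelic locus with reference-allele frequency ``p`` (``q = 1-p``):
    ``He = 2pq`` and ``PIC = 1 - (p^2 + q^2) - 2 p^2 q^2``. When ``regions``
    maps individual ids to region labels, the same table is additionally
    computed within each region; individuals without a region are excluded
    from the per-region tables only.
    """
    per_region: dict[str, pd.DataFrame] = {}
    if regions is not None:
        if isinstance(regions, pd.Series):
            regions = regions.to_dict()
        by_region: dict[str, list[str]] = {}
        for ind in g.ids:
            r = regions.get(ind)
            if r is not None and not (isinstance(r, float) and np.isnan(r)):
                by_region.setdefault(str(r), []).append(ind)
        for r, members in sorted(by_region.items()):
            per_region[r] = _locus_table(g.subset(members))
    return MarkerStats(per_locus=_locus_table(g), per_region=per_region)


def filter_loci_by_missingness(
    g: GenotypeMatrix, max_missing_rate: float
) -> GenotypeMatrix:
    """Drop loci whose missing rate exceeds the threshold (logged)."""
    stats = _locus_table(g)
    keep = stats["missing_rate"] <= max_missing_rate
    dropped = int((~keep).sum())
    if dropped:
        logger.info(
            "dropping %d/%d loci with missing rate > %.2f",
            dropped, g.n_loci, max_missing_rate,
        )
        keep_idx = np.flatnonzero(keep.to_numpy())
        return GenotypeMatrix(
            list(g.ids),
            [g.loci[j] for j in keep_idx],
            g.data[:, keep_idx].copy(),
        )
    return g
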