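"""Genotype containers, file IO, per-SNP quality control, and kinship.

Dosages are stored as a dense float matrix (accessions x SNPs) with values in
{0, 1, 2} counting copies of allele2 (the ALT allele for VCF input) and NaN
for missing calls.  The SNP map carries per-marker metadata (id, chromosome,
1-based position, alleles) as a :class:`pandas.DataFrame` aligned with the
matrix columns.

Quality control follows the common chip-genotyping criteria for an inbred
diversity panel: call rate strictly above a floor, minor allele frequency at
or above a floor, and heterozygosity at or below a ceiling (heterozygous
calls in a selfing species are mostly technical artefacts).  All three rules
are evaluated simultaneously on the raw matrix.

The genomic relationship matrix uses the VanRaden centred-dosage form
``K = ZZ' / (2 * sum_i f_i (1 - f_i))`` with per-SNP mean imputation of
missing dosages, which is the covariance structure assumed for the polygenic
random effect in the mixed-model association scan.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DataFormatError, ModelError

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "KinshipMatrix",
    "SNPQualityControl",
    "read_genotypes",
    "write_genotypes",
    "compute_snp_stats",
    "apply_qc",
    "compute_kinship",
]


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix with per-SNP map metadata.

    Parameters
    ----------
    dosage:
        Float array of shape ``(n_accessions, n_snps)`` with entries in
        {0, 1, 2} and NaN for missing calls.
    accession_ids:
        Unique accession labels, one per row.
    snp_map:
        DataFrame with columns ``snp_id, chrom, pos, allele1, allele2``;
        within each chromosome rows must be sorted by position.
    true_dosage:
        Optional complete (no-missing) matrix attached by the simulator; it
        is never written to disk and is ignored by equality checks.
    """

    dosage: np.ndarray
    accession_ids: list[str]
    snp_map: pd.DataFrame
    true_dosage: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.accession_ids = [str(a) for a in self.accession_ids]
        if self.dosage.ndim != 2:
            raise DataFormatError("dosage must be a 2-D accessions x SNPs matrix")
        n_acc, n_snp = self.dosage.shape
        if len(self.accession_ids) != n_acc:
            raise DataFormatError(
                f"{len(self.accession_ids)} accession ids for {n_acc} matrix rows"
            )
        if len(set(self.accession_ids)) != n_acc:
            dupes = _duplicates(self.accession_ids)
            raise DataFormatError(f"duplicate accession ids: {dupes}")
        self.snp_map = self.snp_map.reset_index(drop=True)
        missing_cols = [c for c in MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise DataFormatError(f"snp_map lacks columns {missing_cols}")
        if len(self.snp_map) != n_snp:
            raise DataFormatError(
                f"{len(self.snp_map)} map rows for {n_snp} matrix columns"
            )
        ids = self.snp_map["snp_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise DataFormatError(f"duplicate SNP ids: {dupes}")
        pos = self.snp_map["pos"].to_numpy()
        if n_snp and (not np.issubdtype(np.asarray(pos).dtype, np.number) or (pos <= 0).any()):
            raise DataFormatError("positions must be positive integers")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if (np.diff(p) < 0).any():
                raise DataFormatError(f"positions on {chrom} are not sorted")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise DataFormatError(f"non-missing dosages must be 0/1/2, found {bad}")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snp_map["snp_id"].astype(str).tolist()

    def subset_snps(self, mask_or_indices) -> "GenotypeMatrix":
        """Return a new matrix keeping the selected SNP columns (order kept)."""
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            accession_ids=list(self.accession_ids),
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
            true_dosage=None if self.true_dosage is None else self.true_dosage[:, idx],
        )

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise DataFormatError(f"unknown accession ids: {missing[:5]}")
        rows = [index[a] for a in ids]
        return GenotypeMatrix(
            dosage=self.dosage[rows],
            accession_ids=[str(a) for a in ids],
            snp_map=self.snp_map.copy(),
            true_dosage=None if self.true_dosage is None else self.true_dosage[rows],
        )


@dataclass
class QCReport:
    """Bookkeeping for one QC pass (thresholds used and per-rule counts)."""

    call_rate_min: float
    maf_min: float
    het_max: float
    n_input: int
    n_output: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_het: int
    n_fail_multiple: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_output

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass
class KinshipMatrix:
    """Symmetric genomic relationship matrix with accession labels."""

    values: np.ndarray
    accession_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise DataFormatError("kinship shape does not match accession ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise DataFormatError("kinship matrix is not symmetric")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.accession_ids
        )

    def restrict(self, ids: Sequence[str]) -> "KinshipMatrix":
        index = {a: i for i, a in enumerate(self.accession_ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise ModelError(f"kinship does not cover accessions: {missing[:5]}")
        rows = np.array([index[a] for a in ids])
        return KinshipMatrix(self.values[np.ix_(rows, rows)], [str(a) for a in ids])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV (dosage dialect) or VCF.

    The TSV dialect has a header ``snp_id chrom pos allele1 allele2`` followed
    by one column per accession; each subsequent row is one SNP with dosage
    tokens in {0, 1, 2, NA}.  VCF input keeps biallelic sites only
    (multi-allelic records are dropped with a logged count) and counts copies
    of the ALT allele.
    """
    path = Path(path)
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        format = "vcf" if ".vcf" in suffixes else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise DataFormatError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(MAP_COLUMNS)] != MAP_COLUMNS:
        raise DataFormatError(
            f"{path}: header must start with {MAP_COLUMNS}, got {header[:5]}"
        )
    accession_ids = header[len(MAP_COLUMNS):]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    snp_map = df[MAP_COLUMNS].copy()
    snp_map["pos"] = pd.to_numeric(snp_map["pos"], errors="raise").astype(int)
    raw = df[accession_ids].to_numpy(dtype=str)
    bad = ~np.isin(raw, ("0", "1", "2", "NA", ""))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataFormatError(
            f"{path}: bad dosage token {raw[i, j]!r} at SNP row {i + 2} "
            f"(snp_id={snp_map['snp_id'].iloc[i]}), accession {accession_ids[j]}"
        )
    dosage = np.full(raw.shape, np.nan)
    for tok, val in (("0", 0.0), ("1", 1.0), ("2", 2.0)):
        dosage[raw == tok] = val
    # matrix is stored SNP-major on disk, accession-major in memory
    return GenotypeMatrix(dosage.T, accession_ids, snp_map)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    accession_ids = list(vcf.samples)
    rows, map_rows = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(var.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        map_rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        logger.info("dropped %d multi-allelic VCF records", n_multi)
    snp_map = pd.DataFrame(map_rows, columns=MAP_COLUMNS)
    if snp_map["snp_id"].duplicated().any():
        dupes = sorted(snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].unique())
        raise DataFormatError(f"duplicate SNP ids in VCF: {dupes}")
    dosage = np.array(rows).T if rows else np.empty((len(accession_ids), 0))
    return GenotypeMatrix(dosage, accession_ids, snp_map)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect (one SNP per row, NA for missing)."""
    dos = G.dosage.T  # SNP-major on disk
    body = pd.DataFrame(
        np.where(np.isnan(dos), "NA", dos.astype(object)),
        columns=G.accession_ids,
    )
    for c in body.columns:
        body[c] = body[c].map(lambda v: v if isinstance(v, str) else f"{int(v)}")
    out = pd.concat([G.snp_map.reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Per-SNP statistics and QC
# ---------------------------------------------------------------------------

def compute_snp_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, minor allele frequency, and heterozygosity rate.

    SNPs with no non-missing calls get NaN maf/het and ``all_missing=True``
    rather than a silent zero.
    """
    if G.n_accessions < 1:
        raise DataFormatError("need at least one accession")
    dos = G.dosage
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    call_rate = n_called / G.n_accessions
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(dos, axis=0) / (2.0 * n_called)
        maf = np.minimum(freq, 1.0 - freq)
        het = (dos == 1).sum(axis=0) / n_called
    all_missing = n_called == 0
    maf = np.where(all_missing, np.nan, maf)
    het = np.where(all_missing, np.nan, het)
    return pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "het_rate": het,
            "n_called": n_called,
            "all_missing": all_missing,
        }
    ).set_index("snp_id")


class SNPQualityControl(BaseEstimator):
    """Simultaneous three-rule SNP filter (call rate, MAF, heterozygosity).

    Boundary semantics mirror the usual chip-QC wording: call rate strictly
    greater than ``call_rate_min``; MAF greater than or equal to ``maf_min``;
    heterozygosity less than or equal to ``het_max``.  All rules are
    evaluated on the input matrix in a single pass, so the filter is
    idempotent.

    Attributes (after :meth:`fit`)
    ------------------------------
    stats_ : per-SNP statistics DataFrame
    keep_mask_ : boolean array over input SNPs
    report_ : :class:`QCReport`
    """

    def __init__(self, call_rate_min: float = 0.80, maf_min: float = 0.05,
                 het_max: float = 0.15):
        self.call_rate_min = call_rate_min
        self.maf_min = maf_min
        self.het_max = het_max

    def fit(self, G: GenotypeMatrix, y=None) -> "SNPQualityControl":
        stats = compute_snp_stats(G)
        # all-missing SNPs fail the call-rate rule (call_rate 0, not >)
        fail_cr = ~(stats["call_rate"].to_numpy() > self.call_rate_min)
        maf = stats["maf"].to_numpy()
        het = stats["het_rate"].to_numpy()
        fail_maf = ~(maf >= self.maf_min)  # NaN fails
        fail_het = ~(het <= self.het_max)  # NaN fails
        n_rules = fail_cr.astype(int) + fail_maf.astype(int) + fail_het.astype(int)
        keep = n_rules == 0
        self.stats_ = stats
        self.keep_mask_ = keep
        self.report_ = QCReport(
            call_rate_min=self.call_rate_min,
            maf_min=self.maf_min,
            het_max=self.het_max,
            n_input=G.n_snps,
            n_output=int(keep.sum()),
            n_fail_call_rate=int(fail_cr.sum()),
            n_fail_maf=int(fail_maf.sum()),
            n_fail_het=int(fail_het.sum()),
            n_fail_multiple=int((n_rules > 1).sum()),
        )
        self._fitted_snp_ids = G.snp_ids
        return self

    def transform(self, G: GenotypeMatrix) -> GenotypeMatrix:
        if G.snp_ids != self._fitted_snp_ids:
            raise DataFormatError("transform input does not match fitted SNP set")
        if self.report_.n_output == 0:
            warnings.warn("QC removed every SNP; returning an empty matrix",
                          stacklevel=2)
        return G.subset_snps(self.keep_mask_)

    def fit_transform(self, G: GenotypeMatrix, y=None) -> GenotypeMatrix:
        return self.fit(G).transform(G)


def apply_qc(G: GenotypeMatrix, call_rate_min: float = 0.80,
             maf_min: float = 0.05, het_max: float = 0.15,
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Filter SNPs by the three QC rules; returns (filtered matrix, report)."""
    qc = SNPQualityControl(call_rate_min, maf_min, het_max)
    out = qc.fit_transform(G)
    return out, qc.report_


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def _vanraden(dosage: np.ndarray) -> np.ndarray:
    """VanRaden GRM from a dosage matrix (NaN allowed; per-SNP mean imputed)."""
    dos = np.asarray(dosage, dtype=float)
    called = ~np.isnan(dos)
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        raise ModelError("kinship input contains all-missing SNPs")
    freq = np.nansum(dos, axis=0) / (2.0 * n_called)
    denom = 2.0 * float(np.sum(freq * (1.0 - freq)))
    if denom <= 0.0:
        raise ModelError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = np.where(called, dos, 2.0 * freq) - 2.0 * freq
    return (Z @ Z.T) / denom


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from (post-QC) dosages."""
    return KinshipMatrix(_vanraden(G.dosage), list(G.accession_ids))


def _duplicates(items: Sequence[str]) -> list[str]:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return sorted(dup)
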