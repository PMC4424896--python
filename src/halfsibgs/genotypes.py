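"""Genotype matrices: additive coding, I/O, allele statistics and SNP filters.

Genotypes are held as an individuals × SNPs array in additive coding
(-1, 0, +1 for aa, Aa, AA — i.e. ALT-allele dosage minus one) with ``nan``
marking missing calls, the convention used throughout GBS-based genomic
selection pipelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("halfsibgs")

_VALID_CODES = (-1.0, 0.0, 1.0)


class GenotypeError(ValueError):
    """Raised for malformed or inconsistent genotype data."""


@dataclass
class GenotypeMatrix:
    """Individuals × SNPs additive-coded genotype matrix.

    Parameters
    ----------
    values
        Float array of shape (n_individuals, n_snps); entries in
        {-1, 0, +1} or ``nan`` for missing.
    individual_ids, snp_ids
        Unique string identifiers for rows and columns.
    family_labels
        Optional open-pollinated family label per individual.
    """

    values: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]
    family_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.values.ndim != 2:
            raise GenotypeError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.individual_ids) != n:
            raise GenotypeError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.snp_ids) != m:
            raise GenotypeError(f"{len(self.snp_ids)} SNP ids for {m} columns")
        if len(set(self.individual_ids)) != n:
            raise GenotypeError("individual ids are not unique")
        if len(set(self.snp_ids)) != m:
            raise GenotypeError("SNP ids are not unique")
        if self.family_labels is not None:
            self.family_labels = [str(f) for f in self.family_labels]
            if len(self.family_labels) != n:
                raise GenotypeError("family_labels length mismatch")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, _VALID_CODES).all():
            bad = finite[~np.isin(finite, _VALID_CODES)]
            raise GenotypeError(f"invalid genotype codes present: {bad[:5]}")

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.values).mean())

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values.copy(),
            list(self.individual_ids),
            list(self.snp_ids),
            list(self.family_labels) if self.family_labels is not None else None,
        )

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.values[:, index],
            list(self.individual_ids),
            [self.snp_ids[i] for i in np.flatnonzero(index) if index.dtype == bool]
            if index.dtype == bool
            else [self.snp_ids[i] for i in index],
            list(self.family_labels) if self.family_labels is not None else None,
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        pos = np.flatnonzero(index) if index.dtype == bool else index
        return GenotypeMatrix(
            self.values[pos, :],
            [self.individual_ids[i] for i in pos],
            list(self.snp_ids),
            [self.family_labels[i] for i in pos]
            if self.family_labels is not None
            else None,
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV, rows=individuals, columns=SNPs, NA for missing."""
        as_str = np.where(
            np.isnan(self.values),
            "NA",
            np.nan_to_num(self.values).astype(int).astype(str),
        )
        df = pd.DataFrame(as_str, index=self.individual_ids, columns=self.snp_ids)
        df.to_csv(path, sep="\t", index_label="individual")

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal unphased VCF v4.2 (GT only, synthetic positions)."""
        code_to_gt = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("##contig=<ID=1>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individual_ids)
                + "\n"
            )
            for j, sid in enumerate(self.snp_ids):
                gts = [
                    "./." if np.isnan(v) else code_to_gt[v]
                    for v in self.values[:, j]
                ]
                fh.write(
                    f"1\t{j + 1}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
                )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV.

    VCF GT values 0/0, 0/1, 1/1, ./. map to -1, 0, +1, missing (ALT dosage
    minus one). Multiallelic sites are skipped with a logged warning.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    # cyvcf2 gt_types: 0=HOM_REF 1=HET 2=UNKNOWN 3=HOM_ALT
    gt_map = np.array([-1.0, 0.0, np.nan, 1.0])
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multiallelic site %s:%s (%s)", var.CHROM, var.POS, var.ID
            )
            continue
        cols.append(gt_map[np.asarray(var.gt_types)])
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
    vcf.close()
    if not cols:
        values = np.empty((len(samples), 0))
    else:
        values = np.column_stack(cols)
    return GenotypeMatrix(values, samples, ids)


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise GenotypeError(f"could not parse {path}: {exc}") from exc
    return GenotypeMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


# -- allele statistics ----------------------------------------------------

def allele_frequencies(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP ALT (reference-panel ``A``) allele frequency, missing-aware.

    p_j = (mean of non-missing codes + 1) / 2.  A SNP with no calls at all
    raises, since its frequency is undefined.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    n_called = (~np.isnan(values)).sum(axis=0)
    if (n_called == 0).any():
        bad = np.flatnonzero(n_called == 0)
        raise GenotypeError(f"allele frequency undefined: all calls missing at SNP index {bad[0]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = (np.nanmean(values, axis=0) + 1.0) / 2.0
    return p


def allele_frequency(genotypes: GenotypeMatrix, snp: int | str) -> float:
    j = genotypes.snp_ids.index(snp) if isinstance(snp, str) else int(snp)
    col = genotypes.values[:, [j]]
    return float(allele_frequencies(col)[0])


def snp_inbreeding_F(genotypes: GenotypeMatrix | np.ndarray, snp: int | str | None = None) -> np.ndarray | float:
    """Per-SNP inbreeding coefficient F = 1 - Ho / (2 p (1-p)).

    Ho is the observed heterozygote fraction over non-missing calls. Returns
    0 by convention for monomorphic SNPs (p in {0, 1}).  Negative F marks
    heterozygote excess (the paralog-collapse signature in GBS data).
    """
    if isinstance(genotypes, GenotypeMatrix) and snp is not None:
        j = genotypes.snp_ids.index(snp) if isinstance(snp, str) else int(snp)
        return float(snp_inbreeding_F(genotypes.values[:, [j]]))
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    p = allele_frequencies(values)
    called = ~np.isnan(values)
    ho = np.where(called, values == 0.0, False).sum(axis=0) / called.sum(axis=0)
    he = 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 1.0 - ho / he
    f = np.where(he == 0.0, 0.0, f)
    if f.size == 1 and (snp is not None or values.shape[1] == 1):
        return float(f[0])
    return f


# -- filtering -------------------------------------------------------------

@dataclass
class FilterSpec:
    """SNP filter thresholds.

    ``max_missing_fraction`` follows the study's 30%/60% missing-data
    thresholds; ``min_maf`` the mnMAF = 0.05 rule; ``min_inbreeding_F`` the
    mnF = 0.05 rule (keep SNPs with F >= threshold, removing excess-
    heterozygosity paralog artifacts); ``min_call_fraction`` drops SNPs
    genotyped in fewer than 40% of samples.
    """

    max_missing_fraction: float = 0.30
    min_maf: float = 0.05
    min_inbreeding_F: float = 0.05
    min_call_fraction: float = 0.40

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "min_maf", "min_call_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"FilterSpec.{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Per-rule removal counts from :func:`filter_snps` (disjoint, in order)."""

    n_input: int
    removed_call_rate: int
    removed_missing: int
    removed_inbreeding: int
    removed_maf: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "call_rate",
                    "missing_fraction",
                    "inbreeding_F",
                    "maf",
                    "retained",
                ],
                "count": [
                    self.removed_call_rate,
                    self.removed_missing,
                    self.removed_inbreeding,
                    self.removed_maf,
                    self.n_retained,
                ],
            }
        )


def filter_snps(
    genotypes: GenotypeMatrix, spec: FilterSpec | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the GBS SNP filters in fixed order.

    Order: call rate, missing-data threshold, inbreeding F, MAF.  Each SNP
    is attributed to the first rule that removes it, so the report counts
    are disjoint.
    """
    spec = spec or FilterSpec()
    values = genotypes.values
    n = values.shape[0]
    called = (~np.isnan(values)).sum(axis=0)
    call_frac = called / n
    keep = np.ones(values.shape[1], dtype=bool)

    fail_call = call_frac < spec.min_call_fraction
    n_call = int(fail_call.sum())
    keep &= ~fail_call

    miss_frac = 1.0 - call_frac
    fail_miss = keep & (miss_frac > spec.max_missing_fraction)
    n_miss = int(fail_miss.sum())
    keep &= ~fail_miss

    # F and MAF are undefined on zero-call SNPs; those were removed above.
    safe = values[:, keep] if keep.any() else values[:, :0]
    idx_keep = np.flatnonzero(keep)
    if idx_keep.size:
        f = snp_inbreeding_F(safe)
        fail_f = np.atleast_1d(f) < spec.min_inbreeding_F
        n_f = int(fail_f.sum())
        idx_keep = idx_keep[~fail_f]
        safe = safe[:, ~fail_f]
    else:
        n_f = 0
    if idx_keep.size:
        p = allele_frequencies(safe)
        maf = np.minimum(p, 1.0 - p)
        fail_maf = maf < spec.min_maf
        n_maf = int(fail_maf.sum())
        idx_keep = idx_keep[~fail_maf]
    else:
        n_maf = 0

    report = FilterReport(
        n_input=values.shape[1],
        removed_call_rate=n_call,
        removed_missing=n_miss,
        removed_inbreeding=n_f,
        removed_maf=n_maf,
        n_retained=int(idx_keep.size),
    )
    if idx_keep.size == 0:
        logger.warning("all SNPs removed by filtering")
    return genotypes.subset_snps(idx_keep), report


def center_standardize(
    genotypes: GenotypeMatrix | np.ndarray, scale: bool = False
) -> np.ndarray:
    """VanRaden-center the code matrix: column j shifted by 2 p_j - 1.

    With ``scale=True`` the whole matrix is additionally divided by
    sqrt(2 Σ p_j (1 - p_j)) so that W Wᵀ is on the relationship scale.
    Missing entries must be imputed first.
    """
    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    if np.isnan(values).any():
        raise GenotypeError(
            "genotype matrix contains missing entries; impute before standardizing"
        )
    p = (values.mean(axis=0) + 1.0) / 2.0
    w = values - (2.0 * p - 1.0)
    if scale:
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise GenotypeError("all SNPs monomorphic; cannot scale")
        w = w / np.sqrt(denom)
    return w
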