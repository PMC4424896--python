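"""Relationship matrices: pedigree numerator A for half-sib designs, the
VanRaden marker-based G, missing-aware individual distances, and group
coancestry.

Everything is kept on the *relationship* scale (self = 1 for a non-inbred
individual); the single conversion to the coancestry scale (self = 1/2)
happens inside :func:`group_coancestry`, so factor-of-2 bookkeeping lives in
one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("halfsibgs")

#: ridge added to G's diagonal before inversion in GBLUP paths
G_RIDGE = 1e-6


@dataclass
class KinshipMatrix:
    """Symmetric n × n relationship matrix over named individuals."""

    values: np.ndarray
    ids: list[str]
    flavor: str  # "pedigree" | "genomic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        if self.flavor not in ("pedigree", "genomic"):
            raise ValueError(f"unknown kinship flavor {self.flavor!r}")

    def subset(self, ids: list[str]) -> "KinshipMatrix":
        pos = [self.ids.index(i) for i in ids]
        return KinshipMatrix(self.values[np.ix_(pos, pos)], list(ids), self.flavor)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


def pedigree_A_halfsib(pedigree: pd.DataFrame) -> KinshipMatrix:
    """Numerator relationship matrix for an idealized half-sib design.

    Diagonal 1, 0.25 between members of the same open-pollinated family,
    0 across families.  ``pedigree`` needs columns ``individual`` and
    ``family``; an individual appearing in several rows (e.g. one row per
    measurement) is collapsed to one entry.
    """
    if "family" not in pedigree.columns or "individual" not in pedigree.columns:
        raise ValueError("pedigree must have 'individual' and 'family' columns")
    ped = pedigree.drop_duplicates("individual")
    if ped["family"].isna().any():
        missing = ped.loc[ped["family"].isna(), "individual"].tolist()
        raise ValueError(f"missing family label for individuals {missing[:5]}")
    fam = ped["family"].to_numpy()
    same = (fam[:, None] == fam[None, :]).astype(float)
    a = 0.25 * same
    np.fill_diagonal(a, 1.0)
    return KinshipMatrix(a, ped["individual"].astype(str).tolist(), "pedigree")


def vanraden_G(genotypes) -> KinshipMatrix:
    """VanRaden marker relationship G = W Wᵀ / (2 Σ p_j (1 - p_j)).

    W is the additive code matrix column-centered by 2p_j - 1 using observed
    allele frequencies.  Monomorphic columns contribute nothing to either
    the numerator or the denominator.
    """
    from .genotypes import GenotypeMatrix, GenotypeError

    if isinstance(genotypes, GenotypeMatrix):
        values, ids = genotypes.values, genotypes.individual_ids
    else:
        values = np.asarray(genotypes, float)
        ids = [str(i) for i in range(values.shape[0])]
    if np.isnan(values).any():
        raise GenotypeError("G requires a complete (imputed) genotype matrix")
    p = (values.mean(axis=0) + 1.0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise GenotypeError("all SNPs monomorphic; G undefined")
    w = values[:, poly] - (2.0 * p[poly] - 1.0)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0
    return KinshipMatrix(g, list(ids), "genomic")


def individual_euclidean_distance(genotypes) -> np.ndarray:
    """Missing-aware Euclidean distance between individuals.

    Squared differences are averaged over pairwise-complete loci and scaled
    back up by the total locus count, so sparser pairs are not artificially
    close:  d_ik = sqrt( m / |S_ik| · Σ_{j∈S_ik} (x_ij - x_kj)² ).
    Pairs sharing no called locus get ``inf`` with a warning.
    """
    from .genotypes import GenotypeMatrix

    values = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    n, m = values.shape
    mask = (~np.isnan(values)).astype(float)
    x0 = np.where(np.isnan(values), 0.0, values)
    sq = x0**2
    shared = mask @ mask.T
    # sum over shared loci of x_i^2, x_k^2 and cross-term
    si = sq @ mask.T
    cross = x0 @ x0.T
    d2 = si + si.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (m / shared)
    none_shared = shared == 0
    if none_shared.any():
        logger.warning("some individual pairs share no called locus; distance set to inf")
        d2[none_shared] = np.inf
    d2 = np.maximum(d2, 0.0)
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(d2)
    return (d + d.T) / 2.0


def group_coancestry(kinship: KinshipMatrix, subset: list[str] | np.ndarray | None = None) -> float:
    """Group coancestry Θ of a subset: mean kinship over all ordered pairs
    including self-pairs.  On the relationship scale this is
    Θ = Σ K_sub / (2 n²).
    """
    k = kinship.values if subset is None else kinship.subset(list(subset)).values
    n = k.shape[0]
    if n == 0:
        raise ValueError("empty subset has no group coancestry")
    return float(k.sum() / (2.0 * n * n))


def status_number(kinship: KinshipMatrix, subset=None) -> float:
    """Status number N_s = 0.5 / Θ (pedigree coancestry).

    Approximates the effective number of parents behind the selected set.
    """
    theta = group_coancestry(kinship, subset)
    if theta <= 0:
        raise ValueError(
            "group coancestry <= 0; with a genomic matrix consider bending "
            "(bend_kinship) before computing diversity"
        )
    return 0.5 / theta


def founder_genome_equivalents(kinship: KinshipMatrix, subset=None) -> float:
    """Founder genome equivalents N_ge = 0.5 / Θ on the marker-based matrix."""
    return status_number(kinship, subset)


def bend_kinship(kinship: KinshipMatrix, min_eigenvalue: float = 1e-6) -> KinshipMatrix:
    """Shift the spectrum so the smallest eigenvalue is >= ``min_eigenvalue``."""
    w = np.linalg.eigvalsh(kinship.values)
    lo = float(w.min())
    if lo >= min_eigenvalue:
        return kinship
    shift = min_eigenvalue - lo
    return KinshipMatrix(
        kinship.values + shift * np.eye(len(kinship.ids)), list(kinship.ids), kinship.flavor
    )
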