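"""Marker-effect genomic selection models: RR-BLUP and generalized ridge
regression (GRR).

Both fit y = 1μ + Z b + e by Henderson's mixed-model equations, with Z the
VanRaden-centered additive code matrix.  RR-BLUP shrinks every SNP by the
common λ = σ²_e/σ²_b (estimated by REML through the eigendecomposition of
Z Zᵀ, so no Monte Carlo is involved).  GRR starts from the RR-BLUP fit and
re-solves with SNP-specific shrinkage λ_j = σ²_e/σ̂²_bj, where
σ̂²_bj = b̂_j²/(1 − h_jj) and h_jj is the marker's leverage in the augmented
ridge hat matrix — SNPs with large first-pass effects are shrunk less,
giving the model its variable-selection character.

Solves use the n-dimensional dual forms throughout, so cost scales with
individuals, not markers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import GenotypeMatrix, GenotypeError

logger = logging.getLogger("halfsibgs")

_LAMBDA_CAP = 1e12


@dataclass
class MarkerEffectsModel:
    intercept: float
    effects: np.ndarray
    lambda_: float | np.ndarray      # scalar (RR-BLUP) or per-SNP (GRR)
    allele_frequencies: np.ndarray   # training p_j, travels with the model
    snp_ids: list[str]
    method: str                      # "rrblup" | "grr"
    n_iterations: int = 0
    sigma2_b: float | None = None
    sigma2_e: float | None = None

    def to_json(self, path: str | Path) -> None:
        lam = self.lambda_
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "effects": np.asarray(self.effects).tolist(),
                    "lambda": lam.tolist() if isinstance(lam, np.ndarray) else lam,
                    "allele_frequencies": np.asarray(self.allele_frequencies).tolist(),
                    "snp_ids": self.snp_ids,
                    "method": self.method,
                    "n_iterations": self.n_iterations,
                    "sigma2_b": self.sigma2_b,
                    "sigma2_e": self.sigma2_e,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerEffectsModel":
        raw = json.loads(Path(path).read_text())
        lam = raw["lambda"]
        return cls(
            intercept=raw["intercept"],
            effects=np.asarray(raw["effects"]),
            lambda_=np.asarray(lam) if isinstance(lam, list) else lam,
            allele_frequencies=np.asarray(raw["allele_frequencies"]),
            snp_ids=raw["snp_ids"],
            method=raw["method"],
            n_iterations=raw["n_iterations"],
            sigma2_b=raw["sigma2_b"],
            sigma2_e=raw["sigma2_e"],
        )


def _coded_matrix(genotypes) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(genotypes, GenotypeMatrix):
        values, ids = genotypes.values, list(genotypes.snp_ids)
    else:
        values = np.asarray(genotypes, float)
        ids = [f"snp{j}" for j in range(values.shape[1])]
    if np.isnan(values).any():
        raise GenotypeError("GS models require a complete (imputed) genotype matrix")
    p = (values.mean(axis=0) + 1.0) / 2.0
    z = values - (2.0 * p - 1.0)
    return z, p, ids


def _reml_lambda(y: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """REML of (σ²_b, σ²_e) for y = 1μ + Zb + e via the spectrum of ZZᵀ.

    Returns (sigma2_b, sigma2_e, lambda)."""
    n = y.size
    d, u = np.linalg.eigh(z @ z.T)
    d = np.maximum(d, 0.0)
    yt = u.T @ y
    xt = u.T @ np.ones((n, 1))

    def nll(log_s2):
        s2b, s2e = np.exp(log_s2)
        dv = s2b * d + s2e
        dinv = 1.0 / dv
        xvx = float((xt[:, 0] ** 2 * dinv).sum())
        xvy = float((xt[:, 0] * yt * dinv).sum())
        beta = xvy / xvx
        r = yt - xt[:, 0] * beta
        quad = float((r**2 * dinv).sum())
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi)
            + float(np.log(dv).sum())
            + np.log(xvx)
            + quad
        )
        return -ll if np.isfinite(ll) else 1e30

    from scipy import optimize

    var_y = max(float(np.var(y)), 1e-12)
    mean_d = max(float(d.mean()), 1e-12)
    x0 = np.log([0.5 * var_y / mean_d, 0.5 * var_y])
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
    )
    s2b, s2e = np.exp(res.x)
    if s2b <= 1e-12 * var_y / mean_d:
        logger.warning("marker variance estimated ~0; effects fully shrunk")
    return float(s2b), float(s2e), float(s2e / s2b) if s2b > 0 else _LAMBDA_CAP


def _solve_ridge(y, z, lam) -> tuple[float, np.ndarray]:
    """Dual MME solve: β̂ by GLS under V = Z Λ⁻¹ Zᵀ + I, then
    b̂ = Λ⁻¹Zᵀ V⁻¹ (y − 1β̂).  Identical to the primal MME solution."""
    n = y.size
    lam = np.broadcast_to(np.asarray(lam, float), (z.shape[1],))
    lam = np.minimum(lam, _LAMBDA_CAP)
    zl = z / lam[None, :]
    v = zl @ z.T + np.eye(n)
    vinv_y = np.linalg.solve(v, y)
    vinv_1 = np.linalg.solve(v, np.ones(n))
    beta = float(vinv_y.sum() / vinv_1.sum())
    r = y - beta
    b = zl.T @ np.linalg.solve(v, r)
    return beta, b


def fit_rrblup(
    ebv: np.ndarray, genotypes, lambda_: float | None = None
) -> MarkerEffectsModel:
    """Ridge-regression BLUP of SNP effects from an EBV response.

    λ is estimated by REML unless supplied.  The intercept is the only
    fixed effect; the training allele frequencies are stored so validation
    genotypes are standardized identically.
    """
    y = np.asarray(ebv, float)
    z, p, ids = _coded_matrix(genotypes)
    if y.size != z.shape[0]:
        raise ValueError(f"response length {y.size} != {z.shape[0]} individuals")
    s2b = s2e = None
    if lambda_ is None:
        if np.allclose(y, y[0]):
            # constant response: no genetic variance to fit
            return MarkerEffectsModel(
                float(y[0]), np.zeros(z.shape[1]), _LAMBDA_CAP, p, ids,
                "rrblup", 0, 0.0, 0.0,
            )
        s2b, s2e, lambda_ = _reml_lambda(y, z)
    beta, b = _solve_ridge(y, z, lambda_)
    return MarkerEffectsModel(
        intercept=beta,
        effects=b,
        lambda_=float(lambda_),
        allele_frequencies=p,
        snp_ids=ids,
        method="rrblup",
        n_iterations=0,
        sigma2_b=s2b,
        sigma2_e=s2e,
    )


def marker_leverages(z: np.ndarray, lam: np.ndarray, literal_diag_lambda: bool = False) -> np.ndarray:
    """Diagonal hat-matrix entries h_jj of the augmented ridge regression.

    H = T(TᵀT)⁻¹Tᵀ with T stacking [1 Z] over the ridge augmentation rows.
    Default augmentation uses diag(√λ), making H a true hat matrix with
    h_jj ∈ [0, 1); ``literal_diag_lambda=True`` augments with diag(λ) instead.
    """
    lam = np.asarray(lam, float)
    s2 = lam if not literal_diag_lambda else lam**2  # squared augmentation weights
    # marker block of (TᵀT)⁻¹ is (ZᵀZ + diag(s2))⁻¹ because Z is
    # column-centered (intercept absorbs exactly)
    n = z.shape[0]
    zs = z / s2[None, :]
    core = np.eye(n) + zs @ z.T
    pz = np.linalg.solve(core, zs)          # (n, m): core⁻¹ Z S⁻¹
    quad = np.einsum("ij,ij->j", zs, pz)    # (Z S⁻¹)ᵀ core⁻¹ (Z S⁻¹) diagonal
    diag_inv = 1.0 / s2 - quad
    h = s2 * diag_inv
    return np.clip(h, 0.0, 1.0 - 1e-10)


def fit_grr(
    ebv: np.ndarray,
    genotypes,
    max_iterations: int = 1,
    literal_diag_lambda: bool = False,
) -> MarkerEffectsModel:
    """Generalized ridge regression: RR-BLUP first pass, then SNP-specific
    shrinkage λ_j = σ²_e / σ̂²_bj with σ̂²_bj = b̂_j² / (1 − h_jj).

    One heteroscedastic update is the default (the method's deterministic
    two-step form); more iterations repeat the leverage/variance update.
    """
    y = np.asarray(ebv, float)
    rr = fit_rrblup(y, genotypes)
    z, p, ids = _coded_matrix(genotypes)
    s2e = rr.sigma2_e if rr.sigma2_e is not None else 1.0
    lam = np.full(z.shape[1], float(rr.lambda_))
    b = rr.effects
    beta = rr.intercept
    for _ in range(max_iterations):
        h = marker_leverages(z, lam, literal_diag_lambda=literal_diag_lambda)
        with np.errstate(divide="ignore", invalid="ignore"):
            s2bj = b**2 / (1.0 - h)
        lam = np.where(s2bj > 0, s2e / np.maximum(s2bj, 1e-300), _LAMBDA_CAP)
        lam = np.minimum(lam, _LAMBDA_CAP)
        beta, b = _solve_ridge(y, z, lam)
    return MarkerEffectsModel(
        intercept=beta,
        effects=b,
        lambda_=lam,
        allele_frequencies=p,
        snp_ids=ids,
        method="grr",
        n_iterations=max_iterations,
        sigma2_b=rr.sigma2_b,
        sigma2_e=rr.sigma2_e,
    )


def predict_gebv(model: MarkerEffectsModel, genotypes_new) -> np.ndarray:
    """GEBV of new individuals: ŷ = û + Σ_i Z_ij m̂_i, with Z standardized
    by the *training* allele frequencies stored in the model."""
    if isinstance(genotypes_new, GenotypeMatrix):
        missing = [s for s in model.snp_ids if s not in set(genotypes_new.snp_ids)]
        if missing:
            raise ValueError(
                f"validation genotypes lack {len(missing)} model SNPs, "
                f"e.g. {missing[:5]}"
            )
        order = [genotypes_new.snp_ids.index(s) for s in model.snp_ids]
        values = genotypes_new.values[:, order]
    else:
        values = np.asarray(genotypes_new, float)
        if values.shape[1] != len(model.snp_ids):
            raise ValueError("SNP count mismatch with model")
    if np.isnan(values).any():
        raise GenotypeError("validation genotypes must be complete")
    p = np.asarray(model.allele_frequencies)
    w = values - (2.0 * p - 1.0)
    return model.intercept + w @ np.asarray(model.effects)
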