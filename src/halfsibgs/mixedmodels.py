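"""Individual-tree mixed models: REML variance components, breeding values
and narrow-sense heritability under a pedigree (ABLUP) or marker (GBLUP)
relationship matrix.

Multi-site model:  y = site + block(site) + a + site×genotype + e with
a ~ N(0, K σ²_a), block and interaction iid, e iid.  Site is fixed; the
interaction is carried at the site×family level — the level at which it is
estimable when each tree grows on a single site.  The single-site model
drops all site terms:  y = mean + block + a + e.

REML maximizes the restricted log-likelihood directly over log-variances.
The genetic covariance is eigen-rotated once per data set, the remaining
iid design terms enter through a Woodbury identity, so each likelihood
evaluation is O(n·q²) instead of O(n³).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .kinship import KinshipMatrix

logger = logging.getLogger("halfsibgs")

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    sigma2_sb: float | None = None   # block(-within-site) variance
    sigma2_sa: float | None = None   # site×genotype variance (multi-site)
    standard_errors: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None  # over (a, [sb], [sa], e)
    names: tuple = ()


@dataclass
class ModelFit:
    variance_components: VarianceComponents
    fixed_effects: pd.Series
    ebv: pd.Series
    log_likelihood: float
    converged: bool
    relationship_flavor: str
    model: str            # "multi_site" | "single_site"
    trait: str = ""
    scope: str = "multi-site"


class DesignError(ValueError):
    """Singular or otherwise unusable model design."""


def _indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(labels))
    z = (np.asarray(labels)[:, None] == np.array(levels)[None, :]).astype(float)
    return z, levels


class _RotatedREML:
    """Restricted likelihood of y = Xβ + a + Σ_k Z_k u_k + e after rotating
    by the eigenvectors of the genetic covariance K."""

    def __init__(self, y, x, k_matrix, z_iid: list[np.ndarray]):
        self.n, self.p = x.shape
        d, u = np.linalg.eigh(k_matrix)
        self.d = np.maximum(d, 0.0)
        self.u = u
        self.yt = u.T @ y
        self.xt = u.T @ x
        self.zt = [u.T @ z for z in z_iid]
        self.n_terms = 2 + len(z_iid)  # a, iid..., e

    def _vinv_apply(self, s2: np.ndarray):
        """Return logdet(V) and a function x -> V^{-1}x in rotated space."""
        s2a, s2e = s2[0], s2[-1]
        dvec = s2a * self.d + s2e
        dinv = 1.0 / dvec
        logdet = float(np.sum(np.log(dvec)))
        if self.zt:
            w = np.hstack([np.sqrt(s2[1 + i]) * z for i, z in enumerate(self.zt)])
            a = w * dinv[:, None]
            c = np.eye(w.shape[1]) + w.T @ a
            cf = cho_factor(c, lower=True)
            logdet += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))

            def apply(x):
                return dinv[:, None] * x - a @ cho_solve(cf, a.T @ x)

        else:

            def apply(x):
                return dinv[:, None] * x

        return logdet, apply

    def negloglik(self, log_s2: np.ndarray) -> float:
        s2 = np.exp(log_s2)
        try:
            logdet, vinv = self._vinv_apply(s2)
            xv = vinv(self.xt)
            xvx = self.xt.T @ xv
            xvy = xv.T @ self.yt
            cf = cho_factor(xvx)
            beta = cho_solve(cf, xvy)
            ldx = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            r = self.yt - self.xt @ beta
            quad = float(r @ vinv(r[:, None])[:, 0])
        except np.linalg.LinAlgError:
            return 1e30
        ll = -0.5 * ((self.n - self.p) * _LOG2PI + logdet + ldx + quad)
        if not np.isfinite(ll):
            return 1e30
        return -ll

    def solution(self, s2: np.ndarray):
        """GLS fixed effects, residual V^{-1}r (rotated back) at s2."""
        _, vinv = self._vinv_apply(s2)
        xv = vinv(self.xt)
        beta = np.linalg.solve(self.xt.T @ xv, xv.T @ self.yt)
        r = self.yt - self.xt @ beta
        vinv_r = self.u @ vinv(r[:, None])[:, 0]
        return beta, vinv_r


def _fit_reml(y, x, k_matrix, z_iid, term_names, max_restarts: int = 2):
    eng = _RotatedREML(y, x, k_matrix, z_iid)
    var_y = float(np.var(y))
    nt = eng.n_terms
    start = np.log(np.full(nt, max(var_y, 1e-8) / nt))
    best = None
    x0 = start
    for _ in range(max_restarts + 1):
        res = optimize.minimize(
            eng.negloglik,
            x0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            x0 = res.x  # polish from the optimum
        else:
            break
    s2 = np.exp(best.x)
    ll = -best.fun
    converged = bool(best.fun < eng.negloglik(start) + 1e-9 and np.isfinite(ll))

    # observed-information SEs by central finite differences in sigma^2 space
    cov = None
    try:
        h = _numeric_hessian(lambda v: eng.negloglik(np.log(np.maximum(v, 1e-12))), s2)
        cov = np.linalg.inv(h)
    except np.linalg.LinAlgError:
        logger.warning("information matrix singular; no standard errors")
    ses = {}
    if cov is not None:
        diag = np.diag(cov)
        ses = {
            name: float(np.sqrt(d)) if d > 0 else float("nan")
            for name, d in zip(term_names, diag)
        }
    return eng, s2, ll, converged, ses, cov


def _numeric_hessian(f, x0, rel_step: float = 1e-4):
    k = x0.size
    h = np.zeros((k, k))
    steps = np.maximum(np.abs(x0), 1e-8) * rel_step
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def _prepare(phenotypes: pd.DataFrame, pedigree: pd.DataFrame | None, trait: str) -> pd.DataFrame:
    df = phenotypes.copy()
    needed = {"individual", "site", "block", "family"}
    if pedigree is not None and not needed.issubset(df.columns):
        df = df.merge(pedigree, on="individual", how="left", suffixes=("", "_ped"))
    if trait not in df.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    df = df.dropna(subset=[trait])
    return df


def _align_kinship(kinship: KinshipMatrix, ids: list[str]) -> np.ndarray:
    missing = set(ids) - set(kinship.ids)
    if missing:
        raise ValueError(
            f"kinship matrix does not cover {len(missing)} phenotyped individuals, "
            f"e.g. {sorted(missing)[:3]}"
        )
    return kinship.subset(ids).values


def fit_multi_site(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame | None,
    kinship: KinshipMatrix,
    trait: str,
) -> ModelFit:
    """REML fit of the multi-site individual-tree model.

    Fixed: overall mean + site.  Random: additive (covariance K σ²_a),
    block within site (iid), site×family interaction (iid), residual.
    Breeding values are the BLUPs of the additive effect (MSEBV).
    """
    df = _prepare(phenotypes, pedigree, trait)
    sites = pd.unique(df["site"])
    if len(sites) < 2:
        raise DesignError("multi-site model needs >= 2 sites")
    ids = df["individual"].astype(str).tolist()
    k = _align_kinship(kinship, ids)
    y = df[trait].to_numpy(dtype=float)

    site_dum, _ = _indicator(df["site"].to_numpy())
    x = np.column_stack([np.ones(len(df)), site_dum[:, 1:]])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("fixed-effect design (mean + site) is singular")
    z_block, _ = _indicator(df["block"].to_numpy())
    sxf = (df["site"].astype(str) + ":" + df["family"].astype(str)).to_numpy()
    z_sxf, _ = _indicator(sxf)

    eng, s2, ll, conv, ses, cov = _fit_reml(
        y, x, k, [z_block, z_sxf], ("sigma2_a", "sigma2_sb", "sigma2_sa", "sigma2_e")
    )
    beta, vinv_r = eng.solution(s2)
    ebv = s2[0] * (k @ vinv_r)
    vc = VarianceComponents(
        sigma2_a=float(s2[0]),
        sigma2_sb=float(s2[1]),
        sigma2_sa=float(s2[2]),
        sigma2_e=float(s2[3]),
        standard_errors=ses,
        covariance=cov,
        names=("sigma2_a", "sigma2_sb", "sigma2_sa", "sigma2_e"),
    )
    if not conv:
        logger.warning("multi-site REML did not converge for trait %s", trait)
    fe = pd.Series(beta, index=["mean"] + [f"site[{s}]" for s in sites[1:]])
    return ModelFit(
        variance_components=vc,
        fixed_effects=fe,
        ebv=pd.Series(ebv, index=ids),
        log_likelihood=float(ll),
        converged=conv,
        relationship_flavor=kinship.flavor,
        model="multi_site",
        trait=trait,
        scope="multi-site",
    )


def fit_single_site(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame | None,
    kinship: KinshipMatrix,
    trait: str,
    site: str | None = None,
) -> ModelFit:
    """REML fit of the single-site model y = mean + block + a + e.

    With only one block level the block term is dropped (warned).  Breeding
    values are the site-scope EBVs (SSEBV).
    """
    df = _prepare(phenotypes, pedigree, trait)
    if site is not None:
        df = df[df["site"].astype(str) == str(site)]
        if df.empty:
            raise ValueError(f"no phenotypes at site {site!r}")
    ids = df["individual"].astype(str).tolist()
    k = _align_kinship(kinship, ids)
    y = df[trait].to_numpy(dtype=float)
    x = np.ones((len(df), 1))
    z_block, blocks = _indicator(df["block"].to_numpy())
    z_iid, names = [], ["sigma2_a"]
    if len(blocks) > 1:
        z_iid.append(z_block)
        names.append("sigma2_sb")
    else:
        logger.warning("single block level; block term dropped")
    names.append("sigma2_e")

    eng, s2, ll, conv, ses, cov = _fit_reml(y, x, k, z_iid, tuple(names))
    beta, vinv_r = eng.solution(s2)
    ebv = s2[0] * (k @ vinv_r)
    vc = VarianceComponents(
        sigma2_a=float(s2[0]),
        sigma2_sb=float(s2[1]) if len(z_iid) else None,
        sigma2_sa=None,
        sigma2_e=float(s2[-1]),
        standard_errors=ses,
        covariance=cov,
        names=tuple(names),
    )
    if not conv:
        logger.warning("single-site REML did not converge for trait %s", trait)
    scope = str(site) if site is not None else "single-site"
    return ModelFit(
        variance_components=vc,
        fixed_effects=pd.Series(beta, index=["mean"]),
        ebv=pd.Series(ebv, index=ids),
        log_likelihood=float(ll),
        converged=conv,
        relationship_flavor=kinship.flavor,
        model="single_site",
        trait=trait,
        scope=scope,
    )


def heritability(fit: ModelFit) -> tuple[float, float]:
    """Narrow-sense heritability with a delta-method standard error.

    Multi-site: h² = σ²_a / (σ²_a + σ²_sa + σ²_e); single-site:
    h² = σ²_a / (σ²_a + σ²_e).  Block variance is excluded in both, as in
    standard forest-genetics practice.
    """
    vc = fit.variance_components
    names = list(vc.names)
    vals = {"sigma2_a": vc.sigma2_a, "sigma2_sb": vc.sigma2_sb,
            "sigma2_sa": vc.sigma2_sa, "sigma2_e": vc.sigma2_e}
    if fit.model == "multi_site":
        denom_terms = ["sigma2_a", "sigma2_sa", "sigma2_e"]
    else:
        denom_terms = ["sigma2_a", "sigma2_e"]
    denom = sum(vals[t] for t in denom_terms)
    if denom <= 0:
        raise ValueError("all variance components are zero; heritability undefined")
    h2 = vals["sigma2_a"] / denom
    se = float("nan")
    if vc.covariance is not None:
        grad = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == "sigma2_a":
                grad[i] = (denom - vals["sigma2_a"]) / denom**2
            elif nm in denom_terms:
                grad[i] = -vals["sigma2_a"] / denom**2
        var_h2 = float(grad @ vc.covariance @ grad)
        se = float(np.sqrt(var_h2)) if var_h2 > 0 else float("nan")
    return float(h2), se


def extract_ebv(fit: ModelFit) -> pd.DataFrame:
    """Tidy table of EBVs with trait, relationship flavor and scope."""
    return pd.DataFrame(
        {
            "individual": fit.ebv.index,
            "trait": fit.trait,
            "ebv": fit.ebv.to_numpy(),
            "flavor": fit.relationship_flavor,
            "scope": fit.scope,
        }
    )
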