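"""REML mixed models: likelihood correctness, parameter recovery,
heritability and EBV contracts."""

import numpy as np
import pandas as pd
import pytest

import halfsibgs as h
from halfsibgs.mixedmodels import DesignError, VarianceComponents, ModelFit


def _parametric_multisite(seed, s2a=1.0, s2sb=0.3, s2sa=0.5, s2e=2.0,
                          n_families=25, n_off=14, n_sites=3):
    """Simulate straight from the multi-site model's own covariance structure."""
    cfg = h.SimConfig(n_families=n_families, n_offspring_per_family_site=n_off,
                      n_sites=n_sites, seed=seed, n_snps=10, n_qtl=1)
    ped = h.simulate_pedigree(cfg)
    rng = np.random.default_rng(seed)
    a_mat = h.pedigree_A_halfsib(ped)
    chol = np.linalg.cholesky(a_mat.values + 1e-10 * np.eye(len(a_mat.ids)))
    a = chol @ rng.standard_normal(len(a_mat.ids)) * np.sqrt(s2a)
    blocks = ped["block"].to_numpy()
    beff = dict(zip(pd.unique(blocks), rng.normal(0, np.sqrt(s2sb), blocks.size)))
    sxf = (ped["site"] + ":" + ped["family"]).to_numpy()
    saeff = dict(zip(pd.unique(sxf), rng.normal(0, np.sqrt(s2sa), sxf.size)))
    site_shift = {s: i * 1.0 for i, s in enumerate(pd.unique(ped["site"]))}
    y = (np.array([site_shift[s] for s in ped["site"]])
         + np.array([beff[b] for b in blocks]) + a
         + np.array([saeff[x] for x in sxf])
         + rng.normal(0, np.sqrt(s2e), len(ped)))
    out = ped.copy()
    out["Y"] = y
    return out, a_mat, a


def _dense_restricted_loglik(y, x, v):
    """Brute-force REML objective by dense inversion (oracle)."""
    n, p = x.shape
    vi = np.linalg.inv(v)
    _, ldv = np.linalg.slogdet(v)
    xvx = x.T @ vi @ x
    _, ldx = np.linalg.slogdet(xvx)
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldv + ldx + r @ vi @ r)


class TestMultiSite:
    def test_parametric_recovery_within_two_se(self):
        truth = {"sigma2_a": 1.0, "sigma2_sb": 0.3, "sigma2_sa": 0.5, "sigma2_e": 2.0}
        zs = []
        for seed in range(5):
            pheno, a_mat, _ = _parametric_multisite(seed)
            fit = h.fit_multi_site(pheno, None, a_mat, "Y")
            vc = fit.variance_components
            est = {"sigma2_a": vc.sigma2_a, "sigma2_sb": vc.sigma2_sb,
                   "sigma2_sa": vc.sigma2_sa, "sigma2_e": vc.sigma2_e}
            for name, tv in truth.items():
                zs.append(abs(est[name] - tv) / vc.standard_errors[name])
        # ~95% of z-scores should fall inside 2; allow a couple of excursions
        assert np.mean(np.asarray(zs) <= 2.0) >= 0.8

    def test_zero_additive_variance_hits_boundary(self):
        pheno, a_mat, _ = _parametric_multisite(7, s2a=0.0)
        fit = h.fit_multi_site(pheno, None, a_mat, "Y")
        total = (fit.variance_components.sigma2_a
                 + fit.variance_components.sigma2_e)
        assert fit.variance_components.sigma2_a / total < 0.1

    def test_loglik_matches_dense_oracle(self):
        pheno, a_mat, _ = _parametric_multisite(3, n_families=10, n_off=6, n_sites=2)
        assert len(pheno) <= 200
        fit = h.fit_multi_site(pheno, None, a_mat, "Y")
        vc = fit.variance_components
        sites = pd.get_dummies(pheno["site"]).to_numpy(float)
        x = np.column_stack([np.ones(len(pheno)), sites[:, 1:]])
        zb = pd.get_dummies(pheno["block"]).to_numpy(float)
        zs = pd.get_dummies(pheno["site"] + ":" + pheno["family"]).to_numpy(float)
        v = (vc.sigma2_a * a_mat.values + vc.sigma2_sb * zb @ zb.T
             + vc.sigma2_sa * zs @ zs.T + vc.sigma2_e * np.eye(len(pheno)))
        oracle = _dense_restricted_loglik(pheno["Y"].to_numpy(), x, v)
        assert fit.log_likelihood == pytest.approx(oracle, abs=1e-6)

    def test_needs_two_sites(self, family_panel):
        a_mat = h.pedigree_A_halfsib(family_panel["pedigree"])
        with pytest.raises(DesignError, match="2 sites"):
            h.fit_multi_site(
                family_panel["phenotypes"], family_panel["pedigree"], a_mat, "HT"
            )


class TestSingleSite:
    def test_single_block_dropped_with_warning(self, family_panel, caplog):
        g = h.vanraden_G(family_panel["genotypes"])
        with caplog.at_level("WARNING", logger="halfsibgs"):
            fit = h.fit_single_site(
                family_panel["phenotypes"], family_panel["pedigree"], g, "HT"
            )
        assert "block term dropped" in caplog.text
        assert fit.variance_components.sigma2_sb is None

    def test_h2_recovery(self, family_panel):
        g = h.vanraden_G(family_panel["genotypes"])
        fit = h.fit_single_site(
            family_panel["phenotypes"], family_panel["pedigree"], g, "HT"
        )
        h2, se = h.heritability(fit)
        assert abs(h2 - 0.5) < 0.15
        assert 0 < se < 0.3

    def test_flavor_follows_kinship(self, family_panel):
        a_mat = h.pedigree_A_halfsib(family_panel["pedigree"])
        g = h.vanraden_G(family_panel["genotypes"])
        fa = h.fit_single_site(family_panel["phenotypes"], family_panel["pedigree"], a_mat, "HT")
        fg = h.fit_single_site(family_panel["phenotypes"], family_panel["pedigree"], g, "HT")
        assert fa.relationship_flavor == "pedigree"
        assert fg.relationship_flavor == "genomic"
        assert len(fa.ebv) == len(fg.ebv)


class TestHeritability:
    def _fit(self, model, **vals):
        vc = VarianceComponents(
            sigma2_a=vals.get("a", 0.0), sigma2_e=vals.get("e", 0.0),
            sigma2_sb=vals.get("sb"), sigma2_sa=vals.get("sa"),
            names=tuple(), covariance=None,
        )
        return ModelFit(vc, pd.Series(dtype=float), pd.Series(dtype=float),
                        0.0, True, "pedigree", model)

    def test_single_site_formula(self):
        h2, _ = h.heritability(self._fit("single_site", a=0.5, e=0.5))
        assert h2 == pytest.approx(0.5)

    def test_multi_site_formula_includes_interaction(self):
        h2, _ = h.heritability(self._fit("multi_site", a=0.2, sa=0.2, e=0.6))
        assert h2 == pytest.approx(0.2)

    def test_zero_additive(self):
        h2, _ = h.heritability(self._fit("single_site", a=0.0, e=1.0))
        assert h2 == 0.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            h.heritability(self._fit("single_site", a=0.0, e=0.0))


class TestEBV:
    def test_sum_near_zero_in_balanced_design(self, family_panel):
        g = h.vanraden_G(family_panel["genotypes"])
        fit = h.fit_single_site(
            family_panel["phenotypes"], family_panel["pedigree"], g, "HT"
        )
        ebv = fit.ebv.to_numpy()
        assert abs(ebv.mean()) < 0.05 * ebv.std()

    def test_correlates_with_truth(self, family_panel):
        g = h.vanraden_G(family_panel["genotypes"])
        fit = h.fit_single_site(
            family_panel["phenotypes"], family_panel["pedigree"], g, "HT"
        )
        tbv = family_panel["truth"].true_breeding_values["HT"][:, 0]
        r = np.corrcoef(fit.ebv.to_numpy(), tbv)[0, 1]
        assert r > 0.5

    def test_extract_table_shape(self, family_panel):
        a_mat = h.pedigree_A_halfsib(family_panel["pedigree"])
        fit = h.fit_single_site(
            family_panel["phenotypes"], family_panel["pedigree"], a_mat, "HT",
            site="site1",
        )
        tab = h.extract_ebv(fit)
        assert list(tab.columns) == ["individual", "trait", "ebv", "flavor", "scope"]
        assert (tab["flavor"] == "pedigree").all()
        assert (tab["scope"] == "site1").all()


def test_ablup_inflates_h2_with_hidden_fullsibs():
    """Pedigree-assumption violations push ABLUP heritability above GBLUP."""
    diffs = []
    for seed in range(4):
        cfg = h.SimConfig(n_families=20, n_offspring_per_family_site=20, n_sites=1,
                          n_snps=1200, n_qtl=120, h2_target=0.4,
                          fullsib_fraction=0.55, missing_rate=0.0, seed=60 + seed)
        ped = h.simulate_pedigree(cfg)
        geno = h.simulate_genotypes(ped, cfg)
        pheno, _ = h.simulate_phenotypes(geno, ped, cfg, traits=("HT",))
        a_mat = h.pedigree_A_halfsib(ped)
        g = h.vanraden_G(geno)
        ha, _ = h.heritability(h.fit_single_site(pheno, ped, a_mat, "HT"))
        hg, _ = h.heritability(h.fit_single_site(pheno, ped, g, "HT"))
        diffs.append(ha - hg)
    assert np.mean(diffs) > 0
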