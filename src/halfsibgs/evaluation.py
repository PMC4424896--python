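"""Cross-validation of genomic prediction and type-b genetic correlation.

Four validation scenarios, mirroring multi-site progeny-trial practice:

* ``within_site`` — k-fold CV inside one site, validated against that
  site's single-site EBVs (SSEBV);
* ``cross_site`` — train on all trees of one site, validate on all trees of
  another, for every ordered site pair; replicate spread comes from
  refitting on random 90% subsamples of the training site;
* ``multi_site`` — k-fold CV on the pooled population against multi-site
  EBVs (MSEBV);
* ``multi_to_single`` — train on the pooled population, validate each site
  against its SSEBV.  By default the target site's trees are excluded from
  training (leakage-free); ``allow_leakage=True`` trains on everything.

Accuracy is the Pearson correlation between concatenated validation GEBVs
and the EBV of the same trees, one value per replicate.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gsmodels import fit_rrblup, fit_grr, predict_gebv

logger = logging.getLogger("halfsibgs")

SCENARIOS = ("within_site", "cross_site", "multi_site", "multi_to_single")


@dataclass
class CVResult:
    scenario: str
    trait: str
    method: str
    accuracies: np.ndarray           # one per replicate (or site/pair label)
    mean_accuracy: float
    standard_error: float
    n_replicates: int
    fold_assignments: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)  # e.g. site or pair names
    per_label: pd.DataFrame | None = None


def make_folds(n: int, k: int, reps: int, seed: int) -> np.ndarray:
    """Random k-fold partitions: array (reps, n) of fold ids 0..k-1 with
    fold sizes differing by at most one, reproducible from the seed."""
    if k > n:
        raise ValueError(f"cannot split n={n} into k={k} folds")
    rng = np.random.default_rng(seed)
    base = np.arange(n) % k
    out = np.empty((reps, n), dtype=int)
    for r in range(reps):
        out[r] = rng.permutation(base)
    return out


def prediction_accuracy(gebv: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation of predicted GEBVs with EBVs."""
    gebv = np.asarray(gebv, float)
    ebv = np.asarray(ebv, float)
    if gebv.size != ebv.size:
        raise ValueError("length mismatch")
    if np.std(gebv) == 0 or np.std(ebv) == 0:
        logger.warning("zero variance in accuracy computation; returning nan")
        return float("nan")
    return float(np.corrcoef(gebv, ebv)[0, 1])


def _fitter(method: str):
    if method == "rrblup":
        return fit_rrblup
    if method == "grr":
        return fit_grr
    raise ValueError(f"unknown GS method {method!r}; use 'rrblup' or 'grr'")


def _kfold_cv(
    y: np.ndarray, geno_values: np.ndarray, method: str, k: int, reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    n = y.size
    if k > n:
        logger.warning("k=%d larger than n=%d; reducing", k, n)
        k = n
    folds = make_folds(n, k, reps, seed)
    fit = _fitter(method)
    accs = np.empty(reps)
    for r in range(reps):
        pred = np.empty(n)
        for f in range(k):
            val = folds[r] == f
            model = fit(y[~val], geno_values[~val])
            pred[val] = predict_gebv(model, geno_values[val])
        accs[r] = prediction_accuracy(pred, y)
    return accs, folds


def run_scenario(
    scenario: str,
    ebv_tables: dict[str, pd.Series] | pd.Series,
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    method: str = "rrblup",
    trait: str = "",
    k: int = 10,
    reps: int = 20,
    seed: int = 0,
    site: str | None = None,
    allow_leakage: bool = False,
) -> CVResult:
    """Run one validation scenario.

    ``ebv_tables`` maps scope → EBV Series indexed by individual:
    key "multi-site" for MSEBV and one key per site name for SSEBV
    (a bare Series is accepted for single-scope scenarios).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if isinstance(ebv_tables, pd.Series):
        ebv_tables = {"multi-site" if scenario == "multi_site" else "default": ebv_tables}
    ids = genotypes.individual_ids
    id_pos = {iid: i for i, iid in enumerate(ids)}
    ped = pedigree.drop_duplicates("individual").set_index("individual")
    site_of = ped.loc[ids, "site"].astype(str).to_numpy()
    sites = list(pd.unique(site_of))
    values = genotypes.values
    fit = _fitter(method)

    def _scoped(scope: str) -> pd.Series:
        if scope in ebv_tables:
            return ebv_tables[scope]
        if "default" in ebv_tables:
            return ebv_tables["default"]
        raise ValueError(f"no EBV table for scope {scope!r}")

    if scenario == "within_site":
        targets = [site] if site is not None else sites
        rows, fold_store = [], None
        for s in targets:
            in_site = site_of == s
            ebv = _scoped(s)
            idx = [i for i in np.flatnonzero(in_site) if ids[i] in ebv.index]
            y = ebv.loc[[ids[i] for i in idx]].to_numpy()
            accs, folds = _kfold_cv(
                y, values[idx], method, k, reps,
                seed + zlib.crc32(str(s).encode()) % 10_000,
            )
            fold_store = folds
            rows.append((s, accs))
        accs = np.concatenate([a for _, a in rows])
        per_label = pd.DataFrame(
            {
                "label": [s for s, a in rows for _ in a],
                "accuracy": accs,
            }
        )
        labels = [s for s, _ in rows]
        return _summarize(scenario, trait, method, accs, per_label, labels, fold_store)

    if scenario == "cross_site":
        rng = np.random.default_rng(seed)
        rows = []
        for s_train in sites:
            for s_val in sites:
                if s_train == s_val:
                    continue
                tr = np.flatnonzero(site_of == s_train)
                va = np.flatnonzero(site_of == s_val)
                ebv_tr = _scoped(s_train)
                ebv_va = _scoped(s_val)
                tr = [i for i in tr if ids[i] in ebv_tr.index]
                va = [i for i in va if ids[i] in ebv_va.index]
                y_tr_full = ebv_tr.loc[[ids[i] for i in tr]].to_numpy()
                y_va = ebv_va.loc[[ids[i] for i in va]].to_numpy()
                pair_acc = np.empty(reps)
                n_sub = max(2, int(round(0.9 * len(tr))))
                for r in range(reps):
                    sub = rng.choice(len(tr), size=n_sub, replace=False)
                    model = fit(y_tr_full[sub], values[np.asarray(tr)[sub]])
                    pred = predict_gebv(model, values[va])
                    pair_acc[r] = prediction_accuracy(pred, y_va)
                rows.append((f"{s_train}->{s_val}", pair_acc))
        accs = np.concatenate([a for _, a in rows])
        per_label = pd.DataFrame(
            {"label": [lbl for lbl, a in rows for _ in a], "accuracy": accs}
        )
        return _summarize(scenario, trait, method, accs, per_label, [l for l, _ in rows], None)

    if scenario == "multi_site":
        ebv = _scoped("multi-site")
        idx = [i for i in range(len(ids)) if ids[i] in ebv.index]
        y = ebv.loc[[ids[i] for i in idx]].to_numpy()
        accs, folds = _kfold_cv(y, values[idx], method, k, reps, seed)
        return _summarize(scenario, trait, method, accs, None, [], folds)

    # multi_to_single
    rng = np.random.default_rng(seed)
    rows = []
    for s in sites:
        ebv_s = _scoped(s)
        va = [i for i in range(len(ids)) if site_of[i] == s and ids[i] in ebv_s.index]
        if allow_leakage:
            tr = list(range(len(ids)))
        else:
            tr = [i for i in range(len(ids)) if site_of[i] != s]
        ebv_ms = _scoped("multi-site")
        tr = [i for i in tr if ids[i] in ebv_ms.index]
        y_tr_full = ebv_ms.loc[[ids[i] for i in tr]].to_numpy()
        y_va = ebv_s.loc[[ids[i] for i in va]].to_numpy()
        site_acc = np.empty(reps)
        n_sub = max(2, int(round(0.9 * len(tr))))
        for r in range(reps):
            sub = rng.choice(len(tr), size=n_sub, replace=False)
            model = fit(y_tr_full[sub], values[np.asarray(tr)[sub]])
            pred = predict_gebv(model, values[va])
            site_acc[r] = prediction_accuracy(pred, y_va)
        rows.append((s, site_acc))
    accs = np.concatenate([a for _, a in rows])
    per_label = pd.DataFrame(
        {"label": [lbl for lbl, a in rows for _ in a], "accuracy": accs}
    )
    return _summarize(scenario, trait, method, accs, per_label, [l for l, _ in rows], None)


def _summarize(scenario, trait, method, accs, per_label, labels, folds) -> CVResult:
    accs = np.asarray(accs, float)
    ok = accs[~np.isnan(accs)]
    return CVResult(
        scenario=scenario,
        trait=trait,
        method=method,
        accuracies=accs,
        mean_accuracy=float(ok.mean()) if ok.size else float("nan"),
        standard_error=float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else float("nan"),
        n_replicates=int(accs.size),
        fold_assignments=folds,
        labels=labels,
        per_label=per_label,
    )


def truth_referenced_site_accuracy(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    genotypes: GenotypeMatrix,
    kinship,
    trait: str,
    true_bv: dict[str, pd.Series],
    k: int = 5,
    reps: int = 2,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulation benchmark: within-site vs cross-site prediction accuracy
    scored against *known* true breeding values.

    Unlike :func:`run_scenario` (which follows field practice and validates
    against EBVs from a single all-data fit), this routine refits the
    single-site mixed model on the training individuals of every fold, so no
    validation phenotype leaks into the training response, and correlates
    validation GEBVs with the simulator's true breeding values.  That makes
    within-site and cross-site accuracies directly comparable: when the
    across-site genetic correlation is 1, the two coincide up to Monte Carlo
    error.  Returns (mean within-site accuracy, mean cross-site accuracy).

    ``true_bv`` maps site name -> Series of true breeding values (indexed by
    individual) *at that site*.
    """
    from .mixedmodels import fit_single_site

    ids = np.array(genotypes.individual_ids)
    ped = pedigree.drop_duplicates("individual").set_index("individual")
    site_of = ped.loc[ids, "site"].astype(str).to_numpy()
    sites = list(pd.unique(site_of))
    values = genotypes.values
    rng = np.random.default_rng(seed)

    within = []
    for s in sites:
        idx = np.flatnonzero(site_of == s)
        tv = true_bv[s].loc[ids[idx]].to_numpy()
        folds = make_folds(len(idx), k, reps, seed)
        for r in range(reps):
            pred = np.empty(len(idx))
            for f in range(k):
                val = folds[r] == f
                ph_tr = phenotypes[phenotypes["individual"].isin(ids[idx[~val]])]
                fit = fit_single_site(ph_tr, pedigree, kinship, trait, site=s)
                y = fit.ebv.loc[ids[idx[~val]]].to_numpy()
                model = fit_rrblup(y, values[idx[~val]])
                pred[val] = predict_gebv(model, values[idx[val]])
            within.append(prediction_accuracy(pred, tv))

    cross = []
    for s_tr in sites:
        for s_va in sites:
            if s_tr == s_va:
                continue
            tr = np.flatnonzero(site_of == s_tr)
            va = np.flatnonzero(site_of == s_va)
            tv = true_bv[s_va].loc[ids[va]].to_numpy()
            for r in range(reps):
                sub = np.sort(rng.choice(len(tr), max(2, int(0.9 * len(tr))), replace=False))
                ph_tr = phenotypes[phenotypes["individual"].isin(ids[tr[sub]])]
                fit = fit_single_site(ph_tr, pedigree, kinship, trait, site=s_tr)
                y = fit.ebv.loc[ids[tr[sub]]].to_numpy()
                model = fit_rrblup(y, values[tr[sub]])
                pred = predict_gebv(model, values[va])
                cross.append(prediction_accuracy(pred, tv))
    return float(np.nanmean(within)), float(np.nanmean(cross))


def type_b_correlation(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame | None,
    site_i: str,
    site_j: str,
    trait: str,
) -> float:
    """Burdon-style type-b additive genetic correlation between two sites.

    The trait at each site is treated as a separate trait; the correlation
    is estimated from open-pollinated family (co)variances:
    r_B = cov_fam(i, j) / sqrt(var_fam(i) · var_fam(j)), with the per-site
    family variance from a one-way ANOVA (method of moments) and the
    cross-site family covariance from family means (family-mean noise is
    independent across sites, so the covariance needs no correction).
    Clamped to [-1, 1].
    """
    df = phenotypes.copy()
    if pedigree is not None and "family" not in df.columns:
        df = df.merge(pedigree, on="individual", how="left")
    df = df.dropna(subset=[trait])

    def _site_stats(s):
        sub = df[df["site"].astype(str) == str(s)]
        grp = sub.groupby("family")[trait]
        means = grp.mean()
        counts = grp.size()
        # one-way ANOVA method of moments for the between-family component
        grand = sub[trait].mean()
        n_tot = counts.sum()
        f = len(counts)
        ss_b = float((counts * (means - grand) ** 2).sum())
        ss_w = float(((sub[trait] - means.loc[sub["family"]].to_numpy()) ** 2).sum())
        ms_b = ss_b / max(f - 1, 1)
        ms_w = ss_w / max(n_tot - f, 1)
        n0 = (n_tot - float((counts**2).sum()) / n_tot) / max(f - 1, 1)
        var_fam = max((ms_b - ms_w) / max(n0, 1e-12), 0.0)
        return means, var_fam

    means_i, var_i = _site_stats(site_i)
    means_j, var_j = _site_stats(site_j)
    shared = means_i.index.intersection(means_j.index)
    dropped = set(means_i.index).symmetric_difference(means_j.index)
    if dropped:
        logger.warning("families present at only one site excluded: %s", sorted(dropped)[:5])
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} families shared between sites; need >= 3")
    cov = float(np.cov(means_i.loc[shared], means_j.loc[shared])[0, 1])
    if var_i <= 0 or var_j <= 0:
        logger.warning("zero family variance at a site; type-b undefined, returning nan")
        return float("nan")
    return float(np.clip(cov / np.sqrt(var_i * var_j), -1.0, 1.0))
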