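"""Multi-trait genomic selection via PCA on breeding values.

Correlated trait EBVs are distilled into orthogonal principal components
(correlation-matrix PCA, since traits sit on different scales); a
component's scores then serve as a composite phenotype in the standard
RR-BLUP cross-validation machinery.  Components whose loadings carry the
same sign for traits that are antagonistic on PC1 expose concurrent
selection opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import CVResult, run_scenario
from .genotypes import GenotypeMatrix


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # trait × component
    scores: pd.DataFrame            # individual × component
    variance_fractions: np.ndarray  # per component, sums to 1
    loading_pvalues: pd.DataFrame   # trait × component


def pca_on_ebv(ebv_table: pd.DataFrame, traits: list[str]) -> PCAResult:
    """PCA of standardized EBVs.

    ``ebv_table`` is wide (one column per trait, indexed by individual) or
    tidy with columns individual/trait/ebv.  Loadings are signed so each
    component's largest-magnitude loading is positive; loading significance
    is the exact t-test of the trait-EBV vs component-score correlation.
    """
    if {"individual", "trait", "ebv"}.issubset(ebv_table.columns):
        wide = ebv_table.pivot(index="individual", columns="trait", values="ebv")
    else:
        wide = ebv_table
    missing = [t for t in traits if t not in wide.columns]
    if missing:
        raise ValueError(f"EBV table lacks traits {missing}")
    if len(traits) < 2:
        raise ValueError("PCA needs at least two traits")
    x = wide[traits].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("EBV table must be complete (no missing EBVs)")
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"constant EBV column(s): {bad}")
    xs = (x - x.mean(axis=0)) / sd
    n = xs.shape[0]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    # orient: largest-|loading| entry of each component positive
    for c in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[c]))
        if vt[c, lead] < 0:
            vt[c] *= -1.0
            u[:, c] *= -1.0
    scores = u * s
    var = s**2
    fractions = var / var.sum()
    comp_names = [f"PC{c + 1}" for c in range(len(s))]
    load = pd.DataFrame(vt.T, index=traits, columns=comp_names)
    sc = pd.DataFrame(scores, index=wide.index, columns=comp_names)
    pvals = np.empty((len(traits), len(s)))
    for ti in range(len(traits)):
        for c in range(len(s)):
            if scores[:, c].std() == 0:
                pvals[ti, c] = 1.0
            else:
                pvals[ti, c] = stats.pearsonr(xs[:, ti], scores[:, c]).pvalue
    return PCAResult(
        loadings=load,
        scores=sc,
        variance_fractions=fractions,
        loading_pvalues=pd.DataFrame(pvals, index=traits, columns=comp_names),
    )


def gs_on_scores(
    pca: PCAResult,
    component: str | int,
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    scenario: str = "multi_site",
    method: str = "rrblup",
    k: int = 10,
    reps: int = 20,
    seed: int = 0,
) -> CVResult:
    """Cross-validated genomic prediction of a principal-component score."""
    if isinstance(component, int):
        if not 1 <= component <= pca.scores.shape[1]:
            raise ValueError(
                f"component {component} out of range 1..{pca.scores.shape[1]}"
            )
        component = f"PC{component}"
    if component not in pca.scores.columns:
        raise ValueError(f"no component {component!r} in PCA result")
    response = pca.scores[component]
    shared = [i for i in genotypes.individual_ids if i in response.index]
    geno = genotypes.subset_individuals(
        np.array([genotypes.individual_ids.index(i) for i in shared])
    )
    result = run_scenario(
        scenario,
        {"multi-site": response.loc[shared]},
        geno,
        pedigree,
        method=method,
        trait=component,
        k=k,
        reps=reps,
        seed=seed,
    )
    result.trait = component
    return result
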