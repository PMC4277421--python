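"""Per-marker retrospective score test for related individuals.

For site *l* with genotype-score vector ``g_l`` (minor-allele counts), trait
residuals ``r`` and founder minor-allele frequency ``p_l``, the statistic is

    T_l = (r' g_l)^2 / (2 p_l (1 - p_l) * r' Phi r)

where ``Phi`` is the genetic-correlation matrix (entries ``2 phi_ij``).
Phenotypes are treated as fixed and genotypes as random (a retrospective
view, robust to ascertainment through affected members); under the null of
no association ``T_l`` is approximately chi-squared with 1 degree of
freedom.  The denominator scalar ``r' Phi r`` does not depend on genotypes
and is computed once, then reused across sites and permutation replicates.

Sites monomorphic in founders (``p_l = 0``) are untestable: they are flagged
``valid=False`` and assigned P-value 1, and downstream score combination
ignores them.

Genotype centring by ``2 p_l`` is omitted: residuals from any model that
includes an intercept sum to zero, so a constant shift of ``g_l`` leaves
``r' g_l`` unchanged (asserted by test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateTraitError, EstimationError, PedigreeStructureError
from .kinship import KinshipModel
from .pedio import HaplotypeSet, Pedigree, TraitTable

__all__ = [
    "ResidualVector",
    "SiteTestResult",
    "covariate_residuals",
    "founder_maf",
    "site_statistics",
    "site_pvalues_from_scores",
    "results_table",
]


@dataclass
class ResidualVector:
    """Trait residuals after covariate adjustment, pedigree-aligned."""

    residuals: np.ndarray


@dataclass
class SiteTestResult:
    site_id: str
    statistic: float
    pvalue: float
    founder_maf: float
    valid: bool


def covariate_residuals(traits: TraitTable) -> ResidualVector:
    """Ordinary-least-squares residuals of the trait on covariates.

    An intercept is always included, so with no covariates the residuals are
    the mean-centred trait.  The same linear adjustment is applied to
    dichotomous (0/1) and continuous traits.

    Raises
    ------
    DegenerateTraitError
        If the trait is constant.
    EstimationError
        If the covariate matrix (with intercept) is rank deficient.
    """
    y = np.asarray(traits.trait, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateTraitError("trait is constant; nothing to test")
    if traits.covariates is None:
        return ResidualVector(residuals=y - y.mean())
    X = np.column_stack([np.ones_like(y), traits.covariates])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError(
            "covariate matrix (with intercept) is rank deficient"
        )
    r = y - X @ beta
    if np.linalg.norm(r) <= 1e-10 * max(1.0, np.linalg.norm(y)):
        raise DegenerateTraitError(
            "trait is fully explained by the covariates; no residual variation"
        )
    return ResidualVector(residuals=r)


def founder_maf(hap: HaplotypeSet, ped: Pedigree) -> np.ndarray:
    """Minor-allele frequency per site, counted over founder haplotypes only."""
    f = np.asarray(ped.founder_indices, dtype=int)
    if f.size == 0:
        raise PedigreeStructureError("pedigree has no founders")
    return hap.haps[f].reshape(2 * f.size, hap.n_sites).mean(axis=0)


def site_pvalues_from_scores(
    numerators: np.ndarray,
    maf: np.ndarray,
    rt_phi_r: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised core: statistics and P-values from ``r' g_l`` numerators.

    ``numerators`` may be 1-D (one dataset) or 2-D ``(B, L)`` (a batch of
    permutation replicates).  Returns ``(T, pvalues, valid)`` with invalid
    (founder-monomorphic) sites set to ``T = 0``, ``p = 1``.
    """
    maf = np.asarray(maf, dtype=float)
    valid = (maf > 0.0) & (maf < 1.0)
    denom = np.where(valid, 2.0 * maf * (1.0 - maf) * rt_phi_r, 1.0)
    T = np.where(valid, np.asarray(numerators, float) ** 2 / denom, 0.0)
    pvals = np.where(valid, stats.chi2.sf(T, df=1), 1.0)
    return T, pvals, valid


def site_statistics(
    r: ResidualVector,
    hap: HaplotypeSet,
    ped: Pedigree,
    km: KinshipModel,
) -> list[SiteTestResult]:
    """Per-site score statistics and upper-tail chi2(1 df) P-values.

    Raises
    ------
    DegenerateTraitError
        If ``r' Phi r <= 0`` (no usable trait variation).
    """
    rv = np.asarray(r.residuals, dtype=float)
    rt_phi_r = km.quadratic_form(rv)
    if rt_phi_r <= 0:
        raise DegenerateTraitError("r' Phi r <= 0: degenerate residuals")
    maf = founder_maf(hap, ped)
    numer = rv @ hap.genotype_scores()
    T, pvals, valid = site_pvalues_from_scores(numer, maf, rt_phi_r)
    return [
        SiteTestResult(
            site_id=s.id,
            statistic=float(T[l]),
            pvalue=float(pvals[l]),
            founder_maf=float(maf[l]),
            valid=bool(valid[l]),
        )
        for l, s in enumerate(hap.sites)
    ]


def results_table(results: list[SiteTestResult]):
    """Per-site results as a pandas DataFrame (tab-delimited export ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            (r.site_id, r.founder_maf, r.statistic, r.pvalue, r.valid)
            for r in results
        ],
        columns=["site", "founder_maf", "statistic", "pvalue", "valid"],
    )
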