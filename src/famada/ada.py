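"""Adaptive combination of per-site P-values (the family ADA test).

Per-site P-values ``P_1 .. P_L`` (from :mod:`famada.sitetest`) are combined
into significance scores over a grid of truncation thresholds
``theta_1 < ... < theta_J``:

    S_j = sum_l ( -ln P_l ) * 1[ P_l < theta_j ]          (valid sites only)

so sites with large P-values — most likely neutral — are discarded from the
combined statistic, and the truncation threshold is chosen adaptively by the
data.  Because multiple thresholds are examined, significance is assessed by
permutation: ``B`` gene-dropping replicates (random transmission conditional
on founder genotypes, traits fixed) give the null distribution of every
``S_j``.  Each score is converted to a permutation P-value, the minimum over
thresholds (``MinP``) is taken for the observed data and for every
replicate, and the reported adjusted P-value is

    (1 + #{b : MinP^(b) <= MinP}) / (B + 1).

The residual vector, the kinship quadratic form ``r' Phi r`` and the founder
minor-allele frequencies are all invariant under gene-dropping and are
computed once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NoTestError
from .genedrop import (
    descent_indices,
    enumerate_transmissions,
    founder_haplotype_matrix,
    rng_from_seed,
)
from .kinship import KinshipModel, kinship_matrix
from .pedio import HaplotypeSet, Pedigree, TraitTable
from .sitetest import (
    covariate_residuals,
    founder_maf,
    site_pvalues_from_scores,
)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "AdaResult",
    "significance_scores",
    "ada_test",
]

#: default truncation-threshold grid
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))

_TRANSFORMS = {"ln": np.log, "log10": np.log10}


@dataclass
class AdaResult:
    """Observed and permutation quantities of one ADA region test."""

    thresholds: tuple[float, ...]
    scores: np.ndarray                 # observed S_j, shape (J,)
    per_threshold_pvalues: np.ndarray  # p(S_j), shape (J,)
    minp_observed: float
    adjusted_pvalue: float
    B: int
    n_sites: int
    n_valid_sites: int
    transform: str = "ln"
    perm_scores: np.ndarray | None = None  # (B, J)
    perm_minp: np.ndarray | None = None    # (B,)
    seed: int | None = None

    def summary_row(self, region: str = "region") -> str:
        """One-line tab-delimited summary."""
        return (
            f"{region}\t{self.n_sites}\t{self.n_valid_sites}\t{self.B}"
            f"\t{self.minp_observed:.6g}\t{self.adjusted_pvalue:.6g}"
        )

    def to_json(self, **extra) -> str:
        payload = {
            "thresholds": list(self.thresholds),
            "scores": self.scores.tolist(),
            "per_threshold_pvalues": self.per_threshold_pvalues.tolist(),
            "minp_observed": self.minp_observed,
            "adjusted_pvalue": self.adjusted_pvalue,
            "B": self.B,
            "n_sites": self.n_sites,
            "n_valid_sites": self.n_valid_sites,
            "transform": self.transform,
            "seed": self.seed,
            **extra,
        }
        return json.dumps(payload, indent=2)


def _check_thresholds(thresholds) -> np.ndarray:
    th = np.asarray(thresholds, dtype=float)
    if th.size == 0:
        raise ConfigurationError("empty truncation-threshold grid")
    if (th <= 0).any() or (th >= 1).any() or (np.diff(th) <= 0).any():
        raise ConfigurationError(
            "thresholds must be strictly increasing and inside (0, 1)"
        )
    return th


def significance_scores(
    pvalues: np.ndarray,
    valid: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
    transform: str = "ln",
) -> np.ndarray:
    """Scores ``S_j`` over the threshold grid (strict inequality ``P < theta``).

    ``pvalues`` may be ``(L,)`` or a batch ``(B, L)``; invalid sites never
    contribute.  Returns shape ``(J,)`` or ``(B, J)`` accordingly.
    """
    th = _check_thresholds(thresholds)
    log = _TRANSFORMS[transform]
    p = np.asarray(pvalues, dtype=float)
    v = np.broadcast_to(np.asarray(valid, bool), p.shape)
    # guard log(0) on sites that can never be selected
    weight = np.where(v & (p > 0), -log(np.where(p > 0, p, 1.0)), 0.0)
    weight = np.where(v & (p == 0), np.inf, weight)
    sel = v[..., :, None] & (p[..., :, None] < th)  # (..., L, J)
    return np.where(sel, weight[..., :, None], 0.0).sum(axis=-2)


def _rank_pvalues(all_scores: np.ndarray) -> np.ndarray:
    """Exchangeable per-threshold permutation P-values on a common scale.

    ``all_scores`` stacks the observed scores as row 0 over the ``B``
    replicate rows.  Each unit *x* (observed or replicate) gets
    ``p_x,j = #{y != x : S_y,j >= S_x,j} / B`` — every unit is compared
    against the *other* ``B`` units, so under the null all ``B + 1`` rank
    vectors are exchangeable and the min-P adjustment below is a valid
    permutation test.  For the observed row this reduces to the usual
    ``#{b : S_b >= S_obs} / B``.
    """
    B = all_scores.shape[0] - 1
    out = np.empty_like(all_scores, dtype=float)
    for j in range(all_scores.shape[1]):
        col = all_scores[:, j]
        srt = np.sort(col)
        below = np.searchsorted(srt, col, side="left")
        geq_including_self = (B + 1) - below
        out[:, j] = (geq_including_self - 1) / B
    return out


def ada_test(
    ped: Pedigree,
    hap: HaplotypeSet,
    traits: TraitTable,
    km: KinshipModel | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    transform: str = "ln",
    exhaustive: bool = False,
    early_stop_count: int | None = None,
    keep_permutations: bool = False,
) -> AdaResult:
    """Run the family ADA test on one region.

    Parameters
    ----------
    B
        Number of gene-dropping permutations (>= 100; the min-P step is
        meaningless below that).  Ignored when ``exhaustive`` is set.
    seed
        Integer seed or numpy Generator; required unless ``exhaustive``.
    exhaustive
        Replace Monte-Carlo permutation with exact enumeration of all
        ``4^m`` transmission patterns (small pedigrees only).  The adjusted
        P-value is then the exact probability
        ``P(MinP^(pattern) <= MinP_observed)`` with no ``+1`` smoothing.
    early_stop_count
        Optional sequential Monte-Carlo cap: stop permuting once the
        exceedance count for the observed ``MinP`` reaches this value
        (clearly non-significant regions finish early).  Off by default.

    Raises
    ------
    NoTestError
        If every site is monomorphic in founders.
    ConfigurationError
        For an invalid threshold grid or ``B < 100``.
    """
    th = _check_thresholds(thresholds)
    if km is None:
        km = kinship_matrix(ped)
    r = covariate_residuals(traits).residuals
    rt_phi_r = km.quadratic_form(r)

    maf = founder_maf(hap, ped)
    G = hap.genotype_scores().astype(float)
    T_obs, p_obs, valid = site_pvalues_from_scores(r @ G, maf, rt_phi_r)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise NoTestError("all sites are monomorphic in founders")
    S_obs = significance_scores(p_obs, valid, th, transform)

    if exhaustive:
        return _ada_exhaustive(
            ped, hap, r, maf, rt_phi_r, valid, S_obs, th, transform, n_valid
        )

    if B < 100:
        raise ConfigurationError("B must be >= 100")
    if seed is None:
        raise ConfigurationError("a seed is required for permutation")
    rng = rng_from_seed(seed)

    J = th.size
    S_perm = np.empty((0, J))
    chunk = B if early_stop_count is None else max(100, early_stop_count)
    done = 0
    # no recombination: a replicate is a founder-haplotype descent pattern,
    # so r' g_l per replicate is one scatter-add plus a small matmul
    FH = founder_haplotype_matrix(ped, hap.haps).astype(float)
    r2 = np.repeat(r, 2)
    while done < B:
        b = min(chunk, B - done)
        ids = descent_indices(ped, b, rng).reshape(b, -1)
        flat = (ids + (np.arange(b) * FH.shape[0])[:, None]).ravel()
        W = np.bincount(
            flat,
            weights=np.broadcast_to(r2, ids.shape).ravel(),
            minlength=b * FH.shape[0],
        ).reshape(b, FH.shape[0])
        numer = W @ FH
        _, p_b, _ = site_pvalues_from_scores(numer, maf, rt_phi_r)
        S_perm = np.vstack([S_perm, significance_scores(p_b, valid, th, transform)])
        done += b
        if early_stop_count is not None:
            # provisional exceedance of MinP on the replicates so far
            pv = _rank_pvalues(np.vstack([S_obs, S_perm]))
            if int(
                (pv[1:].min(axis=1) <= pv[0].min()).sum()
            ) >= early_stop_count:
                break
    B_eff = S_perm.shape[0]

    pv = _rank_pvalues(np.vstack([S_obs, S_perm]))
    per_threshold = pv[0]
    minp_obs = float(per_threshold.min())
    perm_minp = pv[1:].min(axis=1)
    adjusted = (1 + int((perm_minp <= minp_obs).sum())) / (B_eff + 1)

    return AdaResult(
        thresholds=tuple(th),
        scores=S_obs,
        per_threshold_pvalues=per_threshold,
        minp_observed=minp_obs,
        adjusted_pvalue=float(adjusted),
        B=B_eff,
        n_sites=hap.n_sites,
        n_valid_sites=n_valid,
        transform=transform,
        perm_scores=S_perm if keep_permutations else None,
        perm_minp=perm_minp if keep_permutations else None,
        seed=seed if isinstance(seed, int) else None,
    )


def _ada_exhaustive(
    ped, hap, r, maf, rt_phi_r, valid, S_obs, th, transform, n_valid
) -> AdaResult:
    """Exact-permutation ADA: all 4^m transmission patterns, equal weight."""
    m = len(ped.nonfounder_indices)
    P = 4**m
    # reuse the enumeration engine at genotype-score level
    dist = enumerate_transmissions(ped, hap, representation="genotype_score")
    nonf = ped.nonfounder_indices
    founders_part = np.zeros(hap.n_sites)
    fixed = np.delete(np.arange(ped.n), nonf)
    G = hap.genotype_scores().astype(float)
    founders_part = r[fixed] @ G[fixed]

    configs = np.array([c for c in dist], dtype=float)  # (C, m*L)
    probs = np.array([dist[c] for c in dist])
    g_nonf = configs.reshape(len(configs), m, hap.n_sites)
    numer = founders_part + np.einsum("i,cil->cl", r[nonf], g_nonf)
    _, p_c, _ = site_pvalues_from_scores(numer, maf, rt_phi_r)
    S_c = significance_scores(p_c, valid, th, transform)  # (C, J)

    per_threshold = np.array(
        [probs[S_c[:, j] >= S_obs[j]].sum() for j in range(th.size)]
    )
    minp_obs = float(per_threshold.min())
    # per-pattern P-values on the same exact scale (self included by law)
    pt_c = np.empty_like(S_c)
    for j in range(th.size):
        pt_c[:, j] = [probs[S_c[:, j] >= s].sum() for s in S_c[:, j]]
    minp_c = pt_c.min(axis=1)
    adjusted = float(probs[minp_c <= minp_obs].sum())
    return AdaResult(
        thresholds=tuple(th),
        scores=S_obs,
        per_threshold_pvalues=per_threshold,
        minp_observed=minp_obs,
        adjusted_pvalue=adjusted,
        B=P,
        n_sites=hap.n_sites,
        n_valid_sites=n_valid,
        transform=transform,
    )
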