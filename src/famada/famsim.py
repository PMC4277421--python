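"""Family sequence simulation and type-I error / power experiments.

The generator emulates the study conditions the method was evaluated under:

* a neutral haplotype pool from a single-tree coalescent with a fixed number
  of segregating sites (infinite-sites, no recombination);
* three-generation 12-member families (founders at template positions
  1, 2, 5 and 6): couple (1, 2) has children 3 and 4; founders 6 and 5 marry
  3 and 4; children 7-9 descend from (3, 6) and 10-12 from (4, 5);
* dichotomous traits by a multiplicative per-minor-allele penetrance model
  with baseline 0.05, genotype relative risks derived from per-locus
  population attributable risk (PAR) and population MAF;
* continuous traits as an additive QTL model calibrated so each QTL explains
  a stated fraction of the trait variance.

Five causal sites (Nos. 10, 20, 30, 40, 50; 1-based) are the default in
power designs; causal variants are *not* restricted to be rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ada import DEFAULT_THRESHOLDS, ada_test
from .errors import CalibrationError, ConfigurationError
from .genedrop import rng_from_seed
from .kinship import kinship_matrix
from .pedio import HaplotypeSet, Individual, Pedigree, Site, TraitTable

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "QtlModel",
    "ExperimentConfig",
    "coalescent_pool",
    "three_generation_template",
    "build_families",
    "simulate_families",
    "grr_from_par",
    "dichotomous_trait",
    "continuous_trait",
    "run_experiment",
]

DEFAULT_CAUSAL_SITES_1BASED = (10, 20, 30, 40, 50)


@dataclass
class HaplotypePool:
    """``H`` haplotypes over ``L`` segregating biallelic sites.

    ``maf`` is the pool *minor*-allele frequency per site; ``alt_freq`` is
    the frequency of allele code 1 (the derived allele), which may exceed
    0.5.
    """

    pool: np.ndarray  # (H, L) uint8
    alt_freq: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return self.pool.shape[0]

    @property
    def n_sites(self) -> int:
        return self.pool.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.alt_freq, 1.0 - self.alt_freq)

    def minor_allele_counts(self, haps: np.ndarray) -> np.ndarray:
        """Per-individual minor-allele counts for an ``(n, 2, L)`` array."""
        g = haps.sum(axis=1, dtype=np.int64)
        flip = self.alt_freq > 0.5
        g[:, flip] = 2 - g[:, flip]
        return g


def coalescent_pool(
    n_haplotypes: int,
    n_sites: int,
    rng: int | np.random.Generator,
) -> HaplotypePool:
    """Neutral haplotype pool from one coalescent genealogy, fixed-S mutations.

    A single random genealogy for ``n_haplotypes`` tips is built by
    successive pairwise coalescences with exponential waiting times of rate
    ``k (k - 1) / 2``.  Exactly ``n_sites`` mutations are placed on branches
    with probability proportional to branch length (root branch excluded),
    one infinite-sites mutation per site, so every site segregates in the
    pool.
    """
    H, L = int(n_haplotypes), int(n_sites)
    if H < 2:
        raise ConfigurationError("need at least 2 haplotypes")
    if L < 1:
        raise ConfigurationError("need at least 1 site")
    rng = rng_from_seed(rng)

    n_nodes = 2 * H - 1
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    birth = np.zeros(n_nodes)  # time the lineage above this node starts
    blen = np.zeros(n_nodes)
    ks = np.arange(H, 1, -1)
    waits = rng.exponential(1.0, size=H - 1) * 2.0 / (ks * (ks - 1.0))
    pick_i = rng.integers(0, ks)
    pick_j = rng.integers(0, ks - 1)
    pick_j = np.where(pick_j >= pick_i, pick_j + 1, pick_j)
    active = list(range(H))
    t = 0.0
    for step, nxt in enumerate(range(H, n_nodes)):
        t += waits[step]
        i, j = int(pick_i[step]), int(pick_j[step])
        a, b = active[i], active[j]
        blen[a] = t - birth[a]
        blen[b] = t - birth[b]
        children[nxt] = (a, b)
        birth[nxt] = t
        # swap-remove the two merged lineages, append the parent
        for idx in sorted((i, j), reverse=True):
            active[idx] = active[-1]
            active.pop()
        active.append(nxt)
    blen[active[0]] = 0.0  # root carries no mutations

    weights = blen[:-1]  # exclude root
    probs = weights / weights.sum()
    mut_nodes = rng.choice(weights.size, size=L, replace=True, p=probs)

    pool = np.zeros((H, L), dtype=np.uint8)

    def tips_below(node: int) -> list[int]:
        # iterative: carriers of a mutation = tips below its branch
        tips, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < H:
                tips.append(v)
            else:
                stack.extend(children[v])
        return tips

    for l, node in enumerate(mut_nodes):
        pool[tips_below(int(node)), l] = 1
    return HaplotypePool(pool=pool, alt_freq=pool.mean(axis=0))


def three_generation_template(family_id: str = "F1") -> Pedigree:
    """The three-generation 12-member family used throughout the simulations.

    Founders are members 1, 2, 5 and 6.  Members 3 and 4 are children of
    (1, 2); member 3 marries founder 6 and member 4 marries founder 5;
    members 7-9 are children of (3, 6) and 10-12 of (5, 4).
    """
    F = family_id

    def ind(iid, fat, mot, sex):
        return Individual(F, str(iid), fat and str(fat), mot and str(mot), sex)

    return Pedigree([
        ind(1, None, None, 1),
        ind(2, None, None, 2),
        ind(3, 1, 2, 1),
        ind(4, 1, 2, 2),
        ind(5, None, None, 1),
        ind(6, None, None, 2),
        ind(7, 3, 6, 1),
        ind(8, 3, 6, 2),
        ind(9, 3, 6, 1),
        ind(10, 5, 4, 2),
        ind(11, 5, 4, 1),
        ind(12, 5, 4, 2),
    ])


def build_families(n_families: int, template: Pedigree | None = None) -> Pedigree:
    """Replicate a single-family template into ``n_families`` disjoint families."""
    if template is None:
        template = three_generation_template()
    members: list[Individual] = []
    for f in range(n_families):
        fam = f"F{f + 1}"
        for m in template.members:
            members.append(Individual(fam, m.iid, m.father, m.mother, m.sex))
    return Pedigree(members)


def simulate_families(
    pool: HaplotypePool,
    n_families: int,
    rng: int | np.random.Generator,
    template: Pedigree | None = None,
) -> tuple[Pedigree, HaplotypeSet]:
    """Draw founder haplotypes from the pool and gene-drop the offspring.

    Each founder samples two haplotypes from the pool with replacement;
    every non-founder receives one full-length haplotype from each parent
    (no recombination), generation by generation.  Allele code 1 is the
    pool's derived allele; orient with the pool or via
    :func:`famada.pedio.orient_minor_allele` before frequency-sensitive use.
    """
    rng = rng_from_seed(rng)
    ped = build_families(n_families, template)
    n, L = ped.n, pool.n_sites
    haps = np.zeros((n, 2, L), dtype=np.uint8)
    founders = np.asarray(ped.founder_indices)
    draws = rng.integers(0, pool.n_haplotypes, size=(founders.size, 2))
    haps[founders] = pool.pool[draws]
    for i in ped.nonfounder_indices:
        fi, mi = ped.parent_indices(i)
        cf, cm = rng.integers(0, 2, size=2)
        haps[i, 0] = haps[fi, cf]
        haps[i, 1] = haps[mi, cm]
    sites = [Site(f"site{l + 1}", l + 1) for l in range(L)]
    return ped, HaplotypeSet(sites, haps)


# ---------------------------------------------------------------------------
# trait models
# ---------------------------------------------------------------------------


def grr_from_par(par: float, maf: float) -> float:
    """Genotype relative risk implied by a locus PAR and population MAF.

    GRR = PAR / (MAF * (1 - PAR)) + 1; strictly decreasing in MAF (rarer
    causal variants get larger effects) and increasing in PAR.
    """
    if not (0 < par < 1):
        raise ConfigurationError(f"PAR must be in (0, 1), got {par}")
    if not (0 < maf < 1):
        raise ConfigurationError(f"MAF must be in (0, 1), got {maf}")
    return par / (maf * (1.0 - par)) + 1.0


@dataclass
class DiseaseModel:
    """Multiplicative penetrance model for a dichotomous trait.

    ``causal_sites`` are 0-based site indices; ``grr_per_site`` multiplies
    the baseline penetrance once per minor allele carried at that site, and
    the product is clamped at 1.
    """

    causal_sites: tuple[int, ...]
    grr_per_site: tuple[float, ...]
    baseline_penetrance: float = 0.05

    def __post_init__(self):
        if len(self.causal_sites) != len(self.grr_per_site):
            raise ConfigurationError("one GRR per causal site required")
        if not (0 < self.baseline_penetrance <= 1):
            raise ConfigurationError("baseline penetrance must be in (0, 1]")

    @classmethod
    def null(cls, baseline_penetrance: float = 0.05) -> "DiseaseModel":
        """No causal site: everyone is affected with the baseline probability."""
        return cls((), (), baseline_penetrance)

    @classmethod
    def equal_par(
        cls,
        total_par: float,
        pool: HaplotypePool,
        causal_sites_1based=DEFAULT_CAUSAL_SITES_1BASED,
        baseline_penetrance: float = 0.05,
    ) -> "DiseaseModel":
        """Split a total PAR equally over the causal sites (default Nos.
        10, 20, 30, 40, 50), deriving each GRR from the pool MAF."""
        sites0 = tuple(s - 1 for s in causal_sites_1based)
        if max(sites0, default=-1) >= pool.n_sites:
            raise ConfigurationError("causal site index exceeds site count")
        par = total_par / len(sites0)
        grrs = tuple(grr_from_par(par, float(pool.maf[s])) for s in sites0)
        return cls(sites0, grrs, baseline_penetrance)

    def penetrance(self, haps: np.ndarray, pool: HaplotypePool) -> np.ndarray:
        """Per-individual disease probability: ``f0 * prod_j GRR_j ** c_j``
        (``c_j`` minor-allele count at causal site *j*), clamped at 1."""
        pen = np.full(haps.shape[0], self.baseline_penetrance)
        if self.causal_sites:
            g = pool.minor_allele_counts(haps)[:, list(self.causal_sites)]
            pen = pen * np.prod(np.asarray(self.grr_per_site) ** g, axis=1)
        return np.minimum(pen, 1.0)


def dichotomous_trait(
    haps: np.ndarray,
    model: DiseaseModel,
    pool: HaplotypePool,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Affection status (0/1) under the multiplicative penetrance model.

    Penetrance for an individual is ``f0 * prod_j GRR_j ** c_j`` with ``c_j``
    the minor-allele count at causal site ``j`` (pool-defined minor allele),
    clamped at 1; applied to founders and offspring alike.
    """
    rng = rng_from_seed(rng)
    pen = model.penetrance(haps, pool)
    return (rng.random(haps.shape[0]) < pen).astype(float)


@dataclass
class QtlModel:
    """Additive QTL model for a continuous trait.

    Trait = ``mu + sum_l G_il + eps_i``; the genotypic value ``G_il`` is
    Normal with mean ``+a_l``, 0 or ``-a_l`` for 2, 1 or 0 minor alleles and
    variance ``genotypic_sd**2`` (0 by default), ``eps ~ N(0, error_var)``.
    Effects ``a_l`` are calibrated from ``h2_per_site`` and the pool MAF
    under Hardy-Weinberg founder frequencies: the additive variance at a
    locus with minor-allele frequency ``p`` is ``2 p (1 - p) a**2``, and the
    total variance is ``error_var / (1 - sum h2)``.
    """

    causal_sites: tuple[int, ...]
    h2_per_site: tuple[float, ...]
    mean: float = 100.0
    error_var: float = 100.0
    genotypic_sd: float = 0.0

    def __post_init__(self):
        if len(self.causal_sites) != len(self.h2_per_site):
            raise ConfigurationError("one h2 per causal site required")
        if sum(self.h2_per_site) >= 1:
            raise ConfigurationError("total variance explained must be < 1")

    @classmethod
    def null(cls, mean: float = 100.0, error_var: float = 100.0) -> "QtlModel":
        return cls((), (), mean, error_var)

    @classmethod
    def equal_h2(
        cls,
        total_h2: float,
        n_qtl: int = 5,
        causal_sites_1based=DEFAULT_CAUSAL_SITES_1BASED,
        **kwargs,
    ) -> "QtlModel":
        sites0 = tuple(s - 1 for s in causal_sites_1based[:n_qtl])
        h2 = tuple([total_h2 / len(sites0)] * len(sites0))
        return cls(sites0, h2, **kwargs)

    def effects(self, pool: HaplotypePool) -> np.ndarray:
        """Per-QTL additive effects ``a_l`` matching the target h2 values."""
        h2 = np.asarray(self.h2_per_site, dtype=float)
        total_var = self.error_var / (1.0 - h2.sum())
        p = pool.maf[list(self.causal_sites)]
        if (p <= 0).any() or (p >= 1).any():
            raise CalibrationError("causal site not segregating in pool")
        var_l = h2 * total_var
        num = var_l - self.genotypic_sd**2
        if (num < 0).any():
            raise CalibrationError(
                "genotypic_sd too large for the requested h2"
            )
        return np.sqrt(num / (2.0 * p * (1.0 - p)))


def continuous_trait(
    haps: np.ndarray,
    model: QtlModel,
    pool: HaplotypePool,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Continuous trait under the additive QTL model (see :class:`QtlModel`)."""
    rng = rng_from_seed(rng)
    n = haps.shape[0]
    y = model.mean + rng.normal(0.0, np.sqrt(model.error_var), size=n)
    if model.causal_sites:
        a = model.effects(pool)
        g = pool.minor_allele_counts(haps)[:, list(model.causal_sites)]
        y = y + ((g - 1) * a).sum(axis=1)
        if model.genotypic_sd > 0:
            y = y + rng.normal(
                0.0, model.genotypic_sd, size=(n, len(model.causal_sites))
            ).sum(axis=1)
    return y


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """One rejection-rate experiment (type-I error if ``effect_grid == [0]``).

    ``effect_grid`` lists total PAR values (dichotomous) or total
    variance-explained values (continuous); 0 means the null.  Effects are
    split equally over ``causal_sites_1based``.
    """

    trait_type: str = "dichotomous"  # or "continuous"
    n_families: int = 50
    n_sites: int = 100
    effect_grid: tuple[float, ...] = (0.0,)
    n_replicates: int = 1000
    B: int = 1000
    seed: int = 1
    pool_size: int = 1000
    alphas: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    causal_sites_1based: tuple[int, ...] = DEFAULT_CAUSAL_SITES_1BASED
    baseline_penetrance: float = 0.05

    def __post_init__(self):
        if self.trait_type not in ("dichotomous", "continuous"):
            raise ConfigurationError(f"unknown trait type {self.trait_type!r}")
        if any(e > 0 for e in self.effect_grid) and max(
            self.causal_sites_1based
        ) > self.n_sites:
            raise ConfigurationError(
                "causal site index exceeds the simulated site count"
            )


def _simulate_replicate(cfg: ExperimentConfig, effect: float, rng):
    pool = coalescent_pool(cfg.pool_size, cfg.n_sites, rng)
    ped, hap = simulate_families(pool, cfg.n_families, rng)
    if cfg.trait_type == "dichotomous":
        if effect > 0:
            model = DiseaseModel.equal_par(
                effect, pool, cfg.causal_sites_1based, cfg.baseline_penetrance
            )
        else:
            model = DiseaseModel.null(cfg.baseline_penetrance)
        y = dichotomous_trait(hap.haps, model, pool, rng)
    else:
        if effect > 0:
            model = QtlModel.equal_h2(
                effect, causal_sites_1based=cfg.causal_sites_1based
            )
        else:
            model = QtlModel.null()
        y = continuous_trait(hap.haps, model, pool, rng)
    return ped, hap, TraitTable(trait=y)


def run_experiment(cfg: ExperimentConfig, progress=None) -> pd.DataFrame:
    """Estimate ADA rejection rates over the configured scenario grid.

    Returns a tidy table with one row per (effect, nominal level):
    columns ``trait_type, n_families, n_sites, effect, B, n_replicates,
    alpha, rejection_rate, se`` (binomial standard error).  Degenerate
    replicates (constant trait, e.g. nobody affected) are re-drawn.
    """
    from .errors import DegenerateTraitError, NoTestError

    rng = rng_from_seed(cfg.seed)
    km = kinship_matrix(build_families(cfg.n_families))
    rows = []
    for effect in cfg.effect_grid if cfg.n_replicates > 0 else ():
        pvals = np.empty(cfg.n_replicates)
        done = 0
        while done < cfg.n_replicates:
            ped, hap, traits = _simulate_replicate(cfg, effect, rng)
            try:
                res = ada_test(
                    ped, hap, traits, km=km, thresholds=cfg.thresholds,
                    B=cfg.B, seed=rng,
                )
            except (DegenerateTraitError, NoTestError):
                continue
            pvals[done] = res.adjusted_pvalue
            done += 1
            if progress is not None and done % progress == 0:
                print(f"effect={effect:g}: {done}/{cfg.n_replicates} replicates")
        for alpha in cfg.alphas:
            rate = float((pvals <= alpha).mean())
            se = float(np.sqrt(rate * (1 - rate) / cfg.n_replicates))
            rows.append((
                cfg.trait_type, cfg.n_families, cfg.n_sites, effect,
                cfg.B, cfg.n_replicates, alpha, rate, se,
            ))
    return pd.DataFrame(rows, columns=[
        "trait_type", "n_families", "n_sites", "effect", "B",
        "n_replicates", "alpha", "rejection_rate", "se",
    ])
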