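"""Gene-dropping: randomised haplotype transmission conditional on founders.

Under the permutation null, transmission of haplotypes from parents to
offspring is completely random conditional on parental genotypes, and traits
are held fixed.  Founder haplotypes are never altered; every non-founder's
pair is regenerated generation by generation, drawing one *full-length*
haplotype (no within-region recombination) from each parent's current pair,
independently per individual and per replicate.

Two engines are provided:

* :func:`gene_drop` / :func:`gene_drop_batch` — Monte-Carlo draws (the batch
  form vectorises over replicates and is what the ADA permutation loop uses);
* :func:`enumerate_transmissions` — exact enumeration of all ``4^m`` equally
  likely meiosis patterns for small pedigrees (``m`` non-founders), returning
  the exact distribution over non-founder genotype configurations.

Randomness uses a counter-based (Philox) generator consumed in a fixed
order, so results are reproducible from the seed alone.
"""

from __future__ import annotations

import numpy as np

from .errors import EnumerationSizeError, PhaseError
from .pedio import HaplotypeSet, Pedigree

__all__ = [
    "gene_drop",
    "gene_drop_batch",
    "descent_indices",
    "founder_haplotype_matrix",
    "enumerate_transmissions",
    "rng_from_seed",
]

#: enumeration guard: 2 meioses per non-founder, at most 24 in total
MAX_ENUM_MEIOSES = 24


def rng_from_seed(seed: int | np.random.Generator) -> np.random.Generator:
    """A Philox (counter-based) generator; pass-through for Generators."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.Generator(np.random.Philox(key=int(seed)))


def _check_founder_phase(ped: Pedigree, haps: np.ndarray) -> None:
    if haps.shape[0] != ped.n:
        raise PhaseError("haplotype array does not cover all pedigree members")


def descent_indices(
    ped: Pedigree,
    B: int,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Founder-haplotype descent labels for ``B`` gene-drop replicates.

    Without recombination every haplotype in the pedigree is a verbatim copy
    of one founder haplotype, so a replicate is fully described by an index
    array ``(B, n, 2)`` into the rows of
    :func:`founder_haplotype_matrix` (founder *k* of
    ``ped.founder_indices`` owns rows ``2k`` and ``2k + 1``).  Non-founders
    are resolved in topological order: haplotype 0 descends from the father,
    haplotype 1 from the mother, with independent uniform meiosis choices.
    """
    rng = rng_from_seed(rng)
    n = ped.n
    ids = np.empty((B, n, 2), dtype=np.int32)
    for k, i in enumerate(ped.founder_indices):
        ids[:, i, 0] = 2 * k
        ids[:, i, 1] = 2 * k + 1
    nonf = ped.nonfounder_indices
    if not nonf:
        return ids
    # one meiosis choice per (replicate, non-founder, parent)
    choices = rng.integers(0, 2, size=(B, len(nonf), 2))
    b_idx = np.arange(B)
    for k, i in enumerate(nonf):
        fi, mi = ped.parent_indices(i)
        ids[:, i, 0] = ids[b_idx, fi, choices[:, k, 0]]
        ids[:, i, 1] = ids[b_idx, mi, choices[:, k, 1]]
    return ids


def founder_haplotype_matrix(ped: Pedigree, haps: np.ndarray) -> np.ndarray:
    """Founder haplotypes stacked as a ``(2 * n_founders, L)`` array."""
    _check_founder_phase(ped, haps)
    f = np.asarray(ped.founder_indices, dtype=int)
    return np.ascontiguousarray(haps[f].reshape(2 * f.size, haps.shape[2]))


def gene_drop_batch(
    ped: Pedigree,
    haps: np.ndarray,
    B: int,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """``B`` independent gene-drop replicates, shape ``(B, n, 2, L)``.

    ``haps`` is any ``(n, 2, L)`` allele array (codes need not be 0/1; the
    engine only moves haplotypes around).  Founder rows are copied verbatim
    into every replicate; non-founder rows are regenerated in topological
    order, haplotype 0 from the father and haplotype 1 from the mother.
    """
    haps = np.ascontiguousarray(haps)
    _check_founder_phase(ped, haps)
    FH = founder_haplotype_matrix(ped, haps)
    ids = descent_indices(ped, B, rng)
    return FH[ids]


def gene_drop(
    ped: Pedigree,
    hap: HaplotypeSet,
    rng: int | np.random.Generator,
) -> HaplotypeSet:
    """One permutation replicate of the genotype data (traits untouched)."""
    new = gene_drop_batch(ped, hap.haps, 1, rng)[0]
    return HaplotypeSet(hap.sites, new)


def enumerate_transmissions(
    ped: Pedigree,
    haps: HaplotypeSet | np.ndarray,
    *,
    representation: str = "genotype_score",
) -> dict[tuple, float]:
    """Exact distribution over non-founder genotype configurations.

    All ``4^m`` joint meiosis patterns (``m`` non-founders) are equally
    likely; patterns mapping to the same genotype configuration are pooled.

    Parameters
    ----------
    haps
        A :class:`HaplotypeSet` (0/1 codes) or a raw ``(n, 2, L)`` integer
        array of *labelled* alleles; only founder rows are consumed.
    representation
        ``"genotype_score"`` — a configuration is the tuple over non-founders
        (in topological order) of per-site allele sums; ``"allele_pair"`` —
        per-site *unordered* allele-label pairs, for labelled-allele
        enumeration.

    Returns
    -------
    dict mapping configuration -> exact probability (sums to 1).

    Raises
    ------
    EnumerationSizeError
        If the pedigree has more than ``MAX_ENUM_MEIOSES / 2`` non-founders.
    """
    arr = haps.haps if isinstance(haps, HaplotypeSet) else np.asarray(haps)
    _check_founder_phase(ped, arr)
    nonf = ped.nonfounder_indices
    m = len(nonf)
    if 2 * m > MAX_ENUM_MEIOSES:
        raise EnumerationSizeError(
            f"{m} non-founders -> {2 * m} meioses exceeds the enumeration "
            f"guard of {MAX_ENUM_MEIOSES}"
        )
    if representation not in ("genotype_score", "allele_pair"):
        raise ValueError(f"unknown representation {representation!r}")
    n, _, L = arr.shape
    P = 4**m
    pattern = np.arange(P)
    work = np.broadcast_to(arr.astype(np.int16), (P, n, 2, L)).copy()
    p_idx = np.arange(P)
    for k, i in enumerate(nonf):
        fi, mi = ped.parent_indices(i)
        cf = (pattern >> (2 * k)) & 1
        cm = (pattern >> (2 * k + 1)) & 1
        work[p_idx, i, 0] = work[p_idx, fi, cf]
        work[p_idx, i, 1] = work[p_idx, mi, cm]
    sub = work[:, nonf]  # (P, m, 2, L)
    if representation == "genotype_score":
        config = sub.sum(axis=2)  # (P, m, L)
    else:
        config = np.sort(sub, axis=2).transpose(0, 1, 3, 2)  # (P, m, L, 2)
    flat = config.reshape(P, -1)
    uniq, counts = np.unique(flat, axis=0, return_counts=True)
    return {
        tuple(row.tolist()): c / P for row, c in zip(uniq, counts)
    }
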