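"""Pedigree, phased-genotype and trait input/output.

This module defines the canonical in-memory data model:

* :class:`Pedigree` — ordered individuals with parent links, founder set and
  per-family blocks;
* :class:`HaplotypeSet` — two phased haplotypes per individual over ``L``
  biallelic sites, coded 0 (major/ref) / 1 (minor/alt);
* :class:`TraitTable` — one trait value per individual plus an optional
  covariate matrix.

Conventions
-----------
* An individual is identified by the pair ``(family_id, individual_id)``;
  individual ids must be unique within a family.  ``"0"`` denotes an absent
  parent in PED/FAM input.
* Internal site indexing is 0-based; VCF positions are 1-based per the
  standard.
* Allele code 1 is oriented to the *minor* allele as counted in founders
  (ties at exactly 0.5 keep the file's alt allele).
* Analysis is autosomal only: the sex column is read and stored but unused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    PedigreeStructureError,
    PhaseError,
    UnsupportedSiteError,
)

__all__ = [
    "Individual",
    "Pedigree",
    "Site",
    "HaplotypeSet",
    "TraitTable",
    "MendelianWarning",
    "read_pedigree",
    "read_phased_genotypes",
    "read_traits",
    "write_pedigree",
    "write_phased_vcf",
    "write_haplotype_table",
    "orient_minor_allele",
]

MISSING_PARENT = "0"


class MendelianWarning(UserWarning):
    """A child genotype is impossible given its parents' genotypes."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member. ``father``/``mother`` are ``None`` for founders."""

    family: str
    iid: str
    father: str | None
    mother: str | None
    sex: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.family, self.iid)

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """A validated collection of families.

    Parameters
    ----------
    members
        Individual records in file order.  Order is preserved and defines the
        row index used by every aligned array in the package.

    Raises
    ------
    PedigreeStructureError
        If an individual has exactly one parent recorded, a parent is missing
        from its family, an id is duplicated within a family, or the parent
        graph contains a cycle.
    """

    def __init__(self, members: Sequence[Individual]):
        self.members: list[Individual] = list(members)
        self._index: dict[tuple[str, str], int] = {}
        for i, m in enumerate(self.members):
            if m.key in self._index:
                raise PedigreeStructureError(
                    f"duplicate individual id {m.iid!r} in family {m.family!r}"
                )
            self._index[m.key] = i
        self._validate_parents()
        self.founder_indices: list[int] = [
            i for i, m in enumerate(self.members) if m.is_founder
        ]
        self.family_blocks: dict[str, list[int]] = {}
        for i, m in enumerate(self.members):
            self.family_blocks.setdefault(m.family, []).append(i)
        self._topo = self._topological_order()

    # -- structure ---------------------------------------------------------

    def _validate_parents(self) -> None:
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise PedigreeStructureError(
                    f"individual {m.iid!r} in family {m.family!r} has one "
                    "parent recorded but not the other"
                )
            for role, pid in (("father", m.father), ("mother", m.mother)):
                if pid is not None and (m.family, pid) not in self._index:
                    raise PedigreeStructureError(
                        f"{role} {pid!r} of individual {m.iid!r} not found "
                        f"in family {m.family!r}"
                    )

    def _topological_order(self) -> list[int]:
        """Founders-first ordering; raises on parentage cycles."""
        order: list[int] = []
        state = [0] * len(self.members)  # 0 unvisited, 1 on stack, 2 done

        def visit(i: int) -> None:
            if state[i] == 2:
                return
            if state[i] == 1:
                m = self.members[i]
                raise PedigreeStructureError(
                    f"individual {m.iid!r} in family {m.family!r} is its own "
                    "ancestor (cycle in parentage)"
                )
            state[i] = 1
            for pi in self.parent_indices(i):
                visit(pi)
            state[i] = 2
            order.append(i)

        for i in range(len(self.members)):
            visit(i)
        return order

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.members)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def founder_set(self) -> set[tuple[str, str]]:
        return {self.members[i].key for i in self.founder_indices}

    @property
    def nonfounder_indices(self) -> list[int]:
        """Non-founders in topological (parents-first) order."""
        return [i for i in self._topo if not self.members[i].is_founder]

    @property
    def topological_order(self) -> list[int]:
        return list(self._topo)

    def index_of(self, family: str, iid: str) -> int:
        try:
            return self._index[(family, iid)]
        except KeyError:
            raise ConsistencyError(
                f"individual {iid!r} in family {family!r} not in pedigree"
            ) from None

    def parent_indices(self, i: int) -> tuple[int, ...]:
        m = self.members[i]
        if m.is_founder:
            return ()
        return (
            self._index[(m.family, m.father)],
            self._index[(m.family, m.mother)],
        )


@dataclass(frozen=True)
class Site:
    """Metadata for one biallelic site; allele labels track orientation."""

    id: str
    pos: int | None = None
    ref: str = "A"
    alt: str = "C"


class HaplotypeSet:
    """Phased haplotypes for every pedigree member over ``L`` biallelic sites.

    ``haps`` has shape ``(n, 2, L)`` with codes in {0, 1}; genotype scores
    (minor-allele counts) are ``haps.sum(axis=1)`` in {0, 1, 2}.
    """

    def __init__(self, sites: Sequence[Site], haps: np.ndarray):
        haps = np.asarray(haps, dtype=np.uint8)
        if haps.ndim != 3 or haps.shape[1] != 2:
            raise ValueError("haps must have shape (n, 2, L)")
        if haps.shape[2] != len(sites):
            raise ValueError("site count does not match haplotype length")
        if haps.size and haps.max() > 1:
            raise ValueError("haplotype codes must be 0/1")
        self.sites: list[Site] = list(sites)
        self.haps = haps

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return self.haps.shape[0]

    def genotype_scores(self) -> np.ndarray:
        """Minor-allele counts, shape ``(n, L)``, values in {0, 1, 2}."""
        return self.haps.sum(axis=1, dtype=np.int64)

    def copy(self) -> "HaplotypeSet":
        return HaplotypeSet(self.sites, self.haps.copy())


@dataclass
class TraitTable:
    """Per-individual trait values and optional covariates, pedigree-aligned."""

    trait: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        if self.trait.ndim != 1:
            raise ValueError("trait must be a vector")
        if np.isnan(self.trait).any():
            raise ConsistencyError("missing trait values are not supported")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, float))
            if self.covariates.shape[0] != self.trait.shape[0]:
                raise ConsistencyError("covariate rows do not match trait length")
            if np.isnan(self.covariates).any():
                raise ConsistencyError("missing covariate values are not supported")

    @property
    def is_dichotomous(self) -> bool:
        return bool(np.isin(self.trait, (0.0, 1.0)).all())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED/FAM file (family, individual, father, mother, sex, [pheno...]).

    Whitespace-delimited, at least five columns per row; ``"0"`` marks an
    absent parent.  Lines starting with ``#`` are ignored.
    """
    members: list[Individual] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 5:
                raise PedigreeStructureError(
                    f"{path}: line {ln}: expected >=5 columns, got {len(cols)}"
                )
            fam, iid, fat, mot, sex = cols[:5]
            members.append(
                Individual(
                    family=fam,
                    iid=iid,
                    father=None if fat == MISSING_PARENT else fat,
                    mother=None if mot == MISSING_PARENT else mot,
                    sex=int(sex) if sex.isdigit() else 0,
                )
            )
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str | Path, phenotype=None) -> None:
    pheno = phenotype if phenotype is not None else [-9] * ped.n
    with open(path, "w") as fh:
        for m, p in zip(ped.members, pheno):
            ptxt = f"{p:g}" if isinstance(p, float) else str(p)
            fh.write(
                f"{m.family}\t{m.iid}\t{m.father or '0'}\t{m.mother or '0'}"
                f"\t{m.sex}\t{ptxt}\n"
            )


def _mendel_check(ped: Pedigree, scores: np.ndarray, site_ids: list[str]) -> None:
    """Warn (not fail) on genotype-level Mendelian impossibilities.

    A child score is feasible iff one allele can come from each parent:
    possible transmissions from a parent with score g are {0} (g=0),
    {0,1} (g=1), {1} (g=2).
    """
    opts = [(0,), (0, 1), (1,)]
    for ci in ped.nonfounder_indices:
        fi, mi = ped.parent_indices(ci)
        for l in range(scores.shape[1]):
            gc = scores[ci, l]
            feasible = {
                a + b for a in opts[scores[fi, l]] for b in opts[scores[mi, l]]
            }
            if gc not in feasible:
                m = ped.members[ci]
                warnings.warn(
                    f"Mendelian inconsistency: individual {m.iid} (family "
                    f"{m.family}) has genotype {gc} at site {site_ids[l]} "
                    f"incompatible with parental genotypes",
                    MendelianWarning,
                    stacklevel=3,
                )


def founder_alt_frequency(haps: np.ndarray, ped: Pedigree) -> np.ndarray:
    """Frequency of allele code 1 among founder haplotypes, per site."""
    f = np.asarray(ped.founder_indices, dtype=int)
    if f.size == 0:
        raise PedigreeStructureError("pedigree has no founders")
    return haps[f].reshape(2 * f.size, -1).mean(axis=0)


def orient_minor_allele(
    hap: HaplotypeSet, ped: Pedigree
) -> tuple[HaplotypeSet, np.ndarray]:
    """Flip site codes so that 1 is the minor allele in founders.

    Sites where the founder frequency of allele 1 strictly exceeds 0.5 are
    flipped (codes complemented, ref/alt labels swapped).  Idempotent.
    Returns the oriented set and the boolean flip mask.
    """
    freq = founder_alt_frequency(hap.haps, ped)
    flip = freq > 0.5
    haps = hap.haps.copy()
    haps[:, :, flip] = 1 - haps[:, :, flip]
    sites = [
        Site(s.id, s.pos, s.alt, s.ref) if fl else s
        for s, fl in zip(hap.sites, flip)
    ]
    return HaplotypeSet(sites, haps), flip


def read_phased_genotypes(
    path: str | Path,
    ped: Pedigree,
    *,
    mendel_warnings: bool = True,
) -> HaplotypeSet:
    """Read phased genotypes for all pedigree members.

    ``*.vcf`` input is parsed with cyvcf2 and must be fully phased (``|``
    separator) and biallelic; any other extension is read as a plain
    haplotype table (see :func:`write_haplotype_table`).  VCF sample names
    must equal individual ids (unique across the file).  After loading,
    allele codes are oriented so 1 = minor allele in founders.
    """
    path = Path(path)
    if path.suffix == ".vcf" or path.name.endswith(".vcf.gz"):
        sites, haps = _read_vcf(path, ped)
    else:
        sites, haps = _read_hap_table(path, ped)
    hap = HaplotypeSet(sites, haps)
    if mendel_warnings:
        _mendel_check(ped, hap.genotype_scores(), [s.id for s in hap.sites])
    oriented, _ = orient_minor_allele(hap, ped)
    return oriented


def _read_vcf(path: Path, ped: Pedigree) -> tuple[list[Site], np.ndarray]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ConsistencyError("duplicate sample ids in VCF")
    col = {s: j for j, s in enumerate(samples)}
    # samples may be named either "iid" or "family_iid"
    rows, missing = [], []
    for m in ped.members:
        qualified = f"{m.family}_{m.iid}"
        if qualified in col:
            rows.append(col[qualified])
        elif m.iid in col:
            rows.append(col[m.iid])
        else:
            missing.append(m.iid)
    if missing:
        raise ConsistencyError(
            f"pedigree members missing from VCF: {', '.join(missing[:5])}"
        )

    sites: list[Site] = []
    hap_cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise UnsupportedSiteError(
                f"multi-allelic site at {var.CHROM}:{var.POS} is unsupported"
            )
        gts = np.array(var.genotypes, dtype=object)  # rows: [a0, a1, phased]
        phased = np.array([g[2] for g in var.genotypes], dtype=bool)
        if not phased.all():
            bad = samples[int(np.flatnonzero(~phased)[0])]
            raise PhaseError(
                f"unphased genotype for sample {bad} at {var.CHROM}:{var.POS}"
            )
        alleles = np.array([[g[0], g[1]] for g in var.genotypes], dtype=int)
        if (alleles < 0).any():
            raise ConsistencyError(
                f"missing genotype call at {var.CHROM}:{var.POS}"
            )
        sites.append(Site(var.ID or f"{var.CHROM}:{var.POS}", var.POS,
                          var.REF, var.ALT[0]))
        hap_cols.append(alleles[rows])
    if not sites:
        raise ConsistencyError(f"no variant records in {path}")
    haps = np.stack(hap_cols, axis=2).astype(np.uint8)  # (n, 2, L)
    return sites, haps


def _read_hap_table(path: Path, ped: Pedigree) -> tuple[list[Site], np.ndarray]:
    """Plain text: one row per haplotype, ``family iid hap_index a1 a2 ...``."""
    rows: dict[tuple[str, str, int], list[int]] = {}
    L = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            fam, iid, hidx = cols[0], cols[1], int(cols[2])
            alleles = [int(c) for c in cols[3:]]
            if L is None:
                L = len(alleles)
            elif len(alleles) != L:
                raise ConsistencyError("ragged haplotype table")
            rows[(fam, iid, hidx)] = alleles
    if L is None:
        raise ConsistencyError(f"empty haplotype table {path}")
    haps = np.zeros((ped.n, 2, L), dtype=np.uint8)
    for i, m in enumerate(ped.members):
        for h in (0, 1):
            try:
                haps[i, h] = rows[(m.family, m.iid, h)]
            except KeyError:
                raise ConsistencyError(
                    f"haplotype {h} of individual {m.iid} (family {m.family}) "
                    "missing from haplotype table"
                ) from None
    sites = [Site(f"site{l}", l + 1) for l in range(L)]
    return sites, haps


def read_traits(path: str | Path, ped: Pedigree) -> TraitTable:
    """Read a whitespace table ``family iid trait [covariate ...]``."""
    vals: dict[tuple[str, str], list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            vals[(cols[0], cols[1])] = [float(c) for c in cols[2:]]
    trait = np.empty(ped.n)
    width = None
    covs: list[list[float]] = []
    for i, m in enumerate(ped.members):
        if m.key not in vals:
            raise ConsistencyError(
                f"trait value missing for individual {m.iid} (family {m.family})"
            )
        row = vals[m.key]
        trait[i] = row[0]
        if width is None:
            width = len(row) - 1
        elif len(row) - 1 != width:
            raise ConsistencyError("ragged covariate columns in trait file")
        covs.append(row[1:])
    covariates = np.array(covs) if width else None
    return TraitTable(trait=trait, covariates=covariates)


def write_phased_vcf(hap: HaplotypeSet, ped: Pedigree, path: str | Path,
                     chrom: str = "1") -> None:
    """Write a minimal phased VCF v4.2 (GT only, ``|`` separator).

    Sample names are ``family_iid`` when an individual id occurs in more
    than one family, else the bare individual id.
    """
    iids = [m.iid for m in ped.members]
    unique = len(set(iids)) == len(iids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(
            m.iid if unique else f"{m.family}_{m.iid}" for m in ped.members
        )
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for l, s in enumerate(hap.sites):
            pos = s.pos if s.pos is not None else l + 1
            gts = "\t".join(
                f"{hap.haps[i, 0, l]}|{hap.haps[i, 1, l]}"
                for i in range(ped.n)
            )
            fh.write(f"{chrom}\t{pos}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


def write_haplotype_table(hap: HaplotypeSet, ped: Pedigree,
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(ped.members):
            for h in (0, 1):
                alleles = " ".join(str(a) for a in hap.haps[i, h])
                fh.write(f"{m.family} {m.iid} {h} {alleles}\n")
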