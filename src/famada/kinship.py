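"""Pedigree kinship coefficients and the genetic-correlation matrix.

The kinship coefficient ``phi_ij`` is the probability that one allele drawn
at random from individual *i* and one from *j* are identical by descent.
The genetic-correlation (expected additive relationship) matrix ``Phi`` has
entries ``2 * phi_ij``; its diagonal is ``1 + f_i`` with ``f_i`` the
inbreeding coefficient.  Founders are assumed non-inbred and mutually
unrelated, so individuals in different families are unrelated and ``Phi``
is block-diagonal with one block per family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedio import Pedigree

__all__ = ["KinshipModel", "kinship_matrix", "kinship_long_table"]


@dataclass
class KinshipModel:
    """Pairwise kinship ``phi`` and genetic correlation ``Phi = 2 phi``.

    ``family_blocks`` mirrors :attr:`Pedigree.family_blocks` so the block
    structure of ``Phi`` can be exploited without re-deriving it.
    """

    phi: np.ndarray
    family_blocks: dict[str, list[int]]

    @property
    def Phi(self) -> np.ndarray:
        return 2.0 * self.phi

    def quadratic_form(self, r: np.ndarray) -> float:
        """``r' Phi r`` computed block-wise (exact zero across families)."""
        total = 0.0
        for idx in self.family_blocks.values():
            idx = np.asarray(idx)
            rb = r[idx]
            total += rb @ (2.0 * self.phi[np.ix_(idx, idx)]) @ rb
        return float(total)

    def min_eigenvalue(self) -> float:
        """Smallest eigenvalue of ``Phi`` (PSD check helper)."""
        return float(min(
            np.linalg.eigvalsh(2.0 * self.phi[np.ix_(idx, idx)]).min()
            for idx in self.family_blocks.values()
        ))


def kinship_matrix(ped: Pedigree) -> KinshipModel:
    """Compute pairwise kinship by the standard founders-first recursion.

    For individual *i* with parents *f*, *m* (processed after them):

    * ``phi(i, i) = (1 + phi(f, m)) / 2``
    * ``phi(i, j) = (phi(f, j) + phi(m, j)) / 2`` for any *j* already
      processed (hence never a descendant of *i*),

    with founders having ``phi = 1/2`` with themselves and 0 with every
    other already-processed individual.
    """
    n = ped.n
    phi = np.zeros((n, n))
    order = ped.topological_order
    seen: list[int] = []
    fam_of = [m.family for m in ped.members]
    for i in order:
        parents = ped.parent_indices(i)
        if not parents:
            phi[i, i] = 0.5
        else:
            f, m = parents
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for j in seen:
                if fam_of[j] != fam_of[i]:
                    continue
                v = 0.5 * (phi[f, j] + phi[m, j])
                phi[i, j] = phi[j, i] = v
        seen.append(i)
    return KinshipModel(phi=phi, family_blocks=ped.family_blocks)


def kinship_long_table(ped: Pedigree, km: KinshipModel):
    """Long-format (family, id1, id2, kinship) pandas table, upper triangle."""
    import pandas as pd

    rows = []
    for fam, idx in km.family_blocks.items():
        for a, i in enumerate(idx):
            for j in idx[a:]:
                rows.append(
                    (fam, ped.members[i].iid, ped.members[j].iid, km.phi[i, j])
                )
    return pd.DataFrame(rows, columns=["family", "id1", "id2", "kinship"])
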