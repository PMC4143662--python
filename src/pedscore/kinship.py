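"""Pedigree-based additive relationship matrix.

K is twice the kinship coefficient matrix: K_ij = 2 * P(two alleles
drawn at random from i and j are identical by descent). It is computed
from pedigree structure alone by the tabular (recursive) method, which
is exact and O(N^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Pedigree

__all__ = ["KinshipMatrix", "additive_relationship", "kinship_submatrix"]


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric PSD additive relationship matrix with its id order.

    Diagonal entries are 1 + F_i (F_i = inbreeding coefficient), so they
    lie in [1, 2] and founders have exactly 1; entries across distinct
    families are exactly 0.
    """

    values: np.ndarray
    id_order: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship values must be square")
        if v.shape[0] != len(self.id_order):
            raise ValueError("id_order length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def index_of(self, ids) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.id_order)}
        unknown = [i for i in ids if i not in pos]
        if unknown:
            raise KeyError(f"ids not in kinship matrix: {unknown}")
        return np.array([pos[i] for i in ids], dtype=int)


def additive_relationship(pedigree: Pedigree) -> KinshipMatrix:
    """Tabular-method additive relationship matrix in pedigree id order.

    Processing individuals parents-first: A_ii = 1 + A_{f,m}/2 (founders
    have A_ii = 1) and A_ij = (A_{j,f} + A_{j,m})/2 for previously
    processed j, where f, m are i's parents.
    """
    n = pedigree.n
    father, mother = pedigree.parent_indices()
    topo = pedigree.topological_order()
    a = np.zeros((n, n))
    done: list[int] = []
    for i in topo:
        f, m = father[i], mother[i]
        if f < 0:
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0 + 0.5 * a[f, m]
            if done:
                prev = np.asarray(done)
                vals = 0.5 * (a[prev, f] + a[prev, m])
                a[i, prev] = vals
                a[prev, i] = vals
        done.append(int(i))
    return KinshipMatrix(a, pedigree.ids)


def kinship_submatrix(k: KinshipMatrix, ids) -> KinshipMatrix:
    """Principal submatrix of K restricted to ``ids``, in the given order."""
    idx = k.index_of(ids)
    return KinshipMatrix(k.values[np.ix_(idx, idx)], list(ids))
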