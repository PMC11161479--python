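"""Pedigree relationship algebra.

The numerator relationship matrix A holds twice the kinship coefficients
implied by the pedigree; its diagonal is 1 + F (the inbreeding
coefficient).  A is built with the tabular method, A^-1 with Henderson's
rules using exact Mendelian-sampling variances from parental inbreeding
(the Meuwissen–Luo diagonal), and A22 is the principal submatrix for the
genotyped animals.

Unknown parents are treated as unrelated, non-inbred founders; genetic
groups are not modelled.  Animal identifiers are arbitrary strings mapped
to dense indices internally, and every returned matrix is keyed by the
original labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = None  # sentinel for an unknown parent


@dataclass
class Pedigree:
    """Ordered animal/sire/dam triplets.

    ``sire`` / ``dam`` hold per-animal parent indices into ``ids``
    (-1 = unknown).  A pedigree is *sorted* when every parent's index
    precedes all of its offspring's, which the tabular recursions rely on.
    """

    ids: list[str]
    sire: np.ndarray  # int index into ids, -1 unknown
    dam: np.ndarray
    sorted: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.ids) == len(self.sire) == len(self.dam)):
            raise ValueError("ids, sire and dam must have equal length")
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate animal ids in pedigree")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    @classmethod
    def from_records(cls, records: list[tuple[str, str | None, str | None]]) -> "Pedigree":
        """Build from (animal, sire, dam) triples; ``None``/``"0"``/``""`` = unknown.

        Parents that never appear as animals are prepended as founders.
        """
        def norm(x):
            return None if x in (None, "", "0", 0) else str(x)

        seen = {str(a) for a, _, _ in records}
        extra: list[str] = []
        for _, s, d in records:
            for p in (norm(s), norm(d)):
                if p is not None and p not in seen:
                    seen.add(p)
                    extra.append(p)
        ids = extra + [str(a) for a, _, _ in records]
        idx = {a: i for i, a in enumerate(ids)}
        sire = np.full(len(ids), -1, dtype=np.int64)
        dam = np.full(len(ids), -1, dtype=np.int64)
        for a, s, d in records:
            i = idx[str(a)]
            s, d = norm(s), norm(d)
            sire[i] = idx[s] if s is not None else -1
            dam[i] = idx[d] if d is not None else -1
        return cls(ids=ids, sire=sire, dam=dam, _index=idx)

    def to_frame(self) -> pd.DataFrame:
        sire_lab = ["0" if s < 0 else self.ids[s] for s in self.sire]
        dam_lab = ["0" if d < 0 else self.ids[d] for d in self.dam]
        return pd.DataFrame({"animal": self.ids, "sire": sire_lab, "dam": dam_lab})


@dataclass
class RelationshipMatrix:
    """Symmetric relationship coefficients keyed by animal labels."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")

    def loc(self, row_id: str, col_id: str) -> float:
        i = self.ids.index(row_id)
        j = self.ids.index(col_id)
        return float(self.values[i, j])


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so every parent precedes all its offspring.

    Raises ``ValueError`` naming an animal on the cycle if the parentage
    graph is cyclic.
    """
    n = len(ped)
    order: list[int] = []
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on stack, 2 done
    for root in range(n):
        if state[root] == 2:
            continue
        # iterative DFS over parent edges
        stack: list[tuple[int, int]] = [(root, 0)]
        while stack:
            node, phase = stack.pop()
            if phase == 0:
                if state[node] == 2:
                    continue
                if state[node] == 1:
                    raise ValueError(f"pedigree cycle detected involving animal {ped.ids[node]!r}")
                state[node] = 1
                stack.append((node, 1))
                for p in (ped.sire[node], ped.dam[node]):
                    if p >= 0 and state[p] != 2:
                        if state[p] == 1:
                            raise ValueError(
                                f"pedigree cycle detected involving animal {ped.ids[p]!r}"
                            )
                        stack.append((int(p), 0))
            else:
                state[node] = 2
                order.append(node)
    perm = np.array(order, dtype=np.int64)
    inv = np.empty(n, dtype=np.int64)
    inv[perm] = np.arange(n)
    new_ids = [ped.ids[i] for i in perm]
    new_sire = np.where(ped.sire[perm] >= 0, inv[np.clip(ped.sire[perm], 0, None)], -1)
    new_dam = np.where(ped.dam[perm] >= 0, inv[np.clip(ped.dam[perm], 0, None)], -1)
    return Pedigree(ids=new_ids, sire=new_sire, dam=new_dam, sorted=True)


def _require_sorted(ped: Pedigree) -> None:
    if not ped.sorted:
        # verify rather than trust the flag when unset
        s_ok = np.all((ped.sire < np.arange(len(ped))) | (ped.sire < 0))
        d_ok = np.all((ped.dam < np.arange(len(ped))) | (ped.dam < 0))
        if not (s_ok and d_ok):
            raise ValueError("pedigree is not sorted (call sort_pedigree first)")


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)}) for j < i and
    a_ii = 1 + 0.5 a_{sire(i),dam(i)}; unknown parents contribute 0.
    """
    _require_sorted(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(values=A, ids=list(ped.ids))


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding F = A_ii - 1, in pedigree order."""
    A = build_A(ped)
    return np.diag(A.values) - 1.0


def build_A_inverse(ped: Pedigree, sparse_out: bool = False, inbreeding: bool = True):
    """A^-1 by Henderson's rules, with inbreeding by default.

    The Mendelian-sampling variance for animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    d_i = 0.75 - 0.25 F_p with one parent known, and 1 for founders;
    A^-1 accumulates alpha_i = 1/d_i contributions over the (i, sire, dam)
    triangle.  Exact for any (acyclic) pedigree.  ``inbreeding=False``
    treats all parents as non-inbred (Henderson's simple rules), which is
    only exact for pedigrees without inbreeding.
    """
    _require_sorted(ped)
    n = len(ped)
    F = inbreeding_coefficients(ped) if inbreeding else np.zeros(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        s, d = int(ped.sire[i]), int(ped.dam[i])
        if s >= 0 and d >= 0:
            mend = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mend = 0.75 - 0.25 * F[p]
        else:
            mend = 1.0
        alpha = 1.0 / mend
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]
                cols += [p, i]
                vals += [-0.5 * alpha, -0.5 * alpha]
        for p in (s, d):
            if p >= 0:
                for q in (s, d):
                    if q >= 0:
                        rows.append(p)
                        cols.append(q)
                        vals.append(0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if sparse_out:
        return Ainv
    return RelationshipMatrix(values=Ainv.toarray(), ids=list(ped.ids))


def extract_A22(A: RelationshipMatrix, genotyped_ids: list[str]) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in their order."""
    pos = {a: i for i, a in enumerate(A.ids)}
    missing = [g for g in genotyped_ids if g not in pos]
    if missing:
        raise KeyError(f"ids not present in relationship matrix: {missing}")
    idx = np.array([pos[g] for g in genotyped_ids], dtype=np.int64)
    return RelationshipMatrix(values=A.values[np.ix_(idx, idx)], ids=list(genotyped_ids))
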