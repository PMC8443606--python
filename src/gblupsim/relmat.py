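"""Genomic (G) and pedigree numerator (A) relationship matrices.

G follows the centered cross-product form G = WW'/c with
W_ij = X_ij + 1 - 2 p_j, X coded -1/0/1 and c = 2 * sum_j p_j (1 - p_j),
allele frequencies estimated from the supplied (possibly error-corrupted)
genotypes themselves.  A is built by the tabular method, with the diagonal
1 + F carrying the pedigree inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "allele_frequencies",
    "compute_grm",
    "compute_nrm",
    "tabular_extend",
]


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix over an ordered set of individuals."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # "genomic" | "pedigree"
    allele_freqs: np.ndarray | None = None
    scale_c: float | None = None

    @property
    def n(self) -> int:
        return self.ids.size

    def subset(self, ids: np.ndarray) -> "RelationshipMatrix":
        """Principal submatrix for the given individuals, in the given order."""
        pos = {int(i): p for p, i in enumerate(self.ids)}
        try:
            idx = np.array([pos[int(i)] for i in ids])
        except KeyError as e:
            raise KeyError(f"individual {e} not in relationship matrix") from e
        return RelationshipMatrix(
            values=self.values[np.ix_(idx, idx)],
            ids=np.asarray(ids).copy(),
            kind=self.kind,
            allele_freqs=self.allele_freqs,
            scale_c=self.scale_c,
        )

    def offdiagonal(self) -> np.ndarray:
        """Strict upper-triangle values as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_triplets(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n)
        return pd.DataFrame(
            {
                "id_i": self.ids[iu[0]],
                "id_j": self.ids[iu[1]],
                "value": self.values[iu],
            }
        )


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-locus frequency of the dosage-counted allele: mean dosage / 2."""
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    return g.dosage.mean(axis=0) / 2.0


def compute_grm(g: GenotypeMatrix, *, standardized: bool = False) -> RelationshipMatrix:
    """Genomic relationship matrix G = WW'/c from observed genotypes.

    X = dosage - 1 maps genotypes to -1/0/1; W = X + 1 - 2p centers each
    locus at twice its allele frequency.  Monomorphic loci have a constant W
    column and p(1-p) = 0, so they drop out of both numerator and scale.

    With ``standardized=True`` each locus is instead divided by its own
    sqrt(2 p (1-p)) before the cross-product (the per-locus-standardized GRM
    variant); monomorphic loci are excluded from the average.
    """
    if g.n_individuals < 2:
        raise ValueError("GRM needs at least two individuals")
    p = allele_frequencies(g)
    het = 2.0 * p * (1.0 - p)
    w = g.dosage.astype(np.float64) - 2.0 * p  # == (X + 1 - 2p) since X = dosage - 1
    if standardized:
        poly = het > 0
        if not poly.any():
            raise ValueError("all loci are monomorphic; GRM undefined")
        ws = w[:, poly] / np.sqrt(het[poly])
        values = ws @ ws.T / poly.sum()
        c = float(poly.sum())
    else:
        c = float(het.sum())
        if c <= 0.0:
            raise ValueError("all loci are monomorphic; GRM undefined")
        values = w @ w.T / c
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(
        values=values,
        ids=g.individual_ids.copy(),
        kind="genomic",
        allele_freqs=p,
        scale_c=c,
    )


def tabular_extend(
    a: np.ndarray, sire_pos: np.ndarray, dam_pos: np.ndarray
) -> np.ndarray:
    """Extend an NRM by new individuals whose parents are rows of ``a``.

    ``sire_pos``/``dam_pos`` give parent row indices (-1 for unknown).  New
    individuals are appended in order and may be full sibs of each other;
    rows are filled sequentially so within-batch relationships are exact.
    """
    n_old = a.shape[0]
    n_new = sire_pos.size
    n = n_old + n_new
    out = np.zeros((n, n))
    out[:n_old, :n_old] = a
    for k in range(n_new):
        i = n_old + k
        s, d = int(sire_pos[k]), int(dam_pos[k])
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * out[s, :i]
        if d >= 0:
            row += 0.5 * out[d, :i]
        out[i, :i] = row
        out[:i, i] = row
        out[i, i] = 1.0 + (0.5 * out[s, d] if s >= 0 and d >= 0 else 0.0)
    return out


def _topological_order(ids: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Order individuals so parents precede offspring; raise on cycles."""
    n = ids.size
    pos = {int(i): k for k, i in enumerate(ids)}
    depth = np.full(n, -1, dtype=np.int64)
    parent_pos = np.full((n, 2), -1, dtype=np.int64)
    for k in range(n):
        for j, p in enumerate((sire[k], dam[k])):
            p = int(p)
            if p != 0:
                if p not in pos:
                    raise ValueError(f"parent {p} of {int(ids[k])} not in pedigree")
                parent_pos[k, j] = pos[p]
    pending = list(range(n))
    while pending:
        progressed = False
        still = []
        for k in pending:
            dps = [depth[p] for p in parent_pos[k] if p >= 0]
            if all(d >= 0 for d in dps):
                depth[k] = (max(dps) + 1) if dps else 0
                progressed = True
            else:
                still.append(k)
        if not progressed:
            raise ValueError("pedigree contains a cycle")
        pending = still
    return np.argsort(depth, kind="stable")


def compute_nrm(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` needs columns id, sire, dam (0 = unknown parent); any row
    order is accepted.  Founders get diagonal 1; for individual i,
    a(i,j) = (a(sire_i,j) + a(dam_i,j))/2 and a(i,i) = 1 + a(sire_i,dam_i)/2.
    The result is returned in the input row order.
    """
    ids = pedigree["id"].to_numpy(dtype=np.int64)
    if np.unique(ids).size != ids.size:
        raise ValueError("duplicate individual ids in pedigree")
    sire = pedigree["sire"].to_numpy(dtype=np.int64)
    dam = pedigree["dam"].to_numpy(dtype=np.int64)
    order = _topological_order(ids, sire, dam)
    pos_sorted = {int(ids[k]): j for j, k in enumerate(order)}
    sp = np.array(
        [pos_sorted[int(sire[k])] if sire[k] != 0 else -1 for k in order]
    )
    dp = np.array(
        [pos_sorted[int(dam[k])] if dam[k] != 0 else -1 for k in order]
    )
    a = tabular_extend(np.zeros((0, 0)), sp, dp)
    # back to input order
    inv = np.empty(ids.size, dtype=np.int64)
    inv[order] = np.arange(ids.size)
    a = a[np.ix_(inv, inv)]
    return RelationshipMatrix(values=a, ids=ids.copy(), kind="pedigree")
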