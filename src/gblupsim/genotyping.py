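"""Genotype QC, nested SNP panels, and genotyping-error injection.

Genotypes are dosage-coded 0/1/2 (homozygote, heterozygote, other
homozygote).  Scoring errors are modelled by a 3x3 row-stochastic transition
probability matrix P, p_ij being the probability that a SNP with true
genotype class i is scored as class j; observed genotypes are drawn from the
multinomial given by the true genotype's row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "TransitionMatrix",
    "maf_filter",
    "sample_panel",
    "build_transition_matrix",
    "inject_errors",
]


@dataclass
class GenotypeMatrix:
    """Dosage genotypes (individuals x loci) with locus and individual keys."""

    dosage: np.ndarray
    locus_ids: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        n, m = self.dosage.shape
        if self.individual_ids.size != n or self.locus_ids.size != m:
            raise ValueError("index sizes inconsistent with dosage shape")
        if self.dosage.size and not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]


# Off-diagonal miscall pattern per true-genotype row, as a fraction of the
# total error rate: homozygotes miscall 3:2 toward the heterozygote, the
# heterozygote miscalls symmetrically.
_OFFDIAG_SHARE = np.array([[0.6, 0.4], [0.5, 0.5], [0.4, 0.6]])


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 genotype-miscall model."""

    p: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("every row must sum to 1 within 1e-12")
        object.__setattr__(self, "p", p)


def build_transition_matrix(
    rate: float, *, five_percent_as_printed: bool = False
) -> TransitionMatrix:
    """Transition matrix for a nominal per-genotype error rate.

    Rate 0 gives the identity.  For any rate the diagonal is 1 - rate and the
    off-diagonals distribute the rate in the 3:2 / 1:1 / 2:3 row pattern, which
    reproduces the 1% matrix ((0.990, 0.006, 0.004), ...) and the 10% matrix
    ((0.90, 0.06, 0.04), ...) exactly.  The published 5% matrix has
    off-diagonals an order of magnitude too small for its diagonal (rows sum
    to 0.955); by default the pattern above is used so the realized error rate
    is exactly 5%; ``five_percent_as_printed=True`` instead row-normalizes the
    published entries.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("error rate must lie in [0, 1)")
    if five_percent_as_printed and abs(rate - 0.05) < 1e-12:
        printed = np.array(
            [
                [0.9500, 0.003, 0.0020],
                [0.0025, 0.950, 0.0025],
                [0.0020, 0.003, 0.9500],
            ]
        )
        p = printed / printed.sum(axis=1, keepdims=True)
        return TransitionMatrix(p=p, nominal_rate=float(1.0 - p[0, 0]))
    p = np.eye(3) * (1.0 - rate)
    off_cols = [(1, 2), (0, 2), (0, 1)]
    for i, cols in enumerate(off_cols):
        p[i, cols[0]] = rate * _OFFDIAG_SHARE[i, 0]
        p[i, cols[1]] = rate * _OFFDIAG_SHARE[i, 1]
    return TransitionMatrix(p=p, nominal_rate=float(rate))


def maf_filter(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Retain loci with minor allele frequency strictly above ``threshold``.

    Frequencies are estimated from the supplied individuals as mean dosage / 2;
    locus order is preserved.
    """
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    p = g.dosage.mean(axis=0) / 2.0
    keep = np.minimum(p, 1.0 - p) > threshold
    return GenotypeMatrix(
        dosage=g.dosage[:, keep],
        locus_ids=g.locus_ids[keep],
        individual_ids=g.individual_ids,
    )


def sample_panel(g: GenotypeMatrix, k: int, seed: int) -> GenotypeMatrix:
    """Uniform sample of ``k`` loci without replacement (order preserved)."""
    if k < 1:
        raise ValueError("panel size must be >= 1")
    if k > g.n_loci:
        raise ValueError(f"requested panel of {k} loci but only {g.n_loci} available")
    rng = np.random.default_rng(seed)
    pick = np.sort(rng.choice(g.n_loci, size=k, replace=False))
    return GenotypeMatrix(
        dosage=g.dosage[:, pick],
        locus_ids=g.locus_ids[pick],
        individual_ids=g.individual_ids,
    )


def inject_errors(
    g: GenotypeMatrix, tm: TransitionMatrix, seed: int
) -> GenotypeMatrix:
    """Resample every genotype from its true class's transition-matrix row.

    Entries are independent across individuals and loci; with the identity
    matrix the output equals the input exactly.
    """
    if tm.nominal_rate == 0.0 and np.allclose(tm.p, np.eye(3)):
        return GenotypeMatrix(
            dosage=g.dosage.copy(),
            locus_ids=g.locus_ids.copy(),
            individual_ids=g.individual_ids,
        )
    rng = np.random.default_rng(seed)
    u = rng.random(g.dosage.shape)
    cum = np.cumsum(tm.p, axis=1)  # (3, 3) row CDFs
    thresholds = cum[g.dosage.astype(np.intp)]  # (n, m, 3)
    observed = (u[..., np.newaxis] >= thresholds).sum(axis=-1).astype(np.int8)
    return GenotypeMatrix(
        dosage=observed,
        locus_ids=g.locus_ids.copy(),
        individual_ids=g.individual_ids,
    )
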