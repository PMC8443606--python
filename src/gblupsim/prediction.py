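"""Breeding-value prediction by GBLUP and pedigree BLUP.

The model is the standard single-trait animal model

    y = 1 mu + u + e,    u ~ N(0, K sigma2_u),   e ~ N(0, I sigma2_e),

with K a genomic (G) or pedigree (A) relationship matrix.  Variance
components are estimated by REML on the training block via a spectral
decomposition, profiling the restricted likelihood over the variance ratio
delta = sigma2_e / sigma2_u (the mixed.solve approach).  Breeding values of
unphenotyped individuals are the conditional-expectation projection
K[test, train] (K[train, train] + delta I)^-1 (y - mu).

The study design trains on the 70% of a generation whose phenotypes are kept
(the sibs) and predicts the masked 30% (the selection candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .genome import Population
from .genotyping import GenotypeMatrix, TransitionMatrix, inject_errors
from .relmat import RelationshipMatrix, compute_grm, compute_nrm

__all__ = [
    "SplitPlan",
    "MixedModelFit",
    "split_train_test",
    "fit_mixed_model",
    "blup_known_variance",
    "predict_gebv",
    "predict_ebv",
]

_MIN_EIG = -1e-6  # PSD tolerance before jitter repair is refused
_JITTER = 1e-8
_LOG_DELTA_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class SplitPlan:
    """A within-generation train/test partition of individual ids."""

    test_ids: np.ndarray
    train_ids: np.ndarray
    generation_label: str

    @property
    def n_test(self) -> int:
        return self.test_ids.size

    @property
    def n_train(self) -> int:
        return self.train_ids.size


@dataclass
class MixedModelFit:
    """REML variance components, fixed mean and predicted breeding values."""

    var_additive: float
    var_residual: float
    intercept: float
    ebv: pd.Series  # indexed by individual id, train + test
    loglik: float

    @property
    def h2(self) -> float:
        tot = self.var_additive + self.var_residual
        return self.var_additive / tot if tot > 0 else 0.0


def split_train_test(
    generation: Population, fraction: float = 0.30, seed: int = 0
) -> SplitPlan:
    """Randomly reserve ``fraction`` of a generation as masked test animals.

    The test count is round-half-away-from-zero of n * fraction (5000 -> 1500
    test / 3500 train); both sets must be non-empty.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = generation.n
    n_test = int(np.floor(n * fraction + 0.5))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate split: {n_test} test of {n} individuals")
    rng = np.random.default_rng(seed)
    test_pos = rng.choice(n, size=n_test, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[test_pos] = True
    return SplitPlan(
        test_ids=generation.ids[mask].copy(),
        train_ids=generation.ids[~mask].copy(),
        generation_label=generation.generation_label,
    )


def _positions(relmat: RelationshipMatrix, ids: np.ndarray) -> np.ndarray:
    pos = {int(i): p for p, i in enumerate(relmat.ids)}
    return np.array([pos[int(i)] for i in ids])


def fit_mixed_model(
    phenotypes: pd.Series, relmat: RelationshipMatrix
) -> MixedModelFit:
    """REML fit of the animal model and BLUP for every individual in K.

    ``phenotypes`` is indexed by the training individuals' ids; ``relmat``
    must cover training and prediction individuals.  Returns variance
    components, the GLS intercept, the restricted log-likelihood at the
    optimum and breeding values for all individuals of ``relmat``.
    """
    y = np.asarray(phenotypes.to_numpy(), dtype=np.float64)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 training records")
    t = _positions(relmat, phenotypes.index.to_numpy())
    k_tt = relmat.values[np.ix_(t, t)]

    # project out the intercept by double-centering K + I: C(K+I)C is PSD with
    # null space exactly span(1), so its single ~zero eigenvalue is the
    # intercept direction and the remaining eigenvalues are theta + 1 for the
    # n-1 contrast directions (the mixed.solve offset trick).
    m = k_tt + np.eye(n)
    row_mean = m.mean(axis=1, keepdims=True)
    m = m - row_mean - row_mean.T + row_mean.mean()
    lam, v = linalg.eigh(0.5 * (m + m.T))
    theta = lam[1:] - 1.0
    if theta.size and theta[0] < _MIN_EIG:
        raise ValueError(
            f"relationship matrix is not positive semidefinite (min eig {theta[0]:.3g})"
        )
    theta = np.maximum(theta, 0.0)
    eta = v[:, 1:].T @ y
    eta2 = eta**2
    nf = n - 1  # residual degrees of freedom after the intercept

    def neg_reml(log_delta: float) -> float:
        d = theta + 10.0**log_delta
        return nf * np.log(eta2 @ (1.0 / d)) + np.log(d).sum()

    res = optimize.minimize_scalar(
        neg_reml, bounds=_LOG_DELTA_BOUNDS, method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization did not converge: {res.message}")
    delta = 10.0**res.x
    dvec = theta + delta
    var_u = float(eta2 @ (1.0 / dvec) / nf)
    var_e = float(delta * var_u)
    loglik = -0.5 * (
        nf * np.log(var_u) + np.log(dvec).sum() + nf + nf * np.log(2.0 * np.pi)
    )

    # GLS intercept and BLUP through (K_tt + delta I)^-1
    h = k_tt + delta * np.eye(n)
    try:
        cho = linalg.cho_factor(h, lower=True)
    except linalg.LinAlgError:
        cho = linalg.cho_factor(h + _JITTER * np.eye(n), lower=True)
    ones = np.ones(n)
    hi_y = linalg.cho_solve(cho, y)
    hi_1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ hi_y / (ones @ hi_1))
    alpha = linalg.cho_solve(cho, y - mu)
    ebv_all = relmat.values[:, t] @ alpha
    return MixedModelFit(
        var_additive=var_u,
        var_residual=var_e,
        intercept=mu,
        ebv=pd.Series(ebv_all, index=relmat.ids),
        loglik=float(loglik),
    )


def blup_known_variance(
    y: np.ndarray,
    obs_pos: np.ndarray,
    k: np.ndarray,
    var_u: float,
    var_e: float,
) -> np.ndarray:
    """BLUP of u for every row of ``k`` given phenotypes at ``obs_pos`` and
    known variance components (no REML step; used for selection EBVs)."""
    n = obs_pos.size
    h = var_u * k[np.ix_(obs_pos, obs_pos)] + var_e * np.eye(n)
    cho = linalg.cho_factor(h, lower=True)
    ones = np.ones(n)
    hi_y = linalg.cho_solve(cho, y)
    hi_1 = linalg.cho_solve(cho, ones)
    mu = float(ones @ hi_y / (ones @ hi_1))
    alpha = linalg.cho_solve(cho, y - mu)
    return var_u * (k[:, obs_pos] @ alpha)


def _train_phenotypes(population: Population, split: SplitPlan) -> pd.Series:
    if population.phenotype is None:
        raise ValueError("population carries no phenotypes")
    s = pd.Series(population.phenotype, index=population.ids)
    return s.loc[split.train_ids]


def predict_gebv(
    population: Population,
    panel: GenotypeMatrix,
    split: SplitPlan,
    transition: TransitionMatrix | None = None,
    seed: int = 0,
) -> MixedModelFit:
    """GBLUP for a generation: GRM from the (optionally error-corrupted)
    panel genotypes of all individuals, trained on the unmasked sibs."""
    observed = panel if transition is None else inject_errors(panel, transition, seed)
    grm = compute_grm(observed)
    return fit_mixed_model(_train_phenotypes(population, split), grm)


def predict_ebv(
    population: Population,
    pedigree: pd.DataFrame,
    split: SplitPlan,
    nrm: RelationshipMatrix | None = None,
) -> MixedModelFit:
    """Pedigree BLUP for a generation: the NRM is built over the full
    pedigree back to the founders, then restricted to the generation."""
    if nrm is None:
        nrm = compute_nrm(pedigree)
    a_gen = nrm.subset(population.ids)
    return fit_mixed_model(_train_phenotypes(population, split), a_gen)
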