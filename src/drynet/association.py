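"""Pairwise association inference: Pearson with FDR, and SparCC.

Pearson correlation across samples, with two-sided p-values from the exact
t-distribution of r under the bivariate-normal null, is the primary method.
Benjamini-Hochberg step-up over the upper-triangle p-values supplies the FDR
q-values that gate network edges.  SparCC provides the compositionally aware
alternative: it estimates correlations between latent (basis) abundances from
log-ratio variances, iteratively excluding strongly correlated pairs so the
sparsity assumption behind the basis-variance solve holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import AbundanceMatrix
from .tables_io import CountTable

logger = logging.getLogger(__name__)


@dataclass
class AssociationMatrix:
    """Symmetric pairwise association estimates with p and FDR q values.

    ``r`` has unit diagonal; ``p`` and ``q`` are meaningful off-diagonal only
    (their diagonals are 0).  ``constant_taxa`` flags profiles with zero
    variance, for which r=0 and p=1 by policy.
    """

    taxon_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    q: np.ndarray | None
    method: str
    n_samples: int
    constant_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = len(self.taxon_ids)
        if self.r.shape != (d, d):
            raise ValueError("r shape does not match taxon count")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("r must be symmetric")
        if np.abs(self.r).max(initial=0) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class VariationDecomposition:
    """SparCC log-ratio variation components.

    ``T`` is the matrix of log-ratio variances T_ij = Var log(x_i/x_j)
    (zero diagonal, non-negative), ``t`` its row sums, and ``omega`` the
    solved basis variances (floored at a small positive value).
    """

    T: np.ndarray
    t: np.ndarray
    omega: np.ndarray


def pearson_with_p(X: AbundanceMatrix) -> AssociationMatrix:
    """All-pairs Pearson r across samples with two-sided parametric p.

    p comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    Constant profiles (zero variance) get r = 0 and p = 1, and are flagged.
    """
    values = X.values.to_numpy(dtype=float)
    d, n = values.shape
    if n < 3:
        raise ValueError(f"Pearson correlation needs at least 3 samples, got {n}")
    sd = values.std(axis=1)
    constant = sd == 0
    centred = values - values.mean(axis=1, keepdims=True)
    denom = np.sqrt((centred ** 2).sum(axis=1))
    denom[constant] = 1.0  # avoid 0/0; rows zeroed below
    normed = centred / denom[:, None]
    r = normed @ normed.T
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[~np.isfinite(tstat)] = 0.0  # |r| == 1
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    np.fill_diagonal(p, 0.0)

    flagged = [X.taxon_ids[i] for i in np.flatnonzero(constant)]
    if flagged:
        logger.warning("pearson_with_p: %d constant profile(s): %s",
                       len(flagged), ", ".join(flagged[:10]))
    return AssociationMatrix(list(X.taxon_ids), r, p, None, "pearson", n, flagged)


def bh_fdr(assoc: AssociationMatrix) -> AssociationMatrix:
    """Benjamini-Hochberg q-values over the upper-triangle p-values.

    Each unordered pair is tested once; q is mirrored to the lower triangle.
    """
    d = len(assoc.taxon_ids)
    iu = np.triu_indices(d, k=1)
    q = np.zeros_like(assoc.p)
    if iu[0].size:
        _, qvals, _, _ = multipletests(assoc.p[iu], method="fdr_bh")
        q[iu] = qvals
        q[(iu[1], iu[0])] = qvals
    return AssociationMatrix(
        assoc.taxon_ids, assoc.r, assoc.p, q, assoc.method,
        assoc.n_samples, assoc.constant_taxa,
    )


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

_OMEGA_FLOOR = 1e-6


def _logratio_variation(logfrac: np.ndarray) -> VariationDecomposition:
    """T_ij = Var_samples log(x_i/x_j) from per-taxon log fractions."""
    cov = np.cov(logfrac)
    v = np.diag(cov)
    T = v[:, None] + v[None, :] - 2.0 * cov
    T = np.maximum((T + T.T) / 2.0, 0.0)
    np.fill_diagonal(T, 0.0)
    t = T.sum(axis=1)
    return VariationDecomposition(T, t, np.empty(0))


def _basis_correlations(var: VariationDecomposition,
                        excluded: set[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Solve basis variances and correlations given excluded pairs.

    Solves M omega = t where, with no exclusions, t_i = (D-2) omega_i +
    sum_k omega_k; excluding pair (i, j) removes T_ij from both row sums and
    drops the corresponding couplings from M.
    """
    D = var.T.shape[0]
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    t = var.t.copy()
    for i, j in excluded:
        t[i] -= var.T[i, j]
        t[j] -= var.T[i, j]
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        M[i, j] -= 1.0
        M[j, i] -= 1.0
    omega = np.linalg.solve(M, t)
    n_neg = int((omega <= 0).sum())
    if n_neg:
        logger.warning("sparcc: clipped %d non-positive basis variance(s)", n_neg)
        omega = np.maximum(omega, _OMEGA_FLOOR)
    rho = (omega[:, None] + omega[None, :] - var.T) / (
        2.0 * np.sqrt(np.outer(omega, omega))
    )
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return omega, rho


def _sparcc_rho(counts: np.ndarray, n_dirichlet: int, excl_threshold: float,
                excl_iters: int, rng: np.random.Generator) -> np.ndarray:
    """One SparCC correlation estimate from a D x n count matrix."""
    D, n = counts.shape
    frac = np.zeros((D, n))
    alpha = counts + 1.0
    for _ in range(n_dirichlet):
        for s in range(n):
            frac[:, s] += rng.dirichlet(alpha[:, s])
    frac /= n_dirichlet
    var = _logratio_variation(np.log(frac))
    excluded: set[tuple[int, int]] = set()
    _, rho = _basis_correlations(var, excluded)
    for _ in range(excl_iters):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= excl_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        _, rho = _basis_correlations(var, excluded)
    return rho


def sparcc(table: CountTable, n_dirichlet: int = 20, excl_threshold: float = 0.1,
           excl_iters: int = 10, n_boot: int = 100, seed: int = 0) -> AssociationMatrix:
    """SparCC compositional correlations with permutation p-values.

    Fractions are posterior means over ``n_dirichlet`` Dirichlet(counts + 1)
    draws; basis variances are solved from log-ratio variances under the
    sparsity assumption, with up to ``excl_iters`` rounds excluding the
    strongest |rho| pair above ``excl_threshold``.  Two-sided p-values come
    from ``n_boot`` permutations of each taxon's samples, with the add-one
    estimator p = (1 + #{|rho_null| >= |rho_obs|}) / (1 + n_boot).
    """
    counts = table.counts.to_numpy(dtype=float)
    D, n = counts.shape
    if D <= 3:
        raise ValueError(f"SparCC needs more than 3 taxa, got {D}")
    if n < 4:
        raise ValueError(f"SparCC needs at least 4 samples, got {n}")
    rng = np.random.default_rng(seed)
    rho = _sparcc_rho(counts, n_dirichlet, excl_threshold, excl_iters, rng)

    exceed = np.zeros((D, D))
    abs_obs = np.abs(rho)
    for _ in range(n_boot):
        perm = counts.copy()
        for i in range(D):
            perm[i] = perm[i, rng.permutation(n)]
        rho_null = _sparcc_rho(perm, 1, excl_threshold, excl_iters, rng)
        exceed += np.abs(rho_null) >= abs_obs
    p = (1.0 + exceed) / (1.0 + n_boot)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 0.0)
    return AssociationMatrix(table.taxon_ids, rho, p, None, "sparcc", n)
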