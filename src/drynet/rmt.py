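"""Random-matrix-theory threshold selection.

The idea: threshold the absolute correlation matrix at increasing cutoffs and
watch the nearest-neighbour spacing distribution (NNSD) of its unfolded
eigenvalues.  A noise-dominated matrix behaves like a Gaussian orthogonal
ensemble (GOE) member — spacings follow the Wigner surmise with level
repulsion — whereas a matrix reduced to its modular signal has uncorrelated
eigenvalues and Poisson spacing statistics.  The transition point is the
threshold at which genuine structure separates from noise.

The full pipeline defaults to the fixed published cutoff 0.6; the scan here
is the method's provenance and a per-dataset diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .association import AssociationMatrix

logger = logging.getLogger(__name__)

_SPACING_BINS = np.arange(0.0, 3.0 + 1e-9, 0.1)  # plus an open overflow bin
_MIN_EIGENVALUES = 20
_DEDUP_TOL = 1e-8


class DegenerateSpectrumError(ValueError):
    """Too few distinct eigenvalues to unfold; try a lower threshold."""


@dataclass
class ThresholdDiagnostics:
    threshold: float
    n_nodes: int
    n_edges: int
    chi2_poisson: float | None
    chi2_wigner: float | None
    status: str  # "ok" | "degenerate" | "empty"


@dataclass
class ThresholdScan:
    thresholds: list[float]
    diagnostics: list[ThresholdDiagnostics]
    optimal_threshold: float | None
    alpha: float
    chi2_critical: float


def unfold_spacings(eigenvalues: np.ndarray) -> np.ndarray:
    """Unfold a spectrum to unit mean spacing.

    The cumulative spectral function is smoothed by a monotone cubic (PCHIP)
    fit over ceil(N/10) knots; unfolded levels e_i are the smoothed CDF at
    each eigenvalue scaled to [0, N], and spacings are successive differences
    normalised to mean exactly 1.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    # collapse numerically identical levels
    keep = np.ones(lam.size, dtype=bool)
    keep[1:] = np.diff(lam) > _DEDUP_TOL
    lam = lam[keep]
    N = lam.size
    if N < _MIN_EIGENVALUES:
        raise DegenerateSpectrumError(
            f"only {N} distinct eigenvalues (need >= {_MIN_EIGENVALUES}); "
            "use a lower threshold"
        )
    n_knots = max(int(np.ceil(N / 10)), 3)
    knot_idx = np.unique(np.linspace(0, N - 1, n_knots).round().astype(int))
    knot_x = lam[knot_idx]
    knot_y = (knot_idx + 1).astype(float)  # empirical cumulative count
    # strictly increasing abscissae required by the monotone fit
    knot_x, ux = np.unique(knot_x, return_index=True)
    knot_y = knot_y[ux]
    if knot_x.size < 2:
        raise DegenerateSpectrumError("spectrum too clustered to unfold")
    cdf = PchipInterpolator(knot_x, knot_y, extrapolate=True)
    e = np.asarray(cdf(lam), dtype=float)
    e = np.maximum.accumulate(e)
    span = e[-1] - e[0]
    if span <= 0:
        raise DegenerateSpectrumError("flat smoothed spectral function")
    e = (e - e[0]) * (N / span)
    d = np.diff(e)
    d = d / d.mean()
    return d


def _chi2_vs_density(spacings: np.ndarray, cdf) -> float:
    """Binned chi-square of observed spacings against a reference NNSD.

    Bins of width 0.1 on [0, 3] plus an overflow bin; adjacent bins are
    merged until every expected count is >= 1 so the statistic is stable.
    """
    n = spacings.size
    edges = _SPACING_BINS
    obs = np.histogram(spacings, bins=np.append(edges, np.inf))[0].astype(float)
    cdf_vals = np.append(cdf(edges), 1.0)
    exp = n * np.diff(cdf_vals)
    # merge low-expectation bins from the right tail inward
    obs_m: list[float] = []
    exp_m: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 1.0:
            obs_m.append(acc_o)
            exp_m.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_m:
        obs_m[-1] += acc_o
        exp_m[-1] += acc_e
    obs_a, exp_a = np.array(obs_m), np.array(exp_m)
    return float(((obs_a - exp_a) ** 2 / exp_a).sum())


def poisson_nnsd_cdf(d: np.ndarray) -> np.ndarray:
    """CDF of the Poisson NNSD, density exp(-d)."""
    return 1.0 - np.exp(-np.asarray(d, dtype=float))


def wigner_nnsd_cdf(d: np.ndarray) -> np.ndarray:
    """CDF of the Wigner surmise (GOE), density (pi/2) d exp(-pi d^2 / 4)."""
    d = np.asarray(d, dtype=float)
    return 1.0 - np.exp(-np.pi * d ** 2 / 4.0)


def nnsd_chi2(spacings: np.ndarray) -> tuple[float, float]:
    """(chi2 vs Poisson, chi2 vs Wigner/GOE) for unfolded spacings."""
    return (_chi2_vs_density(spacings, poisson_nnsd_cdf),
            _chi2_vs_density(spacings, wigner_nnsd_cdf))


def _threshold_matrix(r: np.ndarray, threshold: float) -> tuple[np.ndarray, int, int]:
    """|r| with sub-threshold entries zeroed; isolated rows dropped."""
    a = np.abs(np.asarray(r, dtype=float)).copy()
    np.fill_diagonal(a, 0.0)
    a[a < threshold] = 0.0
    keep = (a > 0).any(axis=1)
    a = a[np.ix_(keep, keep)]
    n_edges = int((a > 0).sum() // 2)
    np.fill_diagonal(a, 1.0)
    return a, int(keep.sum()), n_edges


def rmt_scan(assoc: AssociationMatrix, t_min: float = 0.30, t_max: float = 0.95,
             step: float = 0.01, alpha: float = 0.001) -> ThresholdScan:
    """Scan correlation thresholds for the GOE-to-Poisson NNSD transition.

    At each threshold the sub-threshold |r| entries are zeroed, taxa without
    any retained partner are dropped, and the NNSD of the unfolded spectrum
    is tested against the Poisson density by a binned chi-square.  The
    optimal threshold is the smallest one accepted at level ``alpha`` whose
    acceptance persists for every larger evaluable threshold.
    """
    if not 0 < t_min < t_max <= 1:
        raise ValueError("need 0 < t_min < t_max <= 1")
    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    diags: list[ThresholdDiagnostics] = []
    for t in thresholds:
        a, n_nodes, n_edges = _threshold_matrix(assoc.r, float(t))
        if n_nodes == 0:
            if t == thresholds[0]:
                raise ValueError(
                    f"no correlations survive the minimum threshold {t_min}"
                )
            diags.append(ThresholdDiagnostics(float(t), 0, 0, None, None, "empty"))
            continue
        try:
            lam = np.linalg.eigvalsh(a)
            d = unfold_spacings(lam)
        except DegenerateSpectrumError:
            diags.append(ThresholdDiagnostics(
                float(t), n_nodes, n_edges, None, None, "degenerate"))
            continue
        chi2_p, chi2_w = nnsd_chi2(d)
        diags.append(ThresholdDiagnostics(
            float(t), n_nodes, n_edges, chi2_p, chi2_w, "ok"))

    # dof: bins minus one; use the nominal 31-bin layout for the critical value
    crit = float(stats.chi2.ppf(1.0 - alpha, df=len(_SPACING_BINS) - 1))
    optimal: float | None = None
    ok = [dg for dg in diags if dg.status == "ok"]
    for idx, dg in enumerate(ok):
        if all(later.chi2_poisson < crit for later in ok[idx:]):
            optimal = dg.threshold
            break
    return ThresholdScan([float(t) for t in thresholds], diags, optimal, alpha, crit)
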