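"""Combining variance-component and burden statistics.

Three strategies for jointly testing rare and common variants (or SKAT and
burden components) computed on the same null model:

* the weighted variance-component sum ``Qws = (1-lam) Q_rare + lam Q_common``
  whose null distribution is the chi-square mixture of the summed kernel;
* Fisher pooling of the two correlated p-values with Brown's
  Satterthwaite-style scaled-chi-square correction;
* the rho-grid combination ``Q(rho) = (1-rho) Q_SKAT + rho Q_burden``
  (the SKAT-O statistic) with a resampling-calibrated overall p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .aggregation import (
    BurdenResult,
    SkatResult,
    davies_pvalue,
    liu_pvalue,
    _psd_eigvals,
)
from .core import NullModel

__all__ = [
    "WeightedSumResult",
    "PooledResult",
    "RhoGridResult",
    "weighted_sum_test",
    "fisher_brown",
    "estimate_null_correlation",
    "rho_grid_combine",
]


@dataclass
class WeightedSumResult:
    lam: float
    q: float
    eigenvalues: np.ndarray
    p: float
    method: str
    flags: tuple = ()

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda outside [0, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass
class PooledResult:
    p_values: np.ndarray
    brown_c: float
    brown_df: float
    statistic: float  # T = -2 sum log p
    p: float


@dataclass
class RhoGridResult:
    grid: np.ndarray
    q_per_rho: np.ndarray
    p_per_rho: np.ndarray
    min_p: float
    p: float  # resampling-calibrated overall p
    n_draws: int

    def __post_init__(self):
        if not 0.0 < self.p <= 1.0:
            raise ValueError("overall p must be in (0, 1]")


def weighted_sum_test(
    rare: SkatResult, common: SkatResult, lam: float
) -> WeightedSumResult:
    """Weighted sum of two variance components, Qws = (1-lam) Qr + lam Qc.

    When both inputs carry their projected half-kernels (linear kernels from
    :func:`~priorvar.aggregation.skat_test`), the null eigenvalues come from
    the joint decomposition of ``(1-lam) K_rare + lam K_common`` so that LD
    between the rare and common sets is handled exactly.  Otherwise the two
    scaled eigenvalue lists are concatenated (independence approximation)
    and the result is flagged "concatenated".
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda outside [0, 1]")
    q = (1.0 - lam) * rare.q + lam * common.q
    flags = ()
    if rare._half_kernel is not None and common._half_kernel is not None:
        if rare._half_kernel.shape[0] != common._half_kernel.shape[0]:
            raise ValueError("rare/common statistics use different subjects")
        C = np.hstack(
            [np.sqrt(1.0 - lam) * rare._half_kernel, np.sqrt(lam) * common._half_kernel]
        )
        lamv = _psd_eigvals(C.T @ C, "Qws")
    else:
        lamv = np.sort(
            np.concatenate(
                [(1.0 - lam) * rare.eigenvalues, lam * common.eigenvalues]
            )
        )[::-1]
        lamv = lamv[lamv > 0]
        flags = ("concatenated",)
    p, method, _ = davies_pvalue(q, lamv)
    return WeightedSumResult(lam, q, lamv, p, method, flags)


# Brown's polynomial mapping from statistic correlation to the covariance of
# -2 log p terms (documented constant choice).
def _brown_cov(rho: np.ndarray) -> np.ndarray:
    return rho * (3.263 + rho * (0.710 + 0.027 * rho))


def fisher_brown(p_values, null_stat_correlation) -> PooledResult:
    """Fisher pooling of correlated p-values with Brown's correction.

    T = -2 sum log p_i has mean 2k; its variance 4k + 2 sum_{i<j} cov_ij is
    built from the pairwise correlations of the underlying statistics via
    the standard cubic approximation.  T is referred to a scaled chi-square
    c * chi2_f with c = Var/(2E) and f = 2E^2/Var; zero correlation reduces
    to plain Fisher (c = 1, f = 2k).
    """
    p = np.asarray(p_values, dtype=float)
    k = p.size
    if k < 2:
        raise ValueError("need at least two p-values to pool")
    if p.min() <= 0 or p.max() > 1:
        raise ValueError("p-values must lie in (0, 1]")
    R = np.asarray(null_stat_correlation, dtype=float)
    if R.shape != (k, k):
        raise ValueError("correlation matrix shape mismatch")
    if np.linalg.eigvalsh(0.5 * (R + R.T)).min() < -1e-8:
        raise ValueError("correlation matrix not positive semidefinite")
    T = float(-2.0 * np.log(p).sum())
    mean = 2.0 * k
    iu = np.triu_indices(k, 1)
    var = 4.0 * k + 2.0 * float(_brown_cov(R[iu]).sum())
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    pooled = float(chi2.sf(T / c, f))
    return PooledResult(p, c, f, T, pooled)


def _liu_params(eigenvalues):
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    return lam


def estimate_null_correlation(
    rare: SkatResult,
    common: SkatResult,
    nm: NullModel,
    n_draws: int = 1000,
    rng=None,
):
    """Correlation of -2 log p between two statistics under the null, by
    parametric resampling from the fitted null covariance.

    Draws whitened residual vectors z ~ N(0, I), projects them through the
    null design, recomputes both quadratic forms, maps each to a p-value
    with the moment-matched mixture approximation (a fixed monotone
    transform of Q, so the correlation is insensitive to the choice), and
    reports the empirical correlation of -2 log p with its resampling SE.
    Requires linear-kernel results carrying their half-kernels.
    """
    if n_draws < 200:
        raise ValueError("n_draws < 200: correlation estimate too noisy")
    if rare._half_kernel is None or common._half_kernel is None:
        raise ValueError("both results must carry linear half-kernels")
    rng = np.random.default_rng(rng)
    Z = rng.standard_normal((nm.n, n_draws))
    x = np.empty((2, n_draws))
    for row, res in enumerate((rare, common)):
        U = res._half_kernel.T @ Z
        qd = np.einsum("ij,ij->j", U, U)
        pd = np.clip(liu_pvalue(qd, res.eigenvalues), 1e-300, 1.0)
        x[row] = -2.0 * np.log(pd)
    corr = np.corrcoef(x)
    rho = corr[0, 1]
    se = (1.0 - rho**2) / np.sqrt(n_draws)
    return corr, float(se)


def estimate_null_correlation_from_dosages(
    d_rare,
    d_common,
    nm: NullModel,
    n_draws: int = 1000,
    rng=None,
    weights_rare=None,
    weights_common=None,
):
    """Convenience wrapper: build unit-weight (or supplied-weight) linear
    SKAT statistics for two dosage matrices and estimate their null
    correlation."""
    import numpy as _np

    from .aggregation import KernelSpec, skat_test
    from .weights import WeightVector

    def make(d, w):
        if w is None:
            w = WeightVector(d.variants["id"].to_numpy(), _np.ones(d.n_variants))
        return skat_test(d, nm, KernelSpec("weighted_linear", w))

    return estimate_null_correlation(
        make(d_rare, weights_rare), make(d_common, weights_common), nm, n_draws, rng
    )


def rho_grid_combine(
    skat: SkatResult,
    burden: BurdenResult,
    grid,
    nm: NullModel,
    n_draws: int = 1000,
    rng=None,
) -> RhoGridResult:
    """SKAT-O style combination Q(rho) = (1-rho) Q_SKAT + rho Q_burden.

    Per grid point the mixed kernel (variance component plus the rank-one
    burden kernel) is eigendecomposed and a Davies p-value reported.  The
    overall statistic is the minimum p over the grid; because the minimum-p
    statistic has no closed-form null, its p-value is calibrated by
    parametric resampling from the null model: each draw's minimum p is
    computed with the same monotone moment-matched transform used on the
    observed data, and the overall p is the add-one permutation estimator
    (never exactly zero).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("rho grid outside [0, 1]")
    if skat._half_kernel is None or burden._b_proj is None:
        raise ValueError("inputs must carry half-kernel / projected burden")
    rng = np.random.default_rng(rng)
    A = skat._half_kernel  # n x m, P Linv G W^(1/2)
    b = burden._b_proj[:, None]  # n x 1
    yw = nm.whiten(nm.trait)
    q_burden = float((b[:, 0] @ yw) ** 2)

    eigs, qs, ps = [], [], []
    for rho in grid:
        C = np.hstack([np.sqrt(1.0 - rho) * A, np.sqrt(rho) * b])
        lam = _psd_eigvals(C.T @ C, f"rho={rho}")
        q = (1.0 - rho) * skat.q + rho * q_burden
        p, _, _ = davies_pvalue(q, lam)
        eigs.append(lam)
        qs.append(q)
        ps.append(p)
    qs, ps = np.asarray(qs), np.asarray(ps)

    # calibration: identical monotone Q -> p map (Liu) for data and draws
    obs_liu = np.array([liu_pvalue(q, lam) for q, lam in zip(qs, eigs)])
    min_p_obs = float(obs_liu.min())
    Z = rng.standard_normal((nm.n, n_draws))
    min_p_draws = np.full(n_draws, np.inf)
    for rho, lam in zip(grid, eigs):
        C = np.hstack([np.sqrt(1.0 - rho) * A, np.sqrt(rho) * b])
        U = C.T @ Z
        qd = np.einsum("ij,ij->j", U, U)
        min_p_draws = np.minimum(min_p_draws, liu_pvalue(qd, lam))
    overall = (1.0 + np.sum(min_p_draws <= min_p_obs)) / (1.0 + n_draws)
    return RhoGridResult(grid, qs, ps, float(ps.min()), float(overall), n_draws)
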