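"""Effective number of independent tests and the LD-adjusted alpha level.

Under the global null the minimum of n independent uniform p-values follows
beta(1, n).  With correlated tests the minimum p over a scan still follows a
beta(1, n_e) law to good approximation, where n_e <= n is the effective
number of independent tests.  Fitting beta(1, n_e) to the minimum p-values
of replicated null-trait scans therefore yields an LD-aware multiple-testing
correction alpha* = alpha / n_e, less conservative than Bonferroni over the
raw test count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import kstest
from scipy.stats import t as t_dist

from .core import DosageMatrix, KinshipMatrix, NullModel

__all__ = [
    "MinPSample",
    "EffectiveTests",
    "single_variant_test",
    "null_minp_replicates",
    "fit_beta_ne",
]


@dataclass
class MinPSample:
    """Minimum p-values over all single-locus tests, one per replicate."""

    min_p: np.ndarray
    n_tests: int

    def __post_init__(self):
        self.min_p = np.asarray(self.min_p, dtype=float)
        if np.any((self.min_p <= 0) | (self.min_p >= 1)):
            # exact 0/1 handled downstream; reject clearly invalid input
            if np.any((self.min_p < 0) | (self.min_p > 1)):
                raise ValueError("min p outside [0, 1]")

    def __len__(self):
        return len(self.min_p)


@dataclass
class EffectiveTests:
    n_e: float
    n: int
    alpha_star: float
    ks_stat: float
    flags: tuple = ()

    @property
    def ratio(self) -> float:
        return self.n_e / self.n if self.n else float("nan")


def single_variant_test(d: DosageMatrix, nm: NullModel, details: bool = False):
    """Per-variant two-sided p-values from the mixed-model score statistic.

    Each variant is tested in whitened coordinates (trait decorrelated by
    the fitted null covariance), where the statistic reduces to the exact
    ordinary-regression t-test of the variant coefficient given the
    covariates; with no kinship this is ordinary least squares.  Monomorphic
    variants are skipped (p = NaN) and flagged.
    """
    if list(d.subjects) != list(nm.subjects):
        raise ValueError("dosage and null-model subjects differ")
    G = nm.project(nm.whiten(d.dosages))
    y = nm.resid_white
    df = nm.n - nm.rank - 1
    gss = np.einsum("ij,ij->j", G, G)
    yss = float(y @ y)
    mono = gss <= 1e-12 * max(1.0, float(np.max(gss, initial=1.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (G.T @ y) / np.sqrt(gss * yss)
        c = np.clip(c, -1.0, 1.0)
        t = c * np.sqrt(df / np.maximum(1.0 - c**2, 1e-300))
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p[mono] = np.nan
    if not details:
        return p
    import pandas as pd

    return pd.DataFrame(
        {"id": d.variants["id"], "t": t, "p": p, "skipped_monomorphic": mono}
    )


def null_minp_replicates(
    d: DosageMatrix,
    m: int,
    kinship: KinshipMatrix | None = None,
    sigma_g2: float = 0.0,
    sigma_e2: float = 1.0,
    rng=None,
) -> MinPSample:
    """Minimum p per replicate of a null (no genetic effect) trait scan.

    Traits are simulated parametrically from the familial covariance
    sigma_g2 * 2K + sigma_e2 * I (pure noise when no kinship is given), each
    replicate is scanned with the per-variant test of
    :func:`single_variant_test` against an intercept-only null model with
    the generating covariance, and the smallest p is recorded.  All
    replicates are tested in one vectorized pass.
    """
    if m < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(rng)
    n = d.n_subjects
    Z = rng.standard_normal((n, m))
    if kinship is not None and sigma_g2 > 0:
        Sigma = sigma_g2 * 2.0 * kinship.align(d.subjects).values + sigma_e2 * np.eye(n)
        w, U = np.linalg.eigh(Sigma)
        w = np.clip(w, 1e-12, None)
        Linv = (U * (1.0 / np.sqrt(w))) @ U.T
        Gw = Linv @ d.dosages
        ones = Linv @ np.ones(n)
    else:
        # traits are already white; covariance scale cancels in the t-test
        Gw = d.dosages.copy()
        ones = np.ones(n)
    # project out the (whitened) intercept
    q0 = ones / np.linalg.norm(ones)
    Gp = Gw - np.outer(q0, q0 @ Gw)
    Yp = Z - np.outer(q0, q0 @ Z)
    df = n - 2
    gss = np.einsum("ij,ij->j", Gp, Gp)
    keep = gss > 1e-12 * max(1.0, float(np.max(gss, initial=1.0)))
    Gp, gss = Gp[:, keep], gss[keep]
    yss = np.einsum("ij,ij->j", Yp, Yp)
    C = (Gp.T @ Yp) / np.sqrt(np.outer(gss, yss))
    np.clip(C, -1.0, 1.0, out=C)
    T = C * np.sqrt(df / np.maximum(1.0 - C**2, 1e-300))
    P = 2.0 * t_dist.sf(np.abs(T), df)
    return MinPSample(P.min(axis=0), int(keep.sum()))


def fit_beta_ne(sample: MinPSample, alpha: float = 0.05) -> EffectiveTests:
    """Maximum-likelihood fit of beta(1, n_e) to replicate minimum p-values.

    For beta(1, b) the MLE has the closed form b_hat = -m / sum log(1 - p_i).
    Reports the adjusted significance level alpha* = alpha / n_e and the
    Kolmogorov-Smirnov statistic of the fit.  An n_e above the raw test
    count is flagged (not fatal); p = 1 is an error and p = 0 is clamped to
    the machine minimum with a flag.
    """
    p = np.asarray(sample.min_p, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 replicates to fit n_e")
    flags = []
    if np.any(p >= 1.0):
        raise ValueError("minimum p of 1 encountered; log(1 - p) undefined")
    if np.any(p <= 0.0):
        p = np.maximum(p, np.finfo(float).tiny)
        flags.append("zero_p_clamped")
    n_e = float(-len(p) / np.sum(np.log1p(-p)))
    if sample.n_tests and n_e > sample.n_tests:
        flags.append("n_e_exceeds_n")
    ks = float(kstest(p, beta_dist(1.0, n_e).cdf).statistic)
    return EffectiveTests(n_e, sample.n_tests, alpha / n_e, ks, tuple(flags))
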