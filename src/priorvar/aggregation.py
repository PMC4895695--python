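"""Region-level rare-variant association tests.

Burden tests collapse weighted minor-allele dosages into one score per
subject, ``s_k = sum_i w_i x_ik``, and test its association with the trait
by a score test against the fitted null model (T5 restricts to variants
with MAF <= 5%).  SKAT is the variance-component counterpart: its statistic
is a quadratic form ``Q = r' K r`` in the whitened null residuals, whose
null distribution is a mixture of independent 1-df chi-squares with the
eigenvalues of the projected kernel as mixture coefficients.  Tail
probabilities of that mixture come from numerical inversion of the
characteristic function (Davies-style, implemented via the Imhof integral)
with a moment-matched noncentral-chi-square fallback (Liu et al.).  A
permutation likelihood-ratio test on thresholded signed burdens covers the
case/control path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .core import DosageMatrix, NullModel, compute_maf
from .weights import WeightVector

__all__ = [
    "BurdenResult",
    "SkatResult",
    "KernelSpec",
    "LrtResult",
    "burden_score",
    "t5_test",
    "skat_test",
    "davies_pvalue",
    "liu_pvalue",
    "weighted_threshold_lrt",
]


# ---------------------------------------------------------------------------
# Chi-square mixture tails

_GL24 = np.polynomial.legendre.leggauss(24)


def _imhof_integral(q: float, lam: np.ndarray, tol: float):
    """Integral of sin(theta(u)) / (u rho(u)) over (0, inf) with an error bound.

    theta(u) = 0.5 sum_j arctan(lam_j u) - q u / 2 and
    rho(u) = prod_j (1 + lam_j^2 u^2)^(1/4).  The integrand's phase velocity
    is bounded by max(sum lam, q)/2, so fixed Gauss-Legendre panels of at
    most one oscillation each integrate it essentially exactly; the tail
    beyond the truncation point is bounded by one half-oscillation of the
    (monotone) envelope once theta' <= -q/4 there.
    """
    sumlam = float(lam.sum())

    def envelope(u):
        return np.exp(-np.log(u) - 0.25 * np.sum(np.log1p((lam * u) ** 2)))

    # truncation point: phase decreasing at rate >= q/4 and tail bound <= tol
    u_max = 1.0 / lam.max()
    while np.sum(lam / (1.0 + (lam * u_max) ** 2)) > 0.5 * q:
        u_max *= 2.0
    while 4.0 * envelope(u_max) / q > tol * np.pi:
        u_max *= 2.0
        if u_max > 1e300:
            raise FloatingPointError("imhof truncation point overflow")
    tail_bound = 4.0 * envelope(u_max) / (q * np.pi)

    h = 2.0 * np.pi / max(sumlam, q)  # at most ~one oscillation per panel
    n_panels = int(np.ceil(u_max / h))
    if n_panels > 2_000_000:
        raise FloatingPointError("imhof panel count too large")
    nodes, gl_w = _GL24
    edges = np.linspace(0.0, n_panels * h, n_panels + 1)
    total = 0.0
    chunk = 20_000
    for s in range(0, n_panels, chunk):
        lo = edges[s : min(s + chunk, n_panels)]
        hi = lo + h
        mid, half = 0.5 * (lo + hi), 0.5 * h
        u = mid[:, None] + half * nodes[None, :]  # panels x nodes
        theta = 0.5 * np.arctan(u[..., None] * lam).sum(axis=-1) - 0.5 * q * u
        logrho = 0.25 * np.log1p((u[..., None] * lam) ** 2).sum(axis=-1)
        vals = np.sin(theta) * np.exp(-np.log(u) - logrho)
        total += float(np.einsum("pn,n->", vals, gl_w) * half)
    return total / np.pi, tail_bound


def davies_pvalue(q: float, eigenvalues, acc: float = 1e-6):
    """P(sum_j lam_j chi2_1j > q) by characteristic-function inversion.

    Numerical inversion of the chi-square-mixture characteristic function
    (Imhof integral) with an explicit truncation bound; default accuracy
    target 1e-6.  Returns ``(p, method, err)`` where ``method`` is "davies"
    or, if the inversion fails its accuracy target, "liu_moment" (the
    moment-matched fallback, err = nan).  Eigenvalues must be nonnegative
    with at least one positive.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    if q <= 0:
        return 1.0, "davies", 0.0
    if lam.size == 1:  # exact: a single scaled 1-df chi-square
        return float(chi2.sf(q / lam[0], 1)), "davies", 0.0
    scale = lam.max()  # p is invariant under joint rescaling
    try:
        val, tail = _imhof_integral(q / scale, lam / scale, min(acc, 1e-8))
        p = 0.5 + val
        err = tail + 1e-10
    except FloatingPointError:
        return float(liu_pvalue(q, lam)), "liu_moment", float("nan")
    if not np.isfinite(p) or err > acc or p < -10 * acc or p > 1 + 10 * acc:
        return float(liu_pvalue(q, lam)), "liu_moment", float("nan")
    return float(min(max(p, 0.0), 1.0)), "davies", float(err)


def liu_pvalue(q, eigenvalues):
    """Moment-matched noncentral chi-square approximation to the mixture
    tail (Liu-Tang-Zhang).  Vectorized over q."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2.0 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = np.sqrt(2.0 * (df + 2.0 * delta))
    t = (np.asarray(q, dtype=float) - c1) / np.sqrt(2.0 * c2)
    return ncx2.sf(t * sigma_x + mu_x, df, delta)


def mixture_quantile(alpha: float, eigenvalues, acc: float = 1e-10) -> float:
    """Upper-alpha quantile of the chi-square mixture (bisection on the
    Davies tail)."""
    lam = np.asarray(eigenvalues, dtype=float)
    lo, hi = 0.0, float(np.sum(lam)) * 2 + 10 * float(np.max(lam))
    while davies_pvalue(hi, lam)[0] > alpha:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if davies_pvalue(mid, lam)[0] > alpha:
            lo = mid
        else:
            hi = mid
        if hi - lo < acc * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Results


@dataclass
class BurdenResult:
    region: str
    burden: np.ndarray
    score: float  # standardized score statistic (z)
    p: float | None
    n_variants: int
    flags: tuple = ()
    _b_proj: np.ndarray = field(repr=False, default=None)  # whitened, projected burden

    def __post_init__(self):
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass
class SkatResult:
    region: str
    q: float
    eigenvalues: np.ndarray  # nonincreasing, nonnegative
    p: float
    method: str  # davies | liu_moment
    n_variants: int = 0
    flags: tuple = ()
    _half_kernel: np.ndarray = field(repr=False, default=None)  # P @ Linv G W^(1/2)

    def __post_init__(self):
        if self.q < -1e-12:
            raise ValueError("Q must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p outside [0, 1]")
        lam = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvalues = np.sort(lam)[::-1]


@dataclass(frozen=True)
class KernelSpec:
    """SKAT kernel: 'weighted_linear' (no SNV interactions),
    'weighted_quadratic' ((1 + x'Wx)^2, pairwise interactions), or
    'weighted_ibs' (weighted allele-sharing)."""

    form: str
    weights: WeightVector

    def __post_init__(self):
        if self.form not in ("weighted_linear", "weighted_quadratic", "weighted_ibs"):
            raise ValueError(f"unknown kernel form {self.form!r}")


@dataclass
class LrtResult:
    region: str
    tau: float
    counts: np.ndarray  # 2x2: rows case/control, cols exceed/not
    lrt: float
    p: float
    n_perm: int

    def __post_init__(self):
        if not 0.0 < self.p <= 1.0:
            raise ValueError("permutation p must be in (0, 1]")


# ---------------------------------------------------------------------------
# Burden


def burden_score(d: DosageMatrix, w: WeightVector) -> np.ndarray:
    """Weighted minor-allele burden s_k = sum_i w_i x_ik per subject k.

    Dosages are used as stored (the minor-allele coding convention; the
    audit flags from :func:`~priorvar.core.compute_maf` report columns whose
    raw frequency exceeds 0.5).  Signed weights are honoured; the weight
    vector must align with the variant columns (matched by id when the ids
    correspond, by position otherwise)."""
    omega = _aligned_weights(d, w)
    return d.dosages @ omega


def _aligned_weights(d: DosageMatrix, w: WeightVector) -> np.ndarray:
    if len(w) != d.n_variants:
        raise ValueError(f"{len(w)} weights for {d.n_variants} variants")
    ids = np.asarray(w.ids).astype(str)
    dids = d.variants["id"].to_numpy().astype(str)
    if len(set(ids)) == len(ids) and set(ids) == set(dids):
        pos = {v: i for i, v in enumerate(ids)}
        order = [pos[v] for v in dids]
        return w.signed[order]
    return w.signed


def _score_test(b: np.ndarray, nm: NullModel):
    """Score test of a per-subject linear score against the null model.

    In whitened coordinates the statistic is U = b~' r~ with variance
    b~' P b~ (unit residual variance after whitening); returns
    (z, p_two_sided, b_proj)."""
    bw = nm.project(nm.whiten(b))
    var = float(bw @ bw)
    if var <= 1e-12 * max(1.0, float(b @ b)):
        return 0.0, None, bw
    u = float(bw @ nm.whiten(nm.trait))
    z = u / np.sqrt(var)
    return z, float(2.0 * norm.sf(abs(z))), bw


def t5_test(
    d: DosageMatrix,
    nm: NullModel,
    w: WeightVector,
    maf_cutoff: float = 0.05,
) -> BurdenResult:
    """Burden test restricted to variants with MAF <= maf_cutoff (T5 at the
    default 5% cutoff); two-sided p from the normal score statistic
    accounting for the null-model covariance."""
    if list(d.subjects) != list(nm.subjects):
        raise ValueError("dosage and null-model subjects differ")
    maf = compute_maf(d)
    keep = maf <= maf_cutoff
    label = "T5"
    if not keep.any():
        return BurdenResult(label, np.zeros(d.n_subjects), 0.0, None, 0, ("empty",))
    omega = _aligned_weights(d, w)[keep]
    sub = d.subset_variants(keep)
    b = sub.dosages @ omega
    z, p, bw = _score_test(b, nm)
    flags = () if p is not None else ("degenerate",)
    return BurdenResult(label, b, z, p, int(keep.sum()), flags, _b_proj=bw)


# ---------------------------------------------------------------------------
# SKAT


def _kernel_matrix(d: DosageMatrix, spec: KernelSpec) -> np.ndarray:
    X = d.dosages
    omega = _aligned_weights(d, spec.weights)
    if spec.form == "weighted_quadratic":
        return (1.0 + (X * omega) @ X.T) ** 2
    # weighted_ibs: IBS(a, b) = 2 - |a - b| per variant, weight-summed
    n = X.shape[0]
    K = np.zeros((n, n))
    for j in range(X.shape[1]):
        K += omega[j] * (2.0 - np.abs(X[:, j][:, None] - X[:, j][None, :]))
    return K


def skat_test(d: DosageMatrix, nm: NullModel, kernel: KernelSpec) -> SkatResult:
    """Variance-component (kernel) score test.

    Q = r~' K~ r~ with r~ the whitened, covariate-projected residuals and
    K~ the kernel mapped into whitened coordinates.  The null distribution
    is the chi-square mixture with eigenvalues of the projected kernel;
    p-values by davies_pvalue with liu_moment fallback, the method used is
    recorded on the result.
    """
    if d.n_variants == 0:
        raise ValueError("empty region")
    if list(d.subjects) != list(nm.subjects):
        raise ValueError("dosage and null-model subjects differ")
    label = "SKAT"
    omega = _aligned_weights(d, kernel.weights)
    if omega.min(initial=0.0) < 0:
        raise ValueError("SKAT kernel weights must be nonnegative")
    if kernel.form == "weighted_linear":
        half = nm.project(nm.whiten(d.dosages)) * np.sqrt(omega)
        u = half.T @ nm.whiten(nm.trait)
        q = float(u @ u)
        lam = _psd_eigvals(half.T @ half, label)
        if lam.size == 0:
            return SkatResult(label, q, lam, 1.0, "davies", d.n_variants,
                              ("degenerate",), _half_kernel=half)
        p, method, _ = davies_pvalue(q, lam)
        return SkatResult(label, q, lam, p, method, d.n_variants, _half_kernel=half)
    K0 = _kernel_matrix(d, kernel)
    A0 = nm.whiten(nm.whiten(K0).T)  # Linv K0 Linv (Linv symmetric)
    rw = nm.resid_white
    q = float(rw @ A0 @ rw)
    A = nm.project(nm.project(A0).T)  # P A0 P
    lam = _psd_eigvals(0.5 * (A + A.T), label)
    p, method, _ = davies_pvalue(q, lam)
    return SkatResult(label, q, lam, p, method, d.n_variants)


def _psd_eigvals(sym: np.ndarray, region: str, tol: float = 1e-10) -> np.ndarray:
    try:
        lam = np.linalg.eigvalsh(sym)
    except np.linalg.LinAlgError as e:
        raise RuntimeError(f"eigenvalue computation failed for region {region}") from e
    top = max(lam.max(initial=0.0), 0.0)
    lam = lam[lam > tol * max(top, 1.0)]
    return np.sort(lam)[::-1]


# ---------------------------------------------------------------------------
# Weighted-threshold permutation LRT (case/control)


def _binomial_lrt(counts: np.ndarray) -> float:
    """2 * (ell(p_case, p_ctrl) - ell(p_pooled)) under binomial likelihoods;
    equals the G statistic of the 2x2 table."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    rows = counts.sum(axis=1, keepdims=True)
    cols = counts.sum(axis=0, keepdims=True)
    expected = rows * cols / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / expected)
    return float(2.0 * np.nansum(np.where(counts > 0, terms, 0.0)))


def weighted_threshold_lrt(
    d: DosageMatrix,
    status,
    w: WeightVector,
    tau: float | None = None,
    n_perm: int = 1000,
    rng=None,
    blocks=None,
) -> LrtResult:
    """Test whether the proportion of subjects whose signed weighted burden
    exceeds tau differs between cases and controls.

    The observed statistic is the binomial likelihood-ratio (G) statistic of
    the 2x2 case/control x exceed/not table; its p-value comes from
    permuting status labels (add-one estimator, never exactly 0).  tau
    defaults to the median burden over all subjects.  When ``blocks`` (e.g.
    sibship labels) are given, permutation is restricted to within-block
    label swaps so familial dependence cannot inflate the type I error.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    status = np.asarray(status, dtype=int)
    if set(np.unique(status)) - {0, 1}:
        raise ValueError("status must be binary 0/1")
    if status.sum() == 0 or status.sum() == len(status):
        raise ValueError("one status class is empty")
    rng = np.random.default_rng(rng)
    b = burden_score(d, w)
    if tau is None:
        tau = float(np.median(b))
    exceed = b > tau

    def table(st):
        return np.array(
            [
                [np.sum(exceed & (st == 1)), np.sum(~exceed & (st == 1))],
                [np.sum(exceed & (st == 0)), np.sum(~exceed & (st == 0))],
            ]
        )

    obs = _binomial_lrt(table(status))
    if blocks is None:
        perm_idx = np.argsort(rng.random((n_perm, len(status))), axis=1)
        exceed_f = exceed.astype(float)
        # a = number of cases exceeding, under each permutation of status
        a = (status[perm_idx] * exceed_f[None, :]).sum(axis=1)
        n_case, n_exc, n = status.sum(), exceed.sum(), len(status)
        ge = 0
        for ai in a:
            t = np.array(
                [[ai, n_case - ai], [n_exc - ai, n - n_case - n_exc + ai]]
            )
            ge += _binomial_lrt(t) >= obs - 1e-12
    else:
        blocks = np.asarray(blocks)
        ge = 0
        for _ in range(n_perm):
            st = status.copy()
            for blk in np.unique(blocks):
                m = blocks == blk
                st[m] = rng.permutation(st[m])
            ge += _binomial_lrt(table(st)) >= obs - 1e-12
    p = (1.0 + ge) / (1.0 + n_perm)
    return LrtResult("LRT", float(tau), table(status), obs, p, n_perm)
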