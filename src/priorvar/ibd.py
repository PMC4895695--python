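"""Pairwise identity-by-descent regression mapping.

For each unordered pair of (nominally unrelated) subjects the squared
trait difference D = (T_i - T_j)^2 and squared trait sum S = (T_i + T_j)^2
are regressed separately on the pair's IBD sharing status at a locus.  At a
linked locus sharing pairs have more similar trait values, decreasing D and
increasing S, so the two slopes carry the same signal with opposite signs.
The slopes are combined by reciprocal-variance cross-weighting,

    beta = sD^2/(sS^2+sD^2) * beta_S + sS^2/(sS^2+sD^2) * beta_D,

tested with t = beta / SE(beta).  Because pairs sharing a subject are not
independent, the genome-wide significance threshold on |t| is estimated by
permuting subject trait labels (which preserves the pair dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairData",
    "IbdTestResult",
    "build_pairs",
    "pair_regression",
    "combined_slope",
    "permutation_threshold",
    "ibd_test",
]


@dataclass
class PairData:
    """Aligned pair arrays: subject indices, per-locus sharing, traits."""

    subjects: list
    traits: np.ndarray  # per subject, covariate-adjusted residuals
    ii: np.ndarray  # pair first-subject index
    jj: np.ndarray  # pair second-subject index
    loci: list
    sharing: np.ndarray  # n_pairs x n_loci, in [0, 1]
    n_dropped: int = 0

    def d_s(self, traits: np.ndarray | None = None):
        t = self.traits if traits is None else traits
        diff = t[self.ii] - t[self.jj]
        tot = t[self.ii] + t[self.jj]
        return diff**2, tot**2


@dataclass
class IbdTestResult:
    locus: str
    beta_s: float
    var_s: float
    beta_d: float
    var_d: float
    beta: float
    se: float
    t: float
    threshold: float | None = None
    p: float | None = None
    flags: tuple = ()


def build_pairs(traits: pd.Series, sharing: pd.DataFrame) -> PairData:
    """Assemble pair records from adjusted trait residuals and a sharing
    table with columns ``subject_i, subject_j, locus, sharing``.

    Self-pairs are an error; pairs with a missing trait are dropped and
    counted; each unordered pair appears once per locus.
    """
    sh = sharing.copy()
    sh["subject_i"] = sh["subject_i"].astype(str)
    sh["subject_j"] = sh["subject_j"].astype(str)
    if (sh["subject_i"] == sh["subject_j"]).any():
        raise ValueError("self-pair (i, i) in sharing table")
    known = set(traits.index.astype(str))
    ok = sh["subject_i"].isin(known) & sh["subject_j"].isin(known)
    n_dropped = int((~ok).sum())
    sh = sh[ok]
    # canonical unordered pair
    a = sh[["subject_i", "subject_j"]].min(axis=1)
    b = sh[["subject_i", "subject_j"]].max(axis=1)
    sh = sh.assign(subject_i=a, subject_j=b)
    if sh.duplicated(["subject_i", "subject_j", "locus"]).any():
        raise ValueError("duplicated pair-locus rows in sharing table")
    wide = sh.pivot(index=["subject_i", "subject_j"], columns="locus", values="sharing")
    if wide.isna().any().any():
        raise ValueError("sharing table is not complete over pairs x loci")
    subjects = sorted({s for pair in wide.index for s in pair})
    pos = {s: k for k, s in enumerate(subjects)}
    ii = np.array([pos[i] for i, _ in wide.index])
    jj = np.array([pos[j] for _, j in wide.index])
    # traits should be covariate-adjusted residuals (the adjustment -- at
    # least mean removal -- happens upstream; D is shift-invariant but S is
    # only meaningful for centered traits)
    tvec = traits.astype(float)
    tvec.index = tvec.index.astype(str)
    t = tvec.loc[subjects].to_numpy()
    vals = wide.to_numpy(dtype=float)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("sharing values outside [0, 1]")
    return PairData(subjects, t, ii, jj, list(wide.columns), vals, n_dropped)


def _ols_slope(x: np.ndarray, Y: np.ndarray):
    """Slope and squared SE of each column of Y on x (intercept included).
    Y may be 1-D or n_pairs x k."""
    Y2 = Y if Y.ndim == 2 else Y[:, None]
    xc = x - x.mean()
    xx = float(xc @ xc)
    n = len(x)
    Yc = Y2 - Y2.mean(axis=0)
    beta = (xc @ Yc) / xx
    rss = np.einsum("ij,ij->j", Yc, Yc) - beta**2 * xx
    var = np.maximum(rss, 0.0) / (n - 2) / xx
    if Y.ndim == 1:
        return float(beta[0]), float(var[0])
    return beta, var


def pair_regression(pairs: PairData, locus) -> IbdTestResult:
    """Separate OLS fits of S and D on sharing at one locus; sigma^2 is the
    squared standard error of each slope.  Constant sharing across pairs is
    degenerate: the locus is skipped with a flag."""
    k = pairs.loci.index(locus)
    x = pairs.sharing[:, k]
    if np.ptp(x) == 0:
        return IbdTestResult(
            str(locus), np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            flags=("degenerate_sharing",),
        )
    D, S = pairs.d_s()
    beta_s, var_s = _ols_slope(x, S)
    beta_d, var_d = _ols_slope(x, D)
    return IbdTestResult(str(locus), beta_s, var_s, beta_d, var_d,
                         np.nan, np.nan, np.nan)


def combined_slope(
    beta_s: float,
    var_s: float,
    beta_d: float,
    var_d: float,
    sign_policy: str = "flip_D",
):
    """Reciprocal-variance cross-weighted combination of the two slopes.

    beta = var_D/(var_S+var_D) * beta_S + var_S/(var_S+var_D) * beta_D,
    SE = sqrt(w_S^2 var_S + w_D^2 var_D) treating the fits as independent,
    t = beta/SE.  Under ``sign_policy='flip_D'`` (default) beta_D is negated
    before combining, since linkage decreases D but increases S; 'literal'
    combines the slopes exactly as estimated.
    """
    if var_s < 0 or var_d < 0:
        raise ValueError("slope variances must be nonnegative")
    tot = var_s + var_d
    if tot == 0:
        raise ValueError("var_S + var_D is zero")
    if sign_policy == "flip_D":
        beta_d = -beta_d
    elif sign_policy != "literal":
        raise ValueError("sign_policy must be 'flip_D' or 'literal'")
    w_s = var_d / tot
    w_d = var_s / tot
    beta = w_s * beta_s + w_d * beta_d
    se = np.sqrt(w_s**2 * var_s + w_d**2 * var_d)
    t = beta / se if se > 0 else 0.0
    return float(beta), float(se), float(t)


def _all_t(pairs: PairData, traits: np.ndarray, sign_policy: str) -> np.ndarray:
    """Combined t per locus for a given trait vector (vectorized over loci);
    NaN at degenerate loci."""
    D, S = pairs.d_s(traits)
    out = np.full(len(pairs.loci), np.nan)
    for k in range(len(pairs.loci)):
        x = pairs.sharing[:, k]
        if np.ptp(x) == 0:
            continue
        bs, vs = _ols_slope(x, S)
        bd, vd = _ols_slope(x, D)
        out[k] = combined_slope(bs, vs, bd, vd, sign_policy)[2]
    return out


def permutation_threshold(
    pairs: PairData,
    n_perm: int = 1000,
    alpha: float = 0.05,
    sign_policy: str = "flip_D",
    rng=None,
):
    """Genome-wide |t| threshold by subject-level trait permutation.

    Permuting subject labels (not pair rows) preserves the dependence
    between pairs sharing a subject; per permutation D and S are rebuilt and
    the maximum |t| over loci recorded.  Returns the empirical (1-alpha)
    quantile of max |t| and the permutation draws.
    """
    if n_perm < 200:
        raise ValueError("need at least 200 permutations")
    if sign_policy not in ("flip_D", "literal"):
        raise ValueError("sign_policy must be 'flip_D' or 'literal'")
    rng = np.random.default_rng(rng)
    n = len(pairs.subjects)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    Tp = pairs.traits[perm]  # n_perm x n
    D = (Tp[:, pairs.ii] - Tp[:, pairs.jj]) ** 2  # n_perm x n_pairs
    S = (Tp[:, pairs.ii] + Tp[:, pairs.jj]) ** 2
    m = D.shape[1]
    max_abs_t = np.zeros(n_perm)
    for k in range(len(pairs.loci)):
        x = pairs.sharing[:, k]
        if np.ptp(x) == 0:
            continue
        xc = x - x.mean()
        xx = float(xc @ xc)

        def slope_var(Y):
            Yc = Y - Y.mean(axis=1, keepdims=True)
            beta = Yc @ xc / xx
            rss = np.einsum("ij,ij->i", Yc, Yc) - beta**2 * xx
            return beta, np.maximum(rss, 0.0) / (m - 2) / xx

        bs, vs = slope_var(S)
        bd, vd = slope_var(D)
        if sign_policy == "flip_D":
            bd = -bd
        tot = vs + vd
        beta = (vd * bs + vs * bd) / tot
        se = np.sqrt((vd / tot) ** 2 * vs + (vs / tot) ** 2 * vd)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        np.maximum(max_abs_t, np.abs(t), out=max_abs_t)
    threshold = float(np.quantile(max_abs_t, 1.0 - alpha))
    return threshold, max_abs_t


def ibd_test(
    pairs: PairData,
    n_perm: int = 1000,
    alpha: float = 0.05,
    sign_policy: str = "flip_D",
    rng=None,
) -> list[IbdTestResult]:
    """Per-locus combined-slope tests with a shared permutation threshold.

    The empirical p per locus is the add-one fraction of permutation
    maximum-|t| draws at or above the locus |t| (genome-wide adjusted).
    """
    obs = _all_t(pairs, pairs.traits, sign_policy)
    threshold, draws = permutation_threshold(pairs, n_perm, alpha, sign_policy, rng)
    D, S = pairs.d_s()
    out = []
    for k, locus in enumerate(pairs.loci):
        x = pairs.sharing[:, k]
        if np.ptp(x) == 0:
            out.append(
                IbdTestResult(str(locus), np.nan, np.nan, np.nan, np.nan,
                              np.nan, np.nan, np.nan, flags=("degenerate_sharing",))
            )
            continue
        bs, vs = _ols_slope(x, S)
        bd, vd = _ols_slope(x, D)
        beta, se, t = combined_slope(bs, vs, bd, vd, sign_policy)
        p = (1.0 + np.sum(draws >= abs(t) - 1e-12)) / (1.0 + n_perm)
        out.append(
            IbdTestResult(str(locus), bs, vs, bd, vd, beta, se, t,
                          threshold=threshold, p=float(p))
        )
    return out


def unrelated_subjects(kinship, cutoff: float = 0.044) -> list:
    """Greedy selection of subjects with pairwise kinship below the cutoff
    (default 0.044, below third-degree relatives)."""
    keep = []
    vals = kinship.values
    for i, s in enumerate(kinship.subjects):
        if all(vals[i, kinship.subjects.index(t)] < cutoff for t in keep):
            keep.append(s)
    return keep
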