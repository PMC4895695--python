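"""Genotype, trait, and kinship containers plus the shared null model.

Every association test in this package is a score-type test computed from a
fitted null model: trait ~ covariates with residual covariance
``sigma_g^2 * 2K + sigma_e^2 * I`` for family samples (K the kinship matrix)
or ``sigma_e^2 * I`` for unrelated designs.  This module provides the I/O
(VCF / dosage TSV / kinship TSV / pedigree), minor-allele-frequency
computation, sliding-window region construction, and the restricted
maximum-likelihood fit of the null variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger("priorvar")

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


class DosageMatrix:
    """Subjects x variants minor-allele dosage matrix.

    Parameters
    ----------
    subjects : sequence of str
        Ordered subject identifiers (unique).
    variants : pandas.DataFrame
        One row per variant with columns ``chrom, pos, id, ref, alt``;
        ``pos`` is 1-based.  Rows are sorted by (chrom, pos) on
        construction and the dosage columns are reordered with them.
    dosages : ndarray, shape (n_subjects, n_variants)
        Real dosages in [0, 2].  Missing values (NaN) are imputed to twice
        the MAF computed on the non-missing entries; the imputation count
        is logged.
    """

    def __init__(self, subjects, variants: pd.DataFrame, dosages: np.ndarray):
        subjects = list(subjects)
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicated subject identifiers")
        variants = variants.reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(subjects), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} does not match "
                f"{len(subjects)} subjects x {len(variants)} variants"
            )
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(variants))):
            variants = variants.iloc[order].reset_index(drop=True)
            dosages = dosages[:, order]
        n_missing = int(np.isnan(dosages).sum())
        if n_missing:
            col_mean = np.nanmean(dosages, axis=0)  # = 2*MAF on non-missing
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(dosages))
            dosages[idx] = col_mean[idx[1]]
            logger.info("imputed %d missing dosages to 2*MAF", n_missing)
        if dosages.size and (dosages.min() < -1e-9 or dosages.max() > 2 + 1e-9):
            raise ValueError("dosages outside [0, 2]")
        self.subjects = subjects
        self.variants = variants
        self.dosages = np.clip(dosages, 0.0, 2.0)
        self.n_imputed = n_missing

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_variants(self, mask) -> "DosageMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.where(mask)[0]
        else:
            idx = mask
        return DosageMatrix(
            self.subjects, self.variants.iloc[idx], self.dosages[:, idx]
        )

    def subset_subjects(self, subjects) -> "DosageMatrix":
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subjects]
        return DosageMatrix(list(subjects), self.variants, self.dosages[idx, :])

    def in_region(self, region: "Region") -> np.ndarray:
        """Boolean mask of variants inside a 0-based half-open region."""
        pos0 = self.variants["pos"].to_numpy() - 1
        return (
            (self.variants["chrom"].to_numpy() == region.chrom)
            & (pos0 >= region.start)
            & (pos0 < region.end)
        )


@dataclass(frozen=True)
class Region:
    """Genomic interval, BED convention: 0-based half-open [start, end)."""

    chrom: str
    start: int
    end: int
    label: str = ""
    variant_ids: tuple = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")


class KinshipMatrix:
    """Symmetric matrix of kinship coefficients phi_ij.

    Diagonal entries are >= 0.5 (self-kinship of a non-inbred individual is
    exactly 0.5) and the matrix must be positive semidefinite within 1e-8.
    """

    PSD_TOL = 1e-8

    def __init__(self, subjects, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        subjects = list(subjects)
        if values.shape != (len(subjects), len(subjects)):
            raise ValueError("kinship shape does not match subject count")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("kinship matrix is not symmetric")
        if values.size and values.diagonal().min() < 0.5 - 1e-12:
            raise ValueError("kinship diagonal below 0.5")
        w = np.linalg.eigvalsh(values)
        if values.size and w.min() < -self.PSD_TOL * max(1.0, w.max()):
            raise ValueError("kinship matrix is not positive semidefinite")
        self.subjects = subjects
        self.values = values

    def align(self, subjects) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subjects]
        return KinshipMatrix(list(subjects), self.values[np.ix_(idx, idx)])


@dataclass
class NullModel:
    """Fitted genetic null model: trait ~ covariates, no variant effects.

    Stores everything score tests need: residuals on the original scale, the
    fitted residual covariance ``sigma_g2 * 2K + sigma_e2 * I`` through its
    inverse square root (the whitener), the fixed-effect fit, and the
    projection that removes the covariate column space in whitened
    coordinates.
    """

    subjects: list
    trait: np.ndarray
    design: np.ndarray  # n x p fixed-effect design (includes intercept)
    beta: np.ndarray
    residuals: np.ndarray  # y - X beta, original scale
    sigma_g2: float
    sigma_e2: float
    h2: float
    covariance: np.ndarray  # fitted Sigma
    _L: np.ndarray = field(repr=False, default=None)  # Sigma^(1/2), symmetric
    _Linv: np.ndarray = field(repr=False, default=None)
    _Q: np.ndarray = field(repr=False, default=None)  # orthonormal basis of whitened design
    binary: bool = False
    status: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.subjects)

    def whiten(self, m: np.ndarray) -> np.ndarray:
        """Multiply by Sigma^(-1/2); whitened null residuals are ~ N(0, P)."""
        return self._Linv @ m

    def project(self, m: np.ndarray) -> np.ndarray:
        """Apply P = I - Q Q', removing the whitened covariate space."""
        return m - self._Q @ (self._Q.T @ m)

    @property
    def resid_white(self) -> np.ndarray:
        """P Sigma^(-1/2) y: whitened, projected residuals (unit variance)."""
        return self.project(self.whiten(self.trait))

    @property
    def rank(self) -> int:
        return self._Q.shape[1]


class TraitTable:
    """One row per subject: trait value plus covariates.

    A thin wrapper over a DataFrame indexed by subject id; the explicit
    ``join`` with a :class:`DosageMatrix` drops (and logs) subjects present
    in only one of the two.
    """

    def __init__(self, df: pd.DataFrame, trait: str, covariates=(), binary=False):
        if df.index.has_duplicates:
            raise ValueError("duplicate subject rows in trait table")
        cols = [trait, *covariates]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"trait table lacks columns {missing}")
        if df[cols].isna().any().any():
            raise ValueError("missing trait/covariate values; complete cases required")
        self.df = df
        self.trait_col = trait
        self.covariate_cols = list(covariates)
        self.binary = binary

    @property
    def subjects(self):
        return list(self.df.index)

    @property
    def trait(self) -> np.ndarray:
        return self.df[self.trait_col].to_numpy(dtype=float)

    def design(self) -> np.ndarray:
        X = [np.ones(len(self.df))]
        for c in self.covariate_cols:
            X.append(self.df[c].to_numpy(dtype=float))
        return np.column_stack(X)

    def join(self, d: DosageMatrix):
        """Align with a dosage matrix; returns (TraitTable, DosageMatrix)."""
        common = [s for s in d.subjects if s in self.df.index]
        dropped = (len(d.subjects) - len(common), len(self.df) - len(common))
        if any(dropped):
            logger.info(
                "join dropped %d genotyped / %d phenotyped subjects", *dropped
            )
        tt = TraitTable(
            self.df.loc[common], self.trait_col, self.covariate_cols, self.binary
        )
        return tt, d.subset_subjects(common)


# ---------------------------------------------------------------------------
# I/O


def read_dosages(path, region: Region | None = None) -> DosageMatrix:
    """Read a dosage matrix from a VCF (v4.x) or a dosage TSV.

    VCF: the ``DS`` FORMAT field is used when present, otherwise the
    ALT-allele count from ``GT``; missing entries are imputed to twice the
    allele frequency of the non-missing entries.  TSV: subject rows, variant
    columns, header ``subject`` then variant ids (``chrom:pos:name`` ids are
    parsed for coordinates).
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path, region)
    return _read_dosage_tsv(path, region)


def _read_vcf(path, region):
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = list(vcf.samples)
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicated sample names in VCF header")
    rows, cols = [], []
    for v in vcf:
        if region is not None:
            pos0 = v.POS - 1
            if v.CHROM != region.chrom or not (region.start <= pos0 < region.end):
                continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.gt_types)  # 0=hom_ref 1=het 2=unknown 3=hom_alt
            col = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
            col[gt == 2] = np.nan
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append((v.CHROM, v.POS, vid, v.REF, v.ALT[0] if v.ALT else "."))
        cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dos = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return DosageMatrix(subjects, variants, dos)


def _parse_variant_id(vid, index):
    parts = str(vid).split(":")
    if len(parts) >= 2 and parts[1].isdigit():
        return parts[0], int(parts[1])
    return "0", index + 1


def _read_dosage_tsv(path, region):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicated subject rows in dosage TSV")
    rows = [
        (*_parse_variant_id(vid, j), str(vid), "N", "N")
        for j, vid in enumerate(df.columns)
    ]
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    d = DosageMatrix(list(df.index.astype(str)), variants, df.to_numpy(dtype=float))
    if region is not None:
        return d.subset_variants(d.in_region(region))
    return d


def write_dosages(d: DosageMatrix, path) -> None:
    """Write the transposable dosage TSV (subject rows, variant-id columns)."""
    ids = [
        f"{r.chrom}:{r.pos}:{r.id}" if ":" not in str(r.id) else str(r.id)
        for r in d.variants.itertuples()
    ]
    out = pd.DataFrame(d.dosages, index=pd.Index(d.subjects, name="subject"), columns=ids)
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_kinship(k: KinshipMatrix, path) -> None:
    pd.DataFrame(k.values, index=k.subjects, columns=k.subjects).to_csv(
        path, sep="\t", float_format="%.8g"
    )


def read_traits(path, trait: str, covariates=(), binary=False) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df, trait, covariates, binary)


def read_regions(path) -> list[Region]:
    """Read a BED file (chrom, start, end[, name]) into Region records."""
    regions = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            label = f[3] if len(f) > 3 else f"region{i}"
            regions.append(Region(f[0], int(f[1]), int(f[2]), label))
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels in BED")
    return regions


# ---------------------------------------------------------------------------
# Allele frequencies and windows


def compute_maf(d: DosageMatrix, details: bool = False):
    """Per-variant minor allele frequency, folded to [0, 0.5].

    The raw frequency is mean dosage / 2; values above 0.5 are folded to
    1 - raw (the stored dosages then count the major allele) and the fold is
    flagged.  Monomorphic variants get MAF 0 and a flag.
    """
    if d.n_subjects == 0:
        raise ValueError("no subjects")
    raw = d.dosages.mean(axis=0) / 2.0
    folded = raw > 0.5
    maf = np.where(folded, 1.0 - raw, raw)
    if not details:
        return maf
    return pd.DataFrame(
        {
            "id": d.variants["id"].to_numpy(),
            "maf": maf,
            "folded": folded,
            "monomorphic": maf == 0.0,
        }
    )


def minor_dosages(d: DosageMatrix) -> np.ndarray:
    """Dosages of the minor allele (folded columns flipped to 2 - x)."""
    raw = d.dosages.mean(axis=0) / 2.0
    return np.where(raw > 0.5, 2.0 - d.dosages, d.dosages)


def sliding_windows(variants: pd.DataFrame, size_bp: int, step_bp: int) -> list[Region]:
    """Tile half-open windows over each chromosome, anchored at the first
    variant position; windows containing no variants are dropped and each
    retained window records its member variant ids."""
    if size_bp <= 0 or step_bp <= 0:
        raise ValueError("window size and step must be positive")
    regions = []
    for chrom, grp in variants.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy() - 1
        ids = grp["id"].to_numpy()
        first, last = pos0.min(), pos0.max()
        start = first
        while start <= last:
            end = start + size_bp
            mask = (pos0 >= start) & (pos0 < end)
            if mask.any():
                regions.append(
                    Region(
                        str(chrom),
                        int(start),
                        int(end),
                        label=f"{chrom}:{start}-{end}",
                        variant_ids=tuple(ids[mask]),
                    )
                )
            start += step_bp
    return regions


# ---------------------------------------------------------------------------
# Pedigree kinship


def kinship_from_pedigree(ped: pd.DataFrame) -> KinshipMatrix:
    """Recursive kinship coefficients from a pedigree table.

    ``ped`` has columns ``id, father, mother`` (founders marked by "0", "",
    or NaN).  phi(i,i) = 0.5 * (1 + phi(f_i, m_i)) and
    phi(i,j) = 0.5 * (phi(f_i, j) + phi(m_i, j)) with i added after its
    parents.  A pedigree cycle raises an error.
    """
    ids = [str(x) for x in ped["id"]]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated individual ids in pedigree")

    def norm(x):
        s = "" if pd.isna(x) else str(x)
        return None if s in ("", "0", "nan") else s

    parents = {
        str(r["id"]): (norm(r["father"]), norm(r["mother"]))
        for _, r in ped.iterrows()
    }
    # topological order: parents before children (Kahn)
    order, placed = [], set()
    pending = list(ids)
    while pending:
        progressed = False
        rest = []
        for i in pending:
            f, m = parents[i]
            if (f is None or f in placed) and (m is None or m in placed):
                order.append(i)
                placed.add(i)
                progressed = True
            else:
                rest.append(i)
        if not progressed:
            raise ValueError(f"pedigree cycle involving {rest}")
        pending = rest

    idx = {s: k for k, s in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for i in order:
        ii = idx[i]
        f, m = parents[i]
        fi = idx.get(f) if f else None
        mi = idx.get(m) if m else None
        phi[ii, ii] = 0.5 * (
            1.0 + (phi[fi, mi] if fi is not None and mi is not None else 0.0)
        )
        for j in order[: order.index(i)]:
            jj = idx[j]
            v = 0.0
            if fi is not None:
                v += 0.5 * phi[fi, jj]
            if mi is not None:
                v += 0.5 * phi[mi, jj]
            phi[ii, jj] = phi[jj, ii] = v
    # restore input order
    perm = [idx[i] for i in ids]
    return KinshipMatrix(ids, phi[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# Null model


def fit_null_model(traits: TraitTable, kinship: KinshipMatrix | None = None) -> NullModel:
    """Fit the genetic null model by REML (family) or OLS (unrelated).

    For a quantitative trait with kinship K the residual covariance is
    ``Sigma = sigma_g^2 * 2K + sigma_e^2 * I``, estimated by restricted
    maximum likelihood through a one-dimensional profile over the
    heritability ratio h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) (grid search
    then bounded refinement, tolerance 1e-6).  Without kinship the fit is
    ordinary least squares.  Binary traits get a null proportion model used
    by the permutation likelihood-ratio test.
    """
    y = traits.trait
    n = len(y)
    X = traits.design()
    if np.ptp(y) == 0:
        raise ValueError("constant trait")

    if traits.binary:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        nm = _assemble(traits, X, beta, resid, 0.0, 1.0, np.eye(n))
        nm.binary = True
        nm.status = y.astype(int)
        return nm

    if kinship is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        p = np.linalg.matrix_rank(X)
        sigma_e2 = float(resid @ resid / (n - p))
        return _assemble(traits, X, beta, resid, 0.0, sigma_e2, sigma_e2 * np.eye(n))

    kin = kinship.align(traits.subjects)
    G = 2.0 * kin.values
    w, U = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    yr, Xr = U.T @ y, U.T @ X
    p = np.linalg.matrix_rank(X)

    def neg_reml(h2):
        v = h2 * w + (1.0 - h2)  # Sigma/sigma2 eigenvalues
        if v.min() <= 0:
            return np.inf
        Xv = Xr / v[:, None]
        XtVX = Xr.T @ Xv
        beta = np.linalg.solve(XtVX, Xv.T @ yr)
        r = yr - Xr @ beta
        rss = float(r @ (r / v))
        sigma2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return 0.5 * ((n - p) * np.log(sigma2) + np.log(v).sum() + logdet)

    grid = np.linspace(0.0, 0.999, 41)
    vals = [neg_reml(h) for h in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            neg_reml, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        h2 = float(res.x) if res.fun <= vals[k] else float(grid[k])
    else:
        h2 = float(grid[k])

    v = h2 * w + (1.0 - h2)
    Xv = Xr / v[:, None]
    beta = np.linalg.solve(Xr.T @ Xv, Xv.T @ yr)
    r = yr - Xr @ beta
    sigma2 = float(r @ (r / v) / (n - p))
    sigma_g2 = h2 * sigma2
    sigma_e2 = (1.0 - h2) * sigma2
    Sigma = (U * (sigma2 * v)) @ U.T
    resid = y - X @ beta
    nm = _assemble(traits, X, beta, resid, sigma_g2, sigma_e2, Sigma,
                   eig=(sigma2 * v, U))
    nm.h2 = h2
    return nm


def _assemble(traits, X, beta, resid, sigma_g2, sigma_e2, Sigma, eig=None):
    if eig is None:
        w, U = np.linalg.eigh(Sigma)
    else:
        w, U = eig
    w = np.clip(w, 1e-12, None)
    L = (U * np.sqrt(w)) @ U.T
    Linv = (U * (1.0 / np.sqrt(w))) @ U.T
    Xw = Linv @ X
    Q, R = np.linalg.qr(Xw)
    # drop columns that are numerically dependent on earlier ones
    dR = np.abs(np.diag(R))
    keep = dR > 1e-10 * max(dR.max(), 1.0)
    total = sigma_g2 + sigma_e2
    return NullModel(
        subjects=traits.subjects,
        trait=traits.trait.copy(),
        design=X,
        beta=beta,
        residuals=resid,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=sigma_g2 / total if total > 0 else 0.0,
        covariance=Sigma,
        _L=L,
        _Linv=Linv,
        _Q=Q[:, keep],
    )


def decorrelate_trait(nm: NullModel) -> np.ndarray:
    """Conditionally independent surrogate: Sigma^(-1/2) residuals.

    Under the null the output has (approximately) identity covariance, so
    downstream tests can treat subjects as exchangeable.  Deterministic:
    the symmetric matrix square root is used, so the same fitted model
    always yields the same surrogate.
    """
    return nm.whiten(nm.residuals)
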