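"""Synthetic genotype / trait / expression / IBD generators.

Every statistical claim in this package is exercised against data from
these generators, so each one is a pure, seeded function of its spec:

* genotypes with controllable MAF spectra and block-exchangeable LD,
  produced by dichotomizing a latent Gaussian copula twice (two alleles)
  at the MAF-matching threshold;
* family genotypes by Mendelian gene-dropping from simulated founders;
* quantitative traits T = sum_i beta_i x_i + g + e with a polygenic
  component g ~ N(0, sigma_g^2 * 2K) and effect sizes that can be driven by
  harmonized functional scores (beta_i = beta_max * score_i, emulating
  generating models where effects grow with predicted functionality);
* expression probes E = b_E * s* + c * T + noise, linking a gene's rare
  burden, its expression, and the trait;
* pairwise IBD sharing tables where, at a linked locus, sharing reflects a
  shared causal allele that also shifts the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import DosageMatrix, KinshipMatrix, TraitTable, VARIANT_COLUMNS
from .weighted_fdr import ExpressionMatrix

__all__ = [
    "GenotypeSimSpec",
    "TraitSimSpec",
    "simulate_genotypes",
    "simulate_family_genotypes",
    "simulate_trait",
    "simulate_expression",
    "simulate_ibd_pairs",
]


@dataclass
class GenotypeSimSpec:
    n_subjects: int
    mafs: np.ndarray  # one target MAF per variant, in (0, 0.5]
    block_sizes: tuple = ()  # empty: all variants independent
    block_r: float = 0.0  # latent within-block correlation, [0, 1)
    chrom: str = "1"
    spacing_bp: int = 1000
    seed: int | None = None

    def __post_init__(self):
        self.mafs = np.atleast_1d(np.asarray(self.mafs, dtype=float))
        if self.mafs.size and (self.mafs.min() <= 0 or self.mafs.max() > 0.5):
            raise ValueError("target MAFs must lie in (0, 0.5]")
        if not 0.0 <= self.block_r < 1.0:
            raise ValueError("latent block correlation must be in [0, 1)")
        if self.block_sizes and sum(self.block_sizes) != self.mafs.size:
            raise ValueError("block sizes must partition the variants")


@dataclass
class TraitSimSpec:
    """Trait generator: causal effects, polygenic and environmental variance."""

    betas: dict = field(default_factory=dict)  # variant id -> effect size
    sigma_g2: float = 0.0
    sigma_e2: float = 1.0
    functional_scores: dict | None = None  # id -> harmonized score
    beta_max: float = 0.0  # with scores: beta_i = beta_max * score_i
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be nonnegative")


def _haplotypes(spec: GenotypeSimSpec, rng, n: int) -> np.ndarray:
    """Two latent-Gaussian allele draws per subject, n x m x 2 in {0, 1}."""
    m = spec.mafs.size
    thresh = norm.ppf(spec.mafs)
    blocks = spec.block_sizes or ((1,) * m)
    alleles = np.empty((n, m, 2), dtype=np.int8)
    for copy in range(2):
        z = np.empty((n, m))
        j = 0
        for size in blocks:
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, size))
            r = spec.block_r if size > 1 else 0.0
            z[:, j : j + size] = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
            j += size
        alleles[:, :, copy] = z < thresh
    return alleles


def simulate_genotypes(spec: GenotypeSimSpec, rng=None) -> DosageMatrix:
    """Gaussian-copula genotypes: dosage = sum of two latent-threshold
    alleles, so marginal dosages are Binomial(2, MAF) and within-block
    latent correlation induces positive LD between dosages."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    alleles = _haplotypes(spec, rng, spec.n_subjects)
    dos = alleles.sum(axis=2).astype(float)
    return _pack(dos, spec)


def _pack(dos: np.ndarray, spec: GenotypeSimSpec, subjects=None) -> DosageMatrix:
    m = dos.shape[1]
    variants = pd.DataFrame(
        {
            "chrom": spec.chrom,
            "pos": np.arange(1, m + 1) * spec.spacing_bp,
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "C",
        },
        columns=VARIANT_COLUMNS,
    )
    if subjects is None:
        subjects = [f"s{i}" for i in range(dos.shape[0])]
    return DosageMatrix(subjects, variants, dos)


def simulate_family_genotypes(
    ped: pd.DataFrame, founder_spec: GenotypeSimSpec, rng=None
) -> DosageMatrix:
    """Founders from the copula model, non-founders by Mendelian
    gene-dropping (one random allele from each parent, per variant)."""
    rng = np.random.default_rng(founder_spec.seed if rng is None else rng)
    ids = [str(x) for x in ped["id"]]

    def norm_p(x):
        s = "" if pd.isna(x) else str(x)
        return None if s in ("", "0", "nan") else s

    parents = {
        str(r["id"]): (norm_p(r["father"]), norm_p(r["mother"]))
        for _, r in ped.iterrows()
    }
    founders = [i for i in ids if parents[i] == (None, None)]
    m = founder_spec.mafs.size
    hap = {}
    fh = _haplotypes(founder_spec, rng, len(founders))
    for k, f in enumerate(founders):
        hap[f] = fh[k]
    pending = [i for i in ids if i not in hap]
    while pending:
        rest = []
        for i in pending:
            f, mo = parents[i]
            if f in hap and mo in hap:
                child = np.empty((m, 2), dtype=np.int8)
                for c, par in enumerate((f, mo)):
                    pick = rng.integers(0, 2, size=m)
                    child[:, c] = hap[par][np.arange(m), pick]
                hap[i] = child
            else:
                rest.append(i)
        if len(rest) == len(pending):
            raise ValueError(f"pedigree cycle or missing parents: {rest}")
        pending = rest
    dos = np.stack([hap[i].sum(axis=1) for i in ids]).astype(float)
    return _pack(dos, founder_spec, subjects=ids)


def simulate_trait(
    d: DosageMatrix,
    spec: TraitSimSpec,
    kinship: KinshipMatrix | None = None,
    rng=None,
    trait_name: str = "trait",
) -> TraitTable:
    """T = sum beta_i x_i + g + e; the variant effects come from explicit
    betas or from the functional-score map beta_i = beta_max * score_i; a
    zero-effect spec yields pure null replicates."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = d.n_subjects
    betas = dict(spec.betas)
    if spec.functional_scores is not None:
        for vid, s in spec.functional_scores.items():
            betas.setdefault(vid, spec.beta_max * s)
    ids = list(d.variants["id"])
    genetic = np.zeros(n)
    for vid, b in betas.items():
        if b and vid in ids:
            genetic += b * d.dosages[:, ids.index(vid)]
    g = np.zeros(n)
    if spec.sigma_g2 > 0:
        if kinship is None:
            raise ValueError("polygenic variance requires a kinship matrix")
        cov = 2.0 * spec.sigma_g2 * kinship.align(d.subjects).values
        w, U = np.linalg.eigh(cov)
        g = U @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n))
    e = np.sqrt(spec.sigma_e2) * rng.standard_normal(n)
    df = pd.DataFrame({trait_name: genetic + g + e}, index=pd.Index(d.subjects, name="subject"))
    return TraitTable(df, trait_name)


def simulate_expression(
    s_star: np.ndarray,
    trait: np.ndarray,
    b_e: float,
    c: float,
    noise_sd: float,
    n_probes: int = 1,
    gene: str = "g",
    subjects=None,
    rng=None,
) -> ExpressionMatrix:
    """Probes E_j = b_E * s* + c * T + noise, independent noise per probe."""
    rng = np.random.default_rng(rng)
    s = np.asarray(s_star, dtype=float)
    T = np.asarray(trait, dtype=float)
    n = len(s)
    E = (
        b_e * s[:, None]
        + c * T[:, None]
        + noise_sd * rng.standard_normal((n, n_probes))
    )
    probes = [f"{gene}_p{j}" for j in range(n_probes)]
    if subjects is None:
        subjects = [f"s{i}" for i in range(n)]
    return ExpressionMatrix(subjects, E, probes, {p: gene for p in probes})


def simulate_ibd_pairs(
    n_subjects: int,
    n_loci: int,
    linked_locus: int | None = None,
    effect: float = 0.0,
    carrier_freq: float = 0.3,
    seed=None,
):
    """Trait plus complete pair x locus IBD sharing table.

    Null loci get independent Bernoulli sharing indicators.  At the linked
    locus each subject carries a latent causal allele (frequency
    ``carrier_freq``) that raises the trait by ``effect``; a pair shares at
    that locus iff both subjects have the same carrier state, so sharing
    pairs have systematically more similar traits.  With ``effect = 0`` the
    linked locus is indistinguishable from a null locus.
    """
    rng = np.random.default_rng(seed)
    subjects = [f"s{i}" for i in range(n_subjects)]
    carrier = rng.random(n_subjects) < carrier_freq
    traits = effect * carrier + rng.standard_normal(n_subjects)
    ii, jj = np.triu_indices(n_subjects, 1)
    match_freq = float(np.mean(carrier) ** 2 + (1 - np.mean(carrier)) ** 2)
    rows = []
    for k in range(n_loci):
        if k == linked_locus:
            share = (carrier[ii] == carrier[jj]).astype(float)
        else:
            share = (rng.random(ii.size) < match_freq).astype(float)
        rows.append(
            pd.DataFrame(
                {
                    "subject_i": np.array(subjects)[ii],
                    "subject_j": np.array(subjects)[jj],
                    "locus": f"L{k}",
                    "sharing": share,
                }
            )
        )
    sharing = pd.concat(rows, ignore_index=True)
    tser = pd.Series(traits, index=subjects, name="trait")
    return tser, sharing


def realized_ld_r2(d: DosageMatrix) -> np.ndarray:
    """Pairwise dosage r^2 (realized, not target, LD)."""
    X = d.dosages
    sd = X.std(axis=0)
    ok = sd > 0
    C = np.corrcoef(X[:, ok], rowvar=False)
    return C**2
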