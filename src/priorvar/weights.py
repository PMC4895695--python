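"""Per-variant prior weights from MAF spectra and functional annotations.

Three families of weights are provided:

* MAF-based: Madsen-Browning ``1/(MAF(1-MAF))``, inverse-MAF ``1/MAF``, and
  the beta(1,25) density ``25 (1-MAF)^24`` evaluated at the MAF.
* Regulatory-evidence based: RegulomeDB categories are reversed to an
  ordinal score s (category 1, strongest evidence, maps to s = 6) and
  weighted as f(s) = s^2 for burden tests, or sqrt(f(s)) = s inside a
  SKAT kernel.
* Binding-site based: signed weights with magnitude 10 (functional, in a
  binding site), 5 (functional, outside), or 1 (nonfunctional), the sign
  taken from a putative effect-direction column.

Raw PolyPhen2 / SIFT / RegulomeDB scores are first harmonized so that a
higher value always means more putatively functional (PolyPhen2 passes
through, SIFT is reversed as 1 - sift, RegulomeDB category c becomes 7 - c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("priorvar")

MAF_SCHEMES = ("madsen_browning", "inverse_maf", "beta_1_25")
BINDING_MAGNITUDE = {"in_binding": 10.0, "functional_not_binding": 5.0, "nonfunctional": 1.0}


@dataclass
class WeightVector:
    """Nonnegative per-variant weights; signed schemes carry direction separately."""

    ids: np.ndarray
    omega: np.ndarray
    direction: np.ndarray | None = None  # +1/-1, only for signed schemes

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.omega = np.asarray(self.omega, dtype=float)
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("non-finite weight")
        if self.omega.min(initial=0.0) < 0:
            raise ValueError("negative weight magnitude")

    @property
    def signed(self) -> np.ndarray:
        if self.direction is None:
            return self.omega
        return self.omega * self.direction

    def __len__(self):
        return len(self.omega)


@dataclass
class FunctionalAnnotation:
    """One variant's functional annotation; absent sources are None."""

    variant_id: str
    polyphen2: float | None = None
    sift: float | None = None
    regulomedb_category: int | None = None
    binding_site: str | None = None
    direction: int | None = None

    def __post_init__(self):
        for name in ("polyphen2", "sift"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")
        if self.regulomedb_category is not None:
            c = int(self.regulomedb_category)
            if not 1 <= c <= 6:
                raise ValueError(f"RegulomeDB category {c} outside 1..6")
            self.regulomedb_category = c
        if self.binding_site is not None and self.binding_site not in BINDING_MAGNITUDE:
            raise ValueError(f"unknown binding flag {self.binding_site!r}")
        if all(
            getattr(self, f) is None
            for f in ("polyphen2", "sift", "regulomedb_category", "binding_site")
        ):
            raise ValueError(f"variant {self.variant_id}: no annotation source present")


@dataclass(frozen=True)
class HarmonizedScore:
    """A raw functional score mapped so that higher = more functional."""

    variant_id: str
    value: float
    source: str


def harmonize(a: FunctionalAnnotation) -> list[HarmonizedScore]:
    """Map each present source to the shared 'damaging is high' direction.

    PolyPhen2 already scores damaging variants near 1 and passes through;
    SIFT scores them near 0 and is reversed to ``1 - sift``; a RegulomeDB
    category c in 1..6 (1 = strongest regulatory evidence) becomes the
    ordinal ``s = 7 - c``, so category 1 maps to s = 6.
    """
    out = []
    if a.polyphen2 is not None:
        out.append(HarmonizedScore(a.variant_id, float(a.polyphen2), "polyphen2"))
    if a.sift is not None:
        out.append(HarmonizedScore(a.variant_id, 1.0 - float(a.sift), "sift"))
    if a.regulomedb_category is not None:
        out.append(
            HarmonizedScore(a.variant_id, float(7 - a.regulomedb_category), "regulomedb")
        )
    return out


def maf_weights(maf, scheme: str, ids=None) -> WeightVector:
    """MAF-based down-weighting of common variants.

    madsen_browning: 1/(MAF(1-MAF)); inverse_maf: 1/MAF;
    beta_1_25: the beta(1,25) density 25(1-MAF)^24.  Monomorphic variants
    (MAF 0) get weight 0 under the first two schemes (a monomorphic variant
    carries no signal) with a warning.
    """
    maf = np.asarray(maf, dtype=float)
    if maf.size and (maf.min() < 0 or maf.max() > 0.5 + 1e-12):
        raise ValueError("MAF outside [0, 0.5]; fold to the minor allele first")
    if scheme not in MAF_SCHEMES:
        raise ValueError(f"unknown MAF scheme {scheme!r}; choose from {MAF_SCHEMES}")
    mono = maf == 0.0
    if scheme == "beta_1_25":
        w = 25.0 * (1.0 - maf) ** 24
    else:
        with np.errstate(divide="ignore"):
            if scheme == "madsen_browning":
                w = 1.0 / (maf * (1.0 - maf))
            else:
                w = 1.0 / maf
        w = np.where(mono, 0.0, w)
        if mono.any():
            logger.warning(
                "%d monomorphic variants assigned weight 0 under %s", mono.sum(), scheme
            )
    if ids is None:
        ids = np.arange(len(maf))
    return WeightVector(ids, w)


def functional_weights(s, target: str, ids=None) -> WeightVector:
    """Regulatory-importance weights from the RegulomeDB ordinal s in 1..6.

    ``target='burden'`` returns f(s) = s^2 (the burden-test weight);
    ``target='kernel'`` returns sqrt(f(s)) = s, the form entering a SKAT
    kernel (SKAT squares kernel weights internally).
    """
    s = np.asarray(s, dtype=float)
    if not np.allclose(s, np.round(s)) or (s.size and (s.min() < 1 or s.max() > 6)):
        raise ValueError("functional ordinal s must be integers in 1..6")
    if target == "burden":
        w = s**2
    elif target == "kernel":
        w = s.copy()
    else:
        raise ValueError("target must be 'burden' or 'kernel'")
    if ids is None:
        ids = np.arange(len(s))
    return WeightVector(ids, w)


def binding_weights(annotations: list[FunctionalAnnotation]) -> WeightVector:
    """Signed binding-site weights: |w| = 10 / 5 / 1 for functional variants
    in binding sites / outside binding sites / nonfunctional variants, the
    sign from the putative effect direction (+1 when absent, logged).
    Variants with no binding flag are counted as nonfunctional."""
    ids, mag, sign = [], [], []
    n_noflag = n_nodir = 0
    for a in annotations:
        flag = a.binding_site
        if flag is None:
            flag = "nonfunctional"
            n_noflag += 1
        d = a.direction
        if d is None:
            d = 1
            n_nodir += 1
        if d not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {d}")
        ids.append(a.variant_id)
        mag.append(BINDING_MAGNITUDE[flag])
        sign.append(float(d))
    if n_noflag:
        logger.info("%d variants without binding flag treated as nonfunctional", n_noflag)
    if n_nodir:
        logger.info("%d variants without direction defaulted to +1", n_nodir)
    return WeightVector(np.array(ids), np.array(mag), np.array(sign))


def read_annotations(path) -> list[FunctionalAnnotation]:
    """Annotation TSV with columns variant_id, polyphen2, sift, regulomedb,
    binding, direction; empty cells mean the source is absent."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    out = []
    for _, r in df.iterrows():
        def get(col, cast=float):
            if col not in df.columns or pd.isna(r[col]):
                return None
            return cast(r[col])

        out.append(
            FunctionalAnnotation(
                variant_id=str(r["variant_id"]),
                polyphen2=get("polyphen2"),
                sift=get("sift"),
                regulomedb_category=get("regulomedb", int),
                binding_site=get("binding", str),
                direction=get("direction", int),
            )
        )
    return out


def combined_prior(annotations: list[FunctionalAnnotation]) -> WeightVector:
    """Optional multi-source prior: max over harmonized sources, rescaled to
    [1, 6] so it is exchangeable with the RegulomeDB ordinal.  Off by
    default everywhere; an explicit, documented choice for users who want a
    single prior from several annotation sources."""
    ids, vals = [], []
    for a in annotations:
        scores = harmonize(a)
        ids.append(a.variant_id)
        vals.append(max(s.value for s in scores) if scores else 0.0)
    v = np.asarray(vals)
    span = v.max() - v.min()
    scaled = 1.0 + 5.0 * (v - v.min()) / span if span > 0 else np.ones_like(v)
    return WeightVector(np.array(ids), scaled)
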