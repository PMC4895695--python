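import numpy as np
import pandas as pd
import pytest

import priorvar as pv
from priorvar.simulate import GenotypeSimSpec, TraitSimSpec, simulate_genotypes, simulate_trait


@pytest.fixture
def rng():
    return np.random.default_rng(20160203)


@pytest.fixture
def small_dosages():
    """400 subjects x 25 variants, mixed MAF spectrum, no LD."""
    mafs = np.concatenate([np.full(15, 0.02), np.full(10, 0.25)])
    return simulate_genotypes(GenotypeSimSpec(400, mafs, seed=101))


@pytest.fixture
def null_model(small_dosages):
    tt = simulate_trait(small_dosages, TraitSimSpec(seed=102))
    return pv.fit_null_model(tt)


@pytest.fixture
def unit_weights(small_dosages):
    return pv.WeightVector(
        small_dosages.variants["id"].to_numpy(), np.ones(small_dosages.n_variants)
    )


def write_vcf(path, records, samples, fmt="GT"):
    """Write a minimal VCF v4.2 text file.

    records: list of (chrom, pos, vid, ref, alt, per-sample strings)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, vid, ref, alt, values in records:
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t" + "\t".join(values)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
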