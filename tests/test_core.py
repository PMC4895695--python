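"""Genotype I/O, MAF, windows, pedigree kinship, and the null model."""

import numpy as np
import pandas as pd
import pytest

import priorvar as pv
from priorvar.core import minor_dosages, write_dosages
from priorvar.simulate import (
    GenotypeSimSpec,
    TraitSimSpec,
    simulate_genotypes,
    simulate_trait,
)

from conftest import write_vcf


class TestReadDosages:
    def test_gt_allele_counting(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "a.vcf",
            [("1", 1000, "v1", "A", "C", ["0/0", "0/1", "1/1"])],
            ["S1", "S2", "S3"],
        )
        d = pv.read_dosages(vcf)
        assert d.subjects == ["S1", "S2", "S3"]
        np.testing.assert_allclose(d.dosages[:, 0], [0.0, 1.0, 2.0])

    def test_missing_gt_imputed_to_twice_maf(self, tmp_path):
        # 9 observed dosages summing to 9 over 10 subjects -> MAF 0.5, impute 1.0
        calls = ["0/1"] * 9 + ["./."]
        vcf = write_vcf(
            tmp_path / "b.vcf", [("1", 500, "v1", "A", "C", calls)],
            [f"S{i}" for i in range(10)],
        )
        d = pv.read_dosages(vcf)
        assert d.dosages[9, 0] == pytest.approx(1.0)
        assert d.n_imputed == 1

    def test_ds_field_preferred(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "c.vcf",
            [("1", 100, "v1", "A", "C", ["0/0:0.12", "1/1:1.88"])],
            ["S1", "S2"],
            fmt="GT:DS",
        )
        d = pv.read_dosages(vcf)
        np.testing.assert_allclose(d.dosages[:, 0], [0.12, 1.88])

    def test_region_half_open(self, tmp_path):
        vcf = write_vcf(
            tmp_path / "d.vcf",
            [
                ("1", 1500, "in", "A", "C", ["0/1"]),
                ("1", 2001, "out", "A", "C", ["0/1"]),
            ],
            ["S1"],
        )
        d = pv.read_dosages(vcf, region=pv.Region("1", 1000, 2000))
        assert list(d.variants["id"]) == ["in"]

    def test_tsv_roundtrip(self, tmp_path, small_dosages):
        path = tmp_path / "dos.tsv"
        write_dosages(small_dosages, path)
        back = pv.read_dosages(path)
        np.testing.assert_allclose(back.dosages, small_dosages.dosages, atol=1e-6)
        assert list(back.variants["pos"]) == list(small_dosages.variants["pos"])

    def test_duplicate_subject_rejected(self, tmp_path):
        (tmp_path / "dup.tsv").write_text("subject\tv1\na\t1\na\t2\n")
        with pytest.raises(ValueError, match="duplicat"):
            pv.read_dosages(tmp_path / "dup.tsv")


class TestMaf:
    def test_simple_and_folding(self):
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1, 2], "id": ["a", "b"], "ref": "A", "alt": "C"}
        )
        d = pv.DosageMatrix(["s1", "s2", "s3"], variants,
                            np.array([[0.0, 2.0], [1.0, 2.0], [2.0, 2.0]]))
        det = pv.compute_maf(d, details=True)
        assert det.loc[0, "maf"] == pytest.approx(0.5)
        assert det.loc[1, "maf"] == pytest.approx(0.0)  # raw 1.0 folds to 0
        assert bool(det.loc[1, "folded"]) and bool(det.loc[1, "monomorphic"])
        # folded column counts the minor allele after flipping
        np.testing.assert_allclose(minor_dosages(d)[:, 1], [0.0, 0.0, 0.0])

    def test_sampling_accuracy(self):
        n = 1000
        d = simulate_genotypes(GenotypeSimSpec(n, np.array([0.1]), seed=42))
        maf = pv.compute_maf(d)[0]
        assert abs(maf - 0.1) < 3 * np.sqrt(0.1 * 0.9 / (2 * n))

    def test_subject_permutation_invariance(self, small_dosages, rng):
        perm = rng.permutation(small_dosages.n_subjects)
        shuffled = pv.DosageMatrix(
            [small_dosages.subjects[i] for i in perm],
            small_dosages.variants,
            small_dosages.dosages[perm],
        )
        np.testing.assert_allclose(pv.compute_maf(shuffled), pv.compute_maf(small_dosages))


class TestSlidingWindows:
    variants = pd.DataFrame(
        {"chrom": "1", "pos": [100, 4300], "id": ["a", "b"], "ref": "A", "alt": "C"}
    )

    def test_non_overlapping(self):
        regions = pv.sliding_windows(self.variants, 4000, 4000)
        assert len(regions) == 2
        assert [r.variant_ids for r in regions] == [("a",), ("b",)]

    def test_overlapping_step(self):
        regions = pv.sliding_windows(self.variants, 4000, 2000)
        hits = sum("b" in r.variant_ids for r in regions)
        assert hits == 2  # variant at 4300 falls in two overlapping windows

    def test_empty_input(self):
        assert pv.sliding_windows(self.variants.iloc[:0], 4000, 4000) == []


class TestKinship:
    def test_textbook_values(self):
        ped = pd.DataFrame(
            {
                "id": ["f", "m", "c1", "c2", "u"],
                "father": ["0", "0", "f", "f", "0"],
                "mother": ["0", "0", "m", "m", "0"],
            }
        )
        k = pv.kinship_from_pedigree(ped)
        i = {s: j for j, s in enumerate(k.subjects)}
        assert k.values[i["f"], i["c1"]] == pytest.approx(0.25)  # parent-offspring
        assert k.values[i["c1"], i["c2"]] == pytest.approx(0.25)  # full sibs
        assert k.values[i["f"], i["m"]] == 0.0
        assert k.values[i["u"], i["u"]] == 0.5

    def test_cycle_detected(self):
        ped = pd.DataFrame(
            {"id": ["a", "b"], "father": ["b", "a"], "mother": ["0", "0"]}
        )
        with pytest.raises(ValueError, match="cycle"):
            pv.kinship_from_pedigree(ped)

    def test_psd_enforced(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            pv.KinshipMatrix(["a", "b"], np.array([[0.5, 0.9], [0.9, 0.5]]))


def _sib_pedigree(n_fam):
    rows = []
    for f in range(n_fam):
        rows += [
            (f"f{f}", "0", "0"), (f"m{f}", "0", "0"),
            (f"a{f}", f"f{f}", f"m{f}"), (f"b{f}", f"f{f}", f"m{f}"),
        ]
    return pd.DataFrame(rows, columns=["id", "father", "mother"])


class TestNullModel:
    def test_ols_residuals_are_centered(self, rng):
        y = rng.standard_normal(50)
        tt = pv.TraitTable(
            pd.DataFrame({"trait": y}, index=[f"s{i}" for i in range(50)]), "trait"
        )
        nm = pv.fit_null_model(tt)
        np.testing.assert_allclose(nm.residuals, y - y.mean(), atol=1e-12)
        assert nm.sigma_g2 == 0.0

    def test_heritability_recovery_sib_pairs(self):
        ped = _sib_pedigree(125)  # n = 500
        kin = pv.kinship_from_pedigree(ped)
        from priorvar.simulate import simulate_family_genotypes

        d = simulate_family_genotypes(
            ped, GenotypeSimSpec(500, np.full(5, 0.3), seed=7), rng=8
        )
        tt = simulate_trait(d, TraitSimSpec(sigma_g2=1.0, sigma_e2=1.0, seed=9), kinship=kin)
        nm = pv.fit_null_model(tt, kin)
        assert abs(nm.h2 - 0.5) < 0.15

    def test_zero_heritability_boundary(self):
        ped = _sib_pedigree(75)
        kin = pv.kinship_from_pedigree(ped)
        df = pd.DataFrame(
            {"trait": np.random.default_rng(3).standard_normal(300)},
            index=[str(i) for i in ped["id"]],
        )
        nm = pv.fit_null_model(pv.TraitTable(df, "trait"), kin)
        assert nm.h2 < 0.1
        np.testing.assert_allclose(
            nm.covariance, nm.sigma_e2 * np.eye(300) + nm.sigma_g2 * 2 * kin.values,
            atol=1e-8,
        )

    def test_constant_trait_rejected(self):
        df = pd.DataFrame({"trait": np.ones(10)}, index=[f"s{i}" for i in range(10)])
        with pytest.raises(ValueError, match="constant"):
            pv.fit_null_model(pv.TraitTable(df, "trait"))

    def test_residuals_orthogonal_to_design(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "trait": rng.standard_normal(n),
                "age": rng.uniform(20, 70, n),
                "sex": rng.integers(0, 2, n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        tt = pv.TraitTable(df, "trait", covariates=["age", "sex"])
        nm = pv.fit_null_model(tt)
        # whitened residuals orthogonal to whitened design columns
        rw = nm.project(nm.whiten(nm.trait))
        Xw = nm.whiten(nm.design)
        assert np.abs(Xw.T @ rw).max() < 1e-8 * n


class TestDecorrelate:
    def test_identity_covariance_passthrough(self, rng):
        y = rng.standard_normal(40)
        tt = pv.TraitTable(
            pd.DataFrame({"trait": y}, index=[f"s{i}" for i in range(40)]), "trait"
        )
        nm = pv.fit_null_model(tt)
        # whitening by sigma_e * I only rescales
        np.testing.assert_allclose(
            pv.decorrelate_trait(nm) * np.sqrt(nm.sigma_e2), nm.residuals, atol=1e-10
        )

    def test_deterministic(self, null_model):
        a = pv.decorrelate_trait(null_model)
        b = pv.decorrelate_trait(null_model)
        np.testing.assert_array_equal(a, b)

    def test_familial_decorrelation(self):
        """Across replicates, sib-pair correlation of the surrogate is ~0."""
        ped = _sib_pedigree(75)
        kin = pv.kinship_from_pedigree(ped)
        n = 300
        cov = 1.0 * 2 * kin.values + 1.0 * np.eye(n)
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(12)
        prods = []
        # fit once on one replicate, then reuse the whitener (known covariance)
        df = pd.DataFrame({"trait": L @ rng.standard_normal(n)},
                          index=[str(i) for i in ped["id"]])
        nm = pv.fit_null_model(pv.TraitTable(df, "trait"), kin)
        sib_a = [i for i, s in enumerate(nm.subjects) if s.startswith("a")]
        sib_b = [i for i, s in enumerate(nm.subjects) if s.startswith("b")]
        for _ in range(300):
            y = L @ rng.standard_normal(n)
            z = nm.whiten(y - y.mean())
            prods.append(np.mean(z[sib_a] * z[sib_b]))
        assert abs(np.mean(prods)) < 0.1
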