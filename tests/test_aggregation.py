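"""Burden/T5, SKAT, chi-square-mixture tails, and the permutation LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, norm

import priorvar as pv
from priorvar.aggregation import _binomial_lrt, mixture_quantile
from priorvar.simulate import (
    GenotypeSimSpec,
    TraitSimSpec,
    simulate_genotypes,
    simulate_trait,
)


class TestDavies:
    @pytest.mark.parametrize(
        "q,lam,expected",
        [
            (3.841, [1.0], 0.0500),
            (5.991, [1.0, 1.0], 0.0500),
            (chi2.isf(0.01, 5), [1.0] * 5, 0.01),
        ],
    )
    def test_chi_square_quantiles(self, q, lam, expected):
        p, method, err = pv.davies_pvalue(q, lam)
        assert p == pytest.approx(expected, abs=1e-4)
        assert method == "davies"

    def test_monte_carlo_agreement(self, rng):
        lam = np.array([2.0, 1.0, 0.5])
        q = 10.0
        p, method, _ = pv.davies_pvalue(q, lam)
        n = 10**6
        draws = lam @ rng.chisquare(1, size=(3, n))
        mc = np.mean(draws > q)
        se = np.sqrt(mc * (1 - mc) / n)
        assert method == "davies"
        assert abs(p - mc) < 3 * se

    def test_scaling_invariance(self):
        lam = [1.7, 0.3, 0.1]
        p1, _, _ = pv.davies_pvalue(5.0, lam)
        p2, _, _ = pv.davies_pvalue(500.0, [100 * x for x in lam])
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_liu_fallback_is_sane(self):
        p = pv.liu_pvalue(5.991, [1.0, 1.0])
        assert p == pytest.approx(0.05, abs=1e-4)  # exact when eigenvalues equal

    def test_requires_positive_eigenvalue(self):
        with pytest.raises(ValueError):
            pv.davies_pvalue(1.0, [0.0, 0.0])

    def test_quantile_inverts_tail(self):
        lam = [2.0, 1.0, 0.5]
        q = mixture_quantile(0.05, lam)
        assert pv.davies_pvalue(q, lam)[0] == pytest.approx(0.05, abs=1e-6)


class TestBurdenScore:
    variants = pd.DataFrame(
        {"chrom": "1", "pos": [1, 2], "id": ["a", "b"], "ref": "A", "alt": "C"}
    )

    def make(self, dosages):
        return pv.DosageMatrix(["s1"], self.variants, np.asarray(dosages, float))

    def test_weighted_sum(self):
        d = self.make([[1.0, 2.0]])
        w = pv.WeightVector(np.array(["a", "b"]), np.ones(2))
        assert pv.burden_score(d, w)[0] == pytest.approx(3.0)

    def test_signed_weights(self):
        d = self.make([[1.0, 1.0]])
        w = pv.WeightVector(np.array(["a", "b"]), np.array([10.0, 5.0]),
                            direction=np.array([1.0, -1.0]))
        assert pv.burden_score(d, w)[0] == pytest.approx(5.0)

    def test_zero_dosages(self):
        d = self.make([[0.0, 0.0]])
        w = pv.WeightVector(np.array(["a", "b"]), np.ones(2))
        assert pv.burden_score(d, w)[0] == 0.0

    def test_misaligned_weights_rejected(self):
        d = self.make([[1.0, 1.0]])
        with pytest.raises(ValueError):
            pv.burden_score(d, pv.WeightVector(np.array(["a"]), np.ones(1)))


class TestT5:
    def test_gls_oracle_small_n(self, rng):
        """Score z agrees with the explicit GLS projection formula, n=50."""
        d = simulate_genotypes(GenotypeSimSpec(50, np.full(6, 0.2), seed=3))
        tt = simulate_trait(d, TraitSimSpec(seed=4))
        nm = pv.fit_null_model(tt)
        w = pv.WeightVector(d.variants["id"].to_numpy(), rng.uniform(0.5, 2, 6))
        res = pv.t5_test(d, nm, w, maf_cutoff=1.0)
        # oracle: whitened regression with known covariance sigma_e2 * I
        from priorvar.core import minor_dosages

        b = minor_dosages(d) @ w.omega
        y = tt.trait
        X = np.column_stack([np.ones(50)])
        P = np.eye(50) - X @ np.linalg.solve(X.T @ X, X.T)
        z_oracle = (b @ P @ y) / np.sqrt(b @ P @ b) / np.sqrt(nm.sigma_e2)
        assert res.score == pytest.approx(z_oracle, abs=1e-6)
        assert res.p == pytest.approx(2 * norm.sf(abs(z_oracle)), abs=1e-6)

    def test_maf_filter_empties_result(self):
        d = simulate_genotypes(GenotypeSimSpec(300, np.array([0.4]), seed=5))
        tt = simulate_trait(d, TraitSimSpec(seed=6))
        nm = pv.fit_null_model(tt)
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(1))
        res = pv.t5_test(d, nm, w, maf_cutoff=0.05)
        assert "empty" in res.flags and res.p is None

    def test_degenerate_constant_burden(self):
        variants = pd.DataFrame(
            {"chrom": "1", "pos": [1], "id": ["a"], "ref": "A", "alt": "C"}
        )
        n = 30
        d = pv.DosageMatrix([f"s{i}" for i in range(n)], variants, np.full((n, 1), 1.0))
        df = pd.DataFrame({"trait": np.random.default_rng(0).standard_normal(n)},
                          index=[f"s{i}" for i in range(n)])
        nm = pv.fit_null_model(pv.TraitTable(df, "trait"))
        w = pv.WeightVector(np.array(["a"]), np.ones(1))
        res = pv.t5_test(d, nm, w, maf_cutoff=1.0)
        assert "degenerate" in res.flags and res.p is None

    def test_null_type_one_error(self):
        """Empirical size at alpha=0.05 within the 95% binomial CI."""
        n, reps = 300, 400
        d = simulate_genotypes(GenotypeSimSpec(n, np.full(8, 0.03), seed=7))
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(8))
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(reps):
            df = pd.DataFrame({"trait": rng.standard_normal(n)}, index=d.subjects)
            nm = pv.fit_null_model(pv.TraitTable(df, "trait"))
            res = pv.t5_test(d, nm, w, maf_cutoff=0.05)
            hits += res.p is not None and res.p < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / reps)


class TestSkat:
    def test_single_variant_equals_score_test(self, small_dosages, null_model):
        d1 = small_dosages.subset_variants(np.array([20]))
        w = pv.WeightVector(d1.variants["id"].to_numpy(), np.ones(1))
        skat = pv.skat_test(d1, null_model, pv.KernelSpec("weighted_linear", w))
        t5 = pv.t5_test(d1, null_model, w, maf_cutoff=1.0)
        assert skat.p == pytest.approx(t5.p, abs=1e-8)

    def test_duplication_doubles_q_keeps_p(self, small_dosages, null_model):
        d = small_dosages
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(d.n_variants))
        base = pv.skat_test(d, null_model, pv.KernelSpec("weighted_linear", w))
        dup_variants = pd.concat(
            [d.variants, d.variants.assign(pos=d.variants["pos"] + 7,
                                           id=d.variants["id"] + "_dup")]
        )
        dd = pv.DosageMatrix(d.subjects, dup_variants, np.hstack([d.dosages] * 2))
        wd = pv.WeightVector(dd.variants["id"].to_numpy(), np.ones(dd.n_variants))
        dup = pv.skat_test(dd, null_model, pv.KernelSpec("weighted_linear", wd))
        assert dup.q == pytest.approx(2 * base.q, rel=1e-10)
        np.testing.assert_allclose(dup.eigenvalues, 2 * base.eigenvalues, rtol=1e-8)
        assert dup.p == pytest.approx(base.p, abs=1e-10)

    def test_weight_scaling_invariance(self, small_dosages, null_model):
        d = small_dosages
        w1 = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(d.n_variants))
        w3 = pv.WeightVector(d.variants["id"].to_numpy(), 3.0 * np.ones(d.n_variants))
        r1 = pv.skat_test(d, null_model, pv.KernelSpec("weighted_linear", w1))
        r3 = pv.skat_test(d, null_model, pv.KernelSpec("weighted_linear", w3))
        assert r3.q == pytest.approx(3 * r1.q, rel=1e-10)  # Q scales with W
        assert r3.p == pytest.approx(r1.p, abs=1e-10)

    def test_ordering_invariance(self, small_dosages, null_model, rng):
        d = small_dosages
        w = pv.WeightVector(d.variants["id"].to_numpy(),
                            rng.uniform(0.5, 2, d.n_variants))
        base = pv.skat_test(d, null_model, pv.KernelSpec("weighted_linear", w))
        # variant order: DosageMatrix re-sorts, weights align by id
        perm = rng.permutation(d.n_variants)
        d2 = pv.DosageMatrix(d.subjects, d.variants.iloc[perm], d.dosages[:, perm])
        w2 = pv.WeightVector(w.ids[perm], w.omega[perm])
        r2 = pv.skat_test(d2, null_model, pv.KernelSpec("weighted_linear", w2))
        assert r2.p == pytest.approx(base.p, abs=1e-10)

    def test_null_p_uniform(self):
        """KS test of SKAT null p-values across fresh genotype/trait draws.

        The mixture p-value is asymptotic in n (the null variance is a
        plug-in estimate), so the check runs at a sample size where the
        asymptotics are accurate."""
        from scipy.stats import kstest

        n, reps = 600, 300
        rng = np.random.default_rng(9)
        ps = []
        for i in range(reps):
            d = simulate_genotypes(
                GenotypeSimSpec(n, rng.uniform(0.02, 0.4, 10), seed=int(rng.integers(2**31)))
            )
            df = pd.DataFrame({"trait": rng.standard_normal(n)}, index=d.subjects)
            nm = pv.fit_null_model(pv.TraitTable(df, "trait"))
            w = pv.maf_weights(pv.compute_maf(d), "beta_1_25",
                               ids=d.variants["id"].to_numpy())
            ps.append(pv.skat_test(d, nm, pv.KernelSpec("weighted_linear", w)).p)
        stat = kstest(ps, "uniform").statistic
        assert stat < 1.36 / np.sqrt(reps)  # 95% critical value

    @pytest.mark.parametrize("form", ["weighted_quadratic", "weighted_ibs"])
    def test_nonlinear_kernels_run(self, small_dosages, null_model, form):
        d = small_dosages.subset_variants(np.arange(8))
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(8))
        res = pv.skat_test(d, null_model, pv.KernelSpec(form, w))
        assert 0 <= res.p <= 1 and res.q >= 0

    def test_functional_weights_beat_uniform_power(self):
        """Effects proportional to functional score: score-informed kernel
        weights give at least the power of uniform weights."""
        n, reps, alpha = 400, 200, 0.05
        scores = np.array([6, 6, 5, 4, 3, 2, 1, 1, 1, 1], dtype=float)
        rng = np.random.default_rng(10)
        d = simulate_genotypes(GenotypeSimSpec(n, np.full(10, 0.05), seed=11))
        ids = d.variants["id"].to_numpy()
        w_fun = pv.functional_weights(scores, "kernel", ids=ids)
        w_uni = pv.WeightVector(ids, np.ones(10))
        beta = 0.18 * scores
        hits_fun = hits_uni = 0
        for _ in range(reps):
            y = d.dosages @ beta + rng.standard_normal(n)
            df = pd.DataFrame({"trait": y}, index=d.subjects)
            nm = pv.fit_null_model(pv.TraitTable(df, "trait"))
            hits_fun += pv.skat_test(d, nm, pv.KernelSpec("weighted_linear", w_fun)).p < alpha
            hits_uni += pv.skat_test(d, nm, pv.KernelSpec("weighted_linear", w_uni)).p < alpha
        assert hits_fun >= hits_uni


class TestWeightedThresholdLrt:
    def _dosage(self, n, rng):
        return simulate_genotypes(
            GenotypeSimSpec(n, np.full(6, 0.1), seed=int(rng.integers(2**31)))
        )

    def test_identical_proportions_give_p_one(self):
        counts = np.array([[30, 70], [30, 70]])
        assert _binomial_lrt(counts) == pytest.approx(0.0, abs=1e-12)

    def test_g_statistic_oracle(self):
        counts = np.array([[20, 80], [5, 95]], dtype=float)
        total, rows, cols = counts.sum(), counts.sum(1), counts.sum(0)
        expected = np.outer(rows, cols) / total
        g = 2 * np.sum(counts * np.log(counts / expected))
        assert _binomial_lrt(counts) == pytest.approx(g, abs=1e-8)

    def test_null_type_one_error(self):
        n, reps = 200, 300
        rng = np.random.default_rng(13)
        d = self._dosage(n, rng)
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.full(6, 5.0))
        hits = 0
        for _ in range(reps):
            status = rng.integers(0, 2, n)
            while status.sum() in (0, n):
                status = rng.integers(0, 2, n)
            res = pv.weighted_threshold_lrt(d, status, w, n_perm=200,
                                            rng=int(rng.integers(2**31)))
            hits += res.p < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / reps) + 0.01

    def test_empty_class_rejected(self, rng):
        d = self._dosage(20, rng)
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(6))
        with pytest.raises(ValueError, match="empty"):
            pv.weighted_threshold_lrt(d, np.ones(20, dtype=int), w, n_perm=100)

    def test_block_permutation_runs(self, rng):
        d = self._dosage(60, rng)
        w = pv.WeightVector(d.variants["id"].to_numpy(), np.ones(6))
        status = rng.integers(0, 2, 60)
        status[0], status[1] = 0, 1
        blocks = np.repeat(np.arange(30), 2)
        res = pv.weighted_threshold_lrt(d, status, w, n_perm=150, rng=1, blocks=blocks)
        assert 0 < res.p <= 1
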