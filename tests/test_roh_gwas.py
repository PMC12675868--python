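import numpy as np
import pandas as pd
import pytest

from rohdep import depression_model as dm
from rohdep import pedigree_kinship as pk
from rohdep import roh_gwas as rg
from rohdep import synthetic_data as sd
from rohdep.io_formats import make_pedigree
from rohdep.roh_detection import roh_state_matrix

from conftest import random_genotypes


def _fit_fixture(seed=11, beta=0.0, **cfg_kw):
    base = dict(n_founders=15, n_generations=3, n_per_generation=40,
                n_chrom=2, chrom_length_bp=40_000_000,
                n_records_per_animal=5, n_cg=4, beta_f_true=beta, seed=seed)
    base.update(cfg_kw)
    cfg = sd.SimConfig(**base)
    ped, geno, pheno, truth = sd.simulate_dataset(
        cfg, with_genotypes=(beta != 0 or bool(base.get("planted_loci"))))
    fit = dm.fit_model(dm.ModelSpec(cfg.trait_name), pheno, ped)
    return cfg, ped, geno, pheno, truth, fit


class TestAdjustedPhenotypes:
    def test_formula_arithmetic(self):
        """u=1.0, pe=0.5, residuals (-0.1, -0.3) -> y_adj = 1.3."""
        fit = dm.MixedModelFit(
            b=pd.Series(dtype=float),
            u=pd.Series({"a": 1.0}), pe=pd.Series({"a": 0.5}),
            varcomp={}, beta=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            residuals=np.array([-0.1, -0.3]),
            record_animals=np.array(["a", "a"]),
            converged=True, n_evals=0)
        y = rg.adjust_phenotypes(fit)
        assert y["a"] == pytest.approx(1.3)

    def test_single_record_mean_is_residual(self):
        fit = dm.MixedModelFit(
            b=pd.Series(dtype=float),
            u=pd.Series({"a": 2.0}), pe=pd.Series({"a": -1.0}),
            varcomp={}, beta=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            residuals=np.array([0.7]), record_animals=np.array(["a"]),
            converged=True, n_evals=0)
        assert rg.adjust_phenotypes(fit)["a"] == pytest.approx(1.7)

    def test_rejects_fit_with_inbreeding_covariate(self):
        fit = dm.MixedModelFit(
            b=pd.Series(dtype=float), u=pd.Series({"a": 0.0}),
            pe=pd.Series({"a": 0.0}), varcomp={},
            beta=pd.Series({"F": -1.0}), se=pd.Series({"F": 0.5}),
            residuals=np.array([0.0]), record_animals=np.array(["a"]),
            converged=True, n_evals=0)
        with pytest.raises(ValueError):
            rg.adjust_phenotypes(fit)

    def test_null_fit_recovers_record_mean_structure(self):
        """On a single-cg no-covariate fit, y_adj equals the animal's mean
        record minus the intercept (u + pe + mean resid reassembles it)."""
        cfg, ped, geno, pheno, truth, fit = _fit_fixture(
            n_cg=1, sigma_cg=0.0, interval_effects=(0,) * 5,
            age_effect_linear=0.0, age_effect_quadratic=0.0)
        y = rg.adjust_phenotypes(fit)
        means = pheno.groupby("animal")["value"].mean()
        # X holds intercept (+ age terms with ~zero effect); compare to
        # mean record minus fitted fixed part per animal
        d = pheno.copy().reset_index(drop=True)
        fitted_fixed = d["value"].to_numpy() - (
            fit.u[d["animal"]].to_numpy()
            + fit.pe[d["animal"]].to_numpy() + fit.residuals)
        fixed_mean = pd.Series(fitted_fixed,
                               index=d["animal"]).groupby(level=0).mean()
        np.testing.assert_allclose(y[means.index],
                                   means - fixed_mean[means.index],
                                   atol=1e-8)


class TestEligibility:
    def test_strictly_more_than_twenty(self):
        H = np.zeros((40, 3), dtype=np.int8)
        H[:20, 0] = 1
        H[:21, 1] = 1
        H[:40, 2] = 1
        assert list(rg.eligible_snps(H)) == [1, 2]

    def test_all_zero_empty(self):
        assert len(rg.eligible_snps(np.zeros((30, 5), dtype=np.int8))) == 0


class TestThresholds:
    def test_published_scan_sizes(self):
        sig, sug = rg.thresholds(36_705)
        assert sig == pytest.approx(0.05 / 36_705)
        assert sug == pytest.approx(1 / 36_705)

    def test_single_snp_capped(self):
        assert rg.thresholds(1) == (0.05, 1.0)

    def test_suggestive_never_tighter(self):
        for n in (1, 10, 12_648, 36_584):
            sig, sug = rg.thresholds(n)
            assert sug >= sig

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            rg.thresholds(0)


class TestRegions:
    def _rows(self, items):
        return pd.DataFrame(items, columns=["snp_id", "chrom", "pos_bp",
                                            "p", "collinear"])

    def test_merge_within_gap(self):
        rows = self._rows([("s1", 1, 1_000_000, 1e-6, False),
                           ("s2", 1, 1_500_000, 1e-7, False)])
        reg = rg.summarize_regions(rows, (1e-8, 1e-4))
        assert len(reg) == 1 and reg.iloc[0].n_snp == 2
        assert reg.iloc[0].min_p == pytest.approx(1e-7)

    def test_isolated_snp_single_region(self):
        rows = self._rows([("s1", 9, 69_514_180, 2.7e-5, False)])
        reg = rg.summarize_regions(rows, (1e-6, 1e-4))
        r = reg.iloc[0]
        assert (r.start_bp, r.end_bp, r.n_snp) == (69_514_180, 69_514_180, 1)
        assert r.tier == "suggestive"

    def test_gap_splits_regions(self):
        rows = self._rows([("s1", 1, 1_000_000, 1e-6, False),
                           ("s2", 1, 3_000_000, 1e-9, False)])
        reg = rg.summarize_regions(rows, (1e-8, 1e-4))
        assert len(reg) == 2
        assert set(reg["tier"]) == {"suggestive", "significant"}

    def test_no_passing_snps_empty(self):
        rows = self._rows([("s1", 1, 1_000_000, 0.5, False)])
        assert len(rg.summarize_regions(rows, (1e-8, 1e-4))) == 0

    def test_min_p_equals_member_minimum(self):
        rng = np.random.default_rng(8)
        items = [(f"s{i}", 1, int(p), float(10 ** -rng.uniform(3, 9)), False)
                 for i, p in enumerate(np.sort(rng.integers(1, 5 * 10 ** 7,
                                                            40)))]
        rows = self._rows(items)
        thr = (1e-7, 1e-3)
        regs = rg.summarize_regions(rows, thr)
        passing = rows[rows["p"] <= thr[1]]
        for r in regs.itertuples(index=False):
            members = passing[(passing["chrom"] == r.chrom)
                              & (passing["pos_bp"] >= r.start_bp)
                              & (passing["pos_bp"] <= r.end_bp)]
            assert r.min_p == members["p"].min()


class TestScan:
    def test_two_stage_close_to_one_stage_joint_fit(self):
        """On a single-cg fixture the two-stage ROH-state effect is within
        10% of the one-stage joint animal-model fit (the two-stage
        procedure is an approximation by construction)."""
        cfg, ped, geno, pheno, truth, fit = _fit_fixture(
            seed=19, beta=0.0, n_cg=1, sigma_cg=0.0,
            interval_effects=(0,) * 5, age_effect_linear=0.0,
            age_effect_quadratic=0.0, n_per_generation=60,
            n_records_per_animal=8)
        bulls = list(dict.fromkeys(pheno["animal"]))
        # synthetic carrier state: a mid-chromosome block; effect injected
        # directly so both routes see the same signal
        rng = np.random.default_rng(0)
        h = (rng.random(len(bulls)) < 0.4).astype(float)
        hs = pd.Series(h, index=bulls)
        pheno2 = pheno.copy()
        pheno2["value"] = pheno2["value"] + hs[pheno2["animal"]].to_numpy() * -2.0
        fit0 = dm.fit_model(dm.ModelSpec(cfg.trait_name), pheno2, ped)
        y = rg.adjust_phenotypes(fit0)
        A, _ = pk.build_A(ped, bulls)
        # build one eligible SNP whose state is h and dosage random
        geno_b = random_genotypes(np.random.default_rng(1), len(bulls), 4)
        geno_b.samples[:] = bulls
        H = np.zeros((len(bulls), 4), dtype=np.int8)
        H[:, 2] = h.astype(np.int8)
        rows = rg.scan(y.loc[bulls], geno_b, H, A)
        beta_two_stage = rows.loc[rows["snp_id"] == "s2", "beta_roh"].iloc[0]
        # one-stage: records model with x and h as animal covariates
        fcov = pd.DataFrame({
            "x": pd.Series(geno_b.codes[:, 2].astype(float), index=bulls),
            "h": hs})
        spec = dm.ModelSpec(cfg.trait_name,
                            inbreeding_covariates=("x", "h"))
        fit1 = dm.fit_model(spec, pheno2, ped, f_covariates=fcov)
        assert beta_two_stage == pytest.approx(fit1.beta["h"], rel=0.10)

    def test_collinear_snp_flagged(self):
        rng = np.random.default_rng(2)
        n = 40
        bulls = [f"b{i}" for i in range(n)]
        geno = random_genotypes(rng, n, 4)
        geno.samples[:] = bulls
        # h identical to dosage column -> collinear with x
        H = np.zeros((n, 4), dtype=np.int8)
        geno.codes[:, 1] = np.where(np.arange(n) < 25, 2, 0)
        H[:, 1] = (geno.codes[:, 1] == 2)
        y = pd.Series(rng.normal(size=n), index=bulls)
        A = np.eye(n)
        rows = rg.scan(y, geno, H, A, variances=(0.5, 1.0))
        r = rows[rows["snp_id"] == "s1"].iloc[0]
        assert r["collinear"] and np.isnan(r["beta_roh"])

    def test_scan_invariant_to_snp_order(self):
        rng = np.random.default_rng(3)
        n = 50
        bulls = [f"b{i}" for i in range(n)]
        geno = random_genotypes(rng, n, 6)
        geno.samples[:] = bulls
        H = (rng.random((n, 6)) < 0.7).astype(np.int8)
        y = pd.Series(rng.normal(size=n), index=bulls)
        A = np.eye(n)
        rows = rg.scan(y, geno, H, A, variances=(0.5, 1.0))
        perm = rng.permutation(6)
        geno2 = geno.subset_snps(np.ones(6, dtype=bool))
        geno2.codes[:] = geno.codes[:, perm]
        # permuting codes and H together only relabels SNPs
        rows2 = rg.scan(y, geno2, H[:, perm], A, variances=(0.5, 1.0))
        got = rows2.set_index(rows2.index)["beta_roh"].to_numpy()
        want = rows.iloc[perm]["beta_roh"].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_per_snp_variance_mode_agrees_on_iid_data(self):
        """With unrelated animals the per-SNP REML and the null-fixed
        variance components describe the same iid model, so the effect
        estimates agree closely."""
        rng = np.random.default_rng(9)
        n = 60
        bulls = [f"b{i}" for i in range(n)]
        geno = random_genotypes(rng, n, 4)
        geno.samples[:] = bulls
        H = (rng.random((n, 4)) < 0.7).astype(np.int8)
        y = pd.Series(rng.normal(size=n), index=bulls)
        A = np.eye(n)
        fixed = rg.scan(y, geno, H, A)
        per = rg.scan(y, geno, H, A, variance_mode="per_snp")
        np.testing.assert_allclose(per["beta_roh"], fixed["beta_roh"],
                                   atol=0.05)
        with pytest.raises(ValueError):
            rg.scan(y, geno, H, A, variance_mode="nope")
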