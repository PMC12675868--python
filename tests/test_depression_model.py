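import numpy as np
import pandas as pd
import pytest

from rohdep import depression_model as dm
from rohdep import pedigree_kinship as pk
from rohdep import synthetic_data as sd
from rohdep.io_formats import ValidationError, make_pedigree, make_phenotype_table


def _pheno(rows):
    return make_phenotype_table(pd.DataFrame(
        rows, columns=["animal", "trait", "value", "cg", "interval_class",
                       "age_months"]))


class TestPhenotypeQc:
    def _table(self):
        rng = np.random.default_rng(0)
        rows = []
        for a in range(5):
            for r in range(30):
                rows.append((f"b{a}", "NUM", float(rng.normal(30, 3)),
                             "cg1", "4", 40.0))
        return _pheno(rows)

    def test_age_window_inclusive(self):
        t = self._table()
        t.loc[0, "age_months"] = 96.0
        t.loc[1, "age_months"] = 97.0
        out, rep = dm.phenotype_qc(t, min_cg=1, min_per_bull=1)
        ages = out["age_months"]
        assert (ages <= 96).all() and rep["after_age_filter"] == len(t) - 1

    def test_small_cg_dropped(self):
        t = self._table()
        t.loc[:18, "cg"] = "cg_small"  # 19 records
        out, _ = dm.phenotype_qc(t, min_cg=20, min_per_bull=1)
        assert "cg_small" not in set(out["cg"])

    def test_mild_outliers_kept(self):
        t = self._table()
        sd_ = t["value"].std()
        t.loc[0, "value"] = t["value"].mean() + 2 * sd_
        out, rep = dm.phenotype_qc(t, min_cg=1, min_per_bull=1)
        assert rep["after_sd_filter"] == rep["input"]

    def test_extreme_outlier_removed(self):
        t = self._table()
        t.loc[0, "value"] = 1e6
        out, rep = dm.phenotype_qc(t, min_cg=1, min_per_bull=1)
        assert rep["after_sd_filter"] == rep["input"] - 1

    def test_low_record_bull_dropped(self):
        t = self._table()
        t = t[~((t["animal"] == "b0") & (t.index % 2 == 0))]
        out, _ = dm.phenotype_qc(t, min_cg=1, min_per_bull=20)
        assert "b0" not in set(out["animal"])

    def test_empty_output_names_step(self):
        t = self._table()
        with pytest.raises(ValidationError, match="after_cg_filter"):
            dm.phenotype_qc(t, min_cg=10_000, min_per_bull=1)


class TestFit:
    def test_degenerates_to_ols_slope(self):
        """With both random effects fixed at zero and a single contemporary
        group, the inbreeding coefficient estimate is the OLS slope."""
        rng = np.random.default_rng(1)
        animals = [f"b{i}" for i in range(30)]
        ped = make_pedigree([(a, None, None) for a in animals])
        f = pd.Series(rng.uniform(0, 0.3, 30), index=animals, name="F")
        rows = []
        for a in animals:
            y = 10 - 2.0 * f[a] + rng.normal(0, 0.5)
            rows.append((a, "NUM", y, "cg1", "4", 40.0))
        data = _pheno(rows)
        spec = dm.ModelSpec("NUM", inbreeding_covariates=("F",))
        fit = dm.fit_model(spec, data, ped, f_covariates=f.to_frame(),
                           variances=(0.0, 0.0, 1.0))
        X = np.column_stack([np.ones(30), f[data["animal"]].to_numpy()])
        beta_ols = np.linalg.lstsq(X, data["value"].to_numpy(), rcond=None)[0]
        assert fit.beta["F"] == pytest.approx(beta_ols[1], abs=1e-9)

    def test_matches_dense_mme_solve(self):
        """Solutions with fixed variances equal the direct dense solve of
        Henderson's equations on a balanced toy."""
        rng = np.random.default_rng(2)
        animals = [f"b{i}" for i in range(10)]
        ped = make_pedigree([(a, None, None) for a in animals])
        rows = []
        for a in animals:
            for r in range(5):
                rows.append((a, "NUM", float(rng.normal(20, 2)),
                             f"cg{r % 2}", "4", 30.0 + r))
        data = _pheno(rows)
        su2, spe2, se2 = 2.0, 1.0, 4.0
        fit = dm.fit_model(dm.ModelSpec("NUM"), data, ped,
                           variances=(su2, spe2, se2))
        # independent dense MME assembly
        n = len(data)
        cg = pd.get_dummies(data["cg"], drop_first=True).to_numpy(float)
        age = data["age_months"].to_numpy()
        ac = age - age.mean()
        X = np.column_stack([np.ones(n), cg, ac, ac * ac])
        Z = np.zeros((n, 10))
        for i, a in enumerate(data["animal"]):
            Z[i, animals.index(a)] = 1
        lam_u, lam_pe = se2 / su2, se2 / spe2
        A_inv = np.eye(10)  # unrelated animals
        top = np.hstack([X.T @ X, X.T @ Z, X.T @ Z])
        mid = np.hstack([Z.T @ X, Z.T @ Z + lam_u * A_inv, Z.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z, Z.T @ Z + lam_pe * np.eye(10)])
        C = np.vstack([top, mid, bot])
        rhs = np.concatenate([X.T @ data["value"], Z.T @ data["value"],
                              Z.T @ data["value"]])
        sol = np.linalg.solve(C, rhs)
        p = X.shape[1]
        np.testing.assert_allclose(fit.u.to_numpy(), sol[p:p + 10],
                                   atol=1e-9)
        np.testing.assert_allclose(fit.pe.to_numpy(), sol[p + 10:],
                                   atol=1e-9)

    def test_beta_invariant_to_reference_level_and_centering(self):
        rng = np.random.default_rng(3)
        animals = [f"b{i}" for i in range(25)]
        ped = make_pedigree([(a, None, None) for a in animals])
        f = pd.Series(rng.uniform(0, 0.3, 25), index=animals, name="F")
        rows = []
        for a in animals:
            for r in range(4):
                rows.append((a, "NUM", float(rng.normal(20 - f[a], 1)),
                             f"cg{r % 3}", "4", float(rng.uniform(20, 80))))
        data = _pheno(rows)
        spec = dm.ModelSpec("NUM", inbreeding_covariates=("F",))
        fit1 = dm.fit_model(spec, data, ped, f_covariates=f.to_frame(),
                            variances=(1.0, 0.5, 1.0))
        # relabel cg so a different level is first; recenter age off
        data2 = data.copy()
        data2["cg"] = data2["cg"].map({"cg0": "z", "cg1": "cg1",
                                       "cg2": "cg2"})
        spec2 = dm.ModelSpec("NUM", inbreeding_covariates=("F",),
                             center_age=False)
        fit2 = dm.fit_model(spec2, data2, ped, f_covariates=f.to_frame(),
                            variances=(1.0, 0.5, 1.0))
        assert fit1.beta["F"] == pytest.approx(fit2.beta["F"], abs=1e-8)
        assert fit1.se["F"] == pytest.approx(fit2.se["F"], abs=1e-8)

    def test_reml_profile_matches_dense_v_likelihood(self):
        """The MME-based profiled restricted likelihood differences equal
        the textbook dense-V REML computed directly."""
        rng = np.random.default_rng(4)
        cfg = sd.SimConfig(n_founders=10, n_generations=2,
                           n_per_generation=20, n_chrom=1,
                           n_records_per_animal=4, n_cg=3, beta_f_true=0.0,
                           seed=5)
        ped = sd.simulate_pedigree(cfg)
        data, _ = sd.simulate_phenotypes(ped, None, cfg)
        A, animals = pk.build_A(ped)

        def dense_neg2_reml(lam_u, lam_pe, se2=1.0):
            d = data.reset_index(drop=True)
            n = len(d)
            cg = pd.get_dummies(d["cg"], drop_first=True).to_numpy(float)
            iv = pd.get_dummies(d["interval_class"],
                                drop_first=True).to_numpy(float)
            age = d["age_months"].to_numpy()
            ac = age - age.mean()
            X = np.column_stack([np.ones(n), cg, iv, ac, ac * ac])
            Z = np.zeros((n, len(animals)))
            phen = list(dict.fromkeys(d["animal"]))
            W = np.zeros((n, len(phen)))
            for i, a in enumerate(d["animal"]):
                Z[i, animals.index(a)] = 1
                W[i, phen.index(a)] = 1
            V = (Z @ A @ Z.T / lam_u + W @ W.T / lam_pe + np.eye(n)) * se2
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
            y = d["value"].to_numpy()
            sign, ld_v = np.linalg.slogdet(V)
            sign2, ld_x = np.linalg.slogdet(XtViX)
            return ld_v + ld_x + float(y @ P @ y)

        # the REML optimum must be a minimum of the dense-V criterion:
        # perturbing any component away from the estimates never lowers it
        fit = dm.fit_model(dm.ModelSpec("MOT"), data, ped)
        vu, vpe, ve = (fit.varcomp["sigma_u2"], fit.varcomp["sigma_pe2"],
                       fit.varcomp["sigma_e2"])
        base = dense_neg2_reml(ve / vu, ve / vpe, ve)
        for fac in (0.7, 1.4):
            assert dense_neg2_reml(ve / (vu * fac), ve / vpe, ve) >= base - 1e-6
            assert dense_neg2_reml(ve / vu, ve / (vpe * fac), ve) >= base - 1e-6
            assert dense_neg2_reml(ve / vu, ve / vpe, ve * fac) >= base - 1e-6

    def test_permutation_destroys_significance(self):
        """Shuffling F across animals wipes out a strong depression
        signal."""
        rng = np.random.default_rng(6)
        cfg = sd.SimConfig(n_founders=20, n_generations=3,
                           n_per_generation=60, n_chrom=2,
                           chrom_length_bp=40_000_000,
                           n_records_per_animal=6, n_cg=5,
                           close_mating_prob=0.5, beta_f_true=-8.0, seed=7)
        ped, geno, data, truth = sd.simulate_dataset(cfg)
        f = truth.f_true.rename("F").to_frame()
        spec = dm.ModelSpec("MOT", inbreeding_covariates=("F",))
        fit = dm.fit_model(spec, data, ped, f_covariates=f)
        z_obs, _, _ = dm.z_test(fit.beta["F"], fit.se["F"])
        assert abs(z_obs) > 3
        zs = []
        for _ in range(20):
            fp = f.copy()
            fp["F"] = rng.permutation(fp["F"].to_numpy())
            fitp = dm.fit_model(spec, data, ped, f_covariates=fp,
                                variances=tuple(fit.varcomp.values()))
            zs.append(abs(dm.z_test(fitp.beta["F"], fitp.se["F"])[0]))
        assert np.median(zs) < 2

    def test_missing_animal_in_pedigree_rejected(self):
        ped = make_pedigree([("b0", None, None)])
        data = _pheno([("ghost", "NUM", 1.0, "cg1", "4", 40.0)])
        with pytest.raises(ValidationError, match="ghost"):
            dm.fit_model(dm.ModelSpec("NUM"), data, ped,
                         variances=(1.0, 1.0, 1.0))


class TestZTest:
    def test_published_strong_example(self):
        """beta = -6.06, SE = 1.61 gives |z| = 3.76 and three stars."""
        z, p, star = dm.z_test(-6.06, 1.61)
        assert z == pytest.approx(-3.764, abs=0.001)
        assert p < 0.001 and star == "***"

    def test_published_borderline_example(self):
        """beta = -3.38, SE = 1.69 gives z = -2.00, a single star."""
        z, p, star = dm.z_test(-3.38, 1.69)
        assert z == pytest.approx(-2.0, abs=1e-9)
        assert 0.01 < p < 0.05 and star == "*"

    def test_null(self):
        z, p, star = dm.z_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0 and star == "ns"

    def test_bad_se(self):
        with pytest.raises(ValueError):
            dm.z_test(1.0, 0.0)
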