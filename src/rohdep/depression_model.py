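"""Repeated-records animal model with inbreeding covariates.

The model is y = Xb + Zu + Wpe + beta*f + e: fixed contemporary-group and
collection-interval factors, linear and quadratic bull-age covariates and
one or two inbreeding covariates in b; additive breeding values u with
covariance sigma_u^2 A over all pedigree animals; permanent-environment
effects pe (one per phenotyped animal) with covariance sigma_pe^2 I; iid
residuals.  Solutions come from Henderson's mixed-model equations.  Variance
components are REML estimates: the residual variance is profiled out in
closed form and the restricted likelihood is maximized over the two variance
ratios (Nelder-Mead on the log scale), every evaluation being one Cholesky
factorization of the MME coefficient matrix.  Regression coefficients are
tested with z = beta_hat / se(beta_hat) against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.optimize as opt
import scipy.sparse as sp
from scipy.stats import norm

from .io_formats import INTERVAL_CLASSES, ValidationError
from .pedigree_kinship import build_A_inverse, pedigree_indices


# ---------------------------------------------------------------------------
# phenotype quality control
# ---------------------------------------------------------------------------

def phenotype_qc(table: pd.DataFrame, sd_mult: float = 4.0,
                 age_range: tuple = (12.0, 96.0), min_cg: int = 20,
                 min_per_bull: int = 20):
    """Record filters, applied in order per trait: (1) values within
    mean +/- sd_mult*SD, (2) collection age inside the inclusive window,
    (3) drop contemporary-group subclasses with fewer than ``min_cg``
    records, (4) drop bulls with fewer than ``min_per_bull`` remaining
    records.  Returns (filtered table, per-step report)."""
    t = table.copy()
    report = {"input": len(t)}

    stats = t.groupby("trait")["value"].agg(["mean", "std"])
    mu = t["trait"].map(stats["mean"])
    sd = t["trait"].map(stats["std"]).fillna(0.0)
    keep = (t["value"] - mu).abs() <= sd_mult * sd
    t = t[keep]
    report["after_sd_filter"] = len(t)

    t = t[(t["age_months"] >= age_range[0]) & (t["age_months"] <= age_range[1])]
    report["after_age_filter"] = len(t)

    cg_n = t.groupby(["trait", "cg"])["value"].transform("size")
    t = t[cg_n >= min_cg]
    report["after_cg_filter"] = len(t)

    bull_n = t.groupby(["trait", "animal"])["value"].transform("size")
    t = t[bull_n >= min_per_bull]
    report["after_bull_filter"] = len(t)

    if len(t) == 0:
        empty_at = next(k for k in ("after_sd_filter", "after_age_filter",
                                    "after_cg_filter", "after_bull_filter")
                        if report[k] == 0)
        raise ValidationError(f"phenotype QC removed all records at step "
                              f"{empty_at}")
    return t.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# model specification and fit container
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    trait: str
    inbreeding_covariates: tuple = ()  # names of columns in f_covariates
    center_age: bool = True


@dataclass
class MixedModelFit:
    b: pd.Series
    u: pd.Series  # EBV, all pedigree animals
    pe: pd.Series  # phenotyped animals
    varcomp: dict
    beta: pd.Series  # inbreeding-covariate estimates
    se: pd.Series
    residuals: np.ndarray  # per record, aligned with the data used
    record_animals: np.ndarray
    converged: bool
    n_evals: int
    reml_objective: float | None = None


def _design_fixed(data: pd.DataFrame, spec: ModelSpec,
                  f_covariates: pd.DataFrame | None):
    """Full-rank fixed-effect design: intercept, factor dummies with the
    first level dropped, centered age polynomial, inbreeding covariates."""
    n = len(data)
    cols, names = [np.ones(n)], ["intercept"]
    for fac in ("cg", "interval_class"):
        levels = (sorted(data[fac].unique()) if fac == "cg"
                  else [c for c in INTERVAL_CLASSES if c in set(data[fac])])
        for lv in levels[1:]:
            cols.append((data[fac] == lv).to_numpy(dtype=float))
            names.append(f"{fac}[{lv}]")
    age = data["age_months"].to_numpy(dtype=float)
    ac = age - age.mean() if spec.center_age else age
    if np.ptp(age) > 0:  # constant age would add singular columns
        cols += [ac, ac * ac]
        names += ["age", "age_sq"]
    f_names = []
    for fc in spec.inbreeding_covariates:
        if f_covariates is None or fc not in f_covariates.columns:
            raise ValueError(f"inbreeding covariate {fc!r} not supplied")
        v = data["animal"].map(f_covariates[fc])
        if v.isna().any():
            missing = data.loc[v.isna(), "animal"].iloc[0]
            raise ValueError(f"no {fc} value for animal {missing!r}")
        cols.append(v.to_numpy(dtype=float))
        names.append(fc)
        f_names.append(fc)
    return np.column_stack(cols), names, f_names


def fit_model(spec: ModelSpec, data: pd.DataFrame, pedigree: pd.DataFrame,
              f_covariates: pd.DataFrame | None = None,
              variances: tuple | None = None, A_inverse=None,
              max_evals: int = 200, tol: float = 1e-8) -> MixedModelFit:
    """Fit the repeated-records animal model for one trait.

    ``variances=(sigma_u2, sigma_pe2, sigma_e2)`` skips REML; zero variance
    components drop the corresponding random effect.  ``f_covariates`` is an
    animal-indexed DataFrame whose columns named in
    ``spec.inbreeding_covariates`` enter the fixed part (the two-ROH-class
    option is simply two columns fitted jointly).
    """
    d = data[data["trait"] == spec.trait]
    if len(d) == 0:
        raise ValueError(f"no records for trait {spec.trait!r}")
    d = d.reset_index(drop=True)
    y = d["value"].to_numpy(dtype=float)
    n = len(y)

    X, names, f_names = _design_fixed(d, spec, f_covariates)
    p = X.shape[1]

    ped_idx, _, _ = pedigree_indices(pedigree)
    try:
        rec_anim = np.array([ped_idx[a] for a in d["animal"]])
    except KeyError as e:
        raise ValidationError(
            f"phenotyped animal {e.args[0]!r} missing from pedigree") from None
    q_u = len(pedigree)
    pheno_animals = list(dict.fromkeys(d["animal"]))
    pe_idx = {a: i for i, a in enumerate(pheno_animals)}
    q_pe = len(pheno_animals)
    rec_pe = np.array([pe_idx[a] for a in d["animal"]])

    Zs = sp.csr_matrix((np.ones(n), (np.arange(n), rec_anim)),
                       shape=(n, q_u))
    Ws = sp.csr_matrix((np.ones(n), (np.arange(n), rec_pe)),
                       shape=(n, q_pe))
    if A_inverse is None:
        A_inverse = build_A_inverse(pedigree)
    Ainv = np.asarray(A_inverse.todense())

    XtX = X.T @ X
    XtZ = np.asarray(Zs.T @ X).T
    XtW = np.asarray(Ws.T @ X).T
    ZtZ = np.asarray((Zs.T @ Zs).todense())
    ZtW = np.asarray((Zs.T @ Ws).todense())
    WtW = np.asarray((Ws.T @ Ws).todense())
    Xty = X.T @ y
    Zty = np.asarray(Zs.T @ y)
    Wty = np.asarray(Ws.T @ y)
    yty = float(y @ y)

    use_u_default = True
    use_pe_default = True

    def assemble(lam_u, lam_pe, use_u=True, use_pe=True):
        blocks, rhs_parts = [], [Xty]
        order = ["b"]
        top = [XtX]
        if use_u:
            top.append(np.asarray(XtZ))
            order.append("u")
            rhs_parts.append(Zty)
        if use_pe:
            top.append(np.asarray(XtW))
            order.append("pe")
            rhs_parts.append(Wty)
        rows = [np.hstack(top)]
        if use_u:
            mid = [np.asarray(XtZ).T, ZtZ + lam_u * Ainv]
            if use_pe:
                mid.append(ZtW)
            rows.append(np.hstack(mid))
        if use_pe:
            bot = [np.asarray(XtW).T]
            if use_u:
                bot.append(ZtW.T)
            bot.append(WtW + lam_pe * np.eye(q_pe))
            rows.append(np.hstack(bot))
        C = np.vstack(rows)
        return C, np.concatenate(rhs_parts), order

    def solve(C, rhs):
        try:
            cf = la.cho_factor(C, lower=True, check_finite=False)
        except la.LinAlgError:
            raise ValidationError(
                "singular mixed-model equations: confounded fixed-effect "
                f"columns among {names}") from None
        sol = la.cho_solve(cf, rhs, check_finite=False)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        return sol, cf, logdet

    n_evals = 0
    converged = True
    objective = None

    if variances is not None:
        su2, spe2, se2 = variances
        use_u, use_pe = su2 > 0, spe2 > 0
        lam_u = se2 / su2 if use_u else 0.0
        lam_pe = se2 / spe2 if use_pe else 0.0
        C, rhs, order = assemble(lam_u, lam_pe, use_u, use_pe)
        sol, cf, _ = solve(C, rhs)
        varcomp = {"sigma_u2": su2, "sigma_pe2": spe2, "sigma_e2": se2}
    else:
        use_u, use_pe = use_u_default, use_pe_default

        def neg2_reml(log_lams):
            nonlocal n_evals
            n_evals += 1
            lam_u, lam_pe = np.exp(log_lams)
            C, rhs, _ = assemble(lam_u, lam_pe)
            sol, _, logdetC = solve(C, rhs)
            ypy = yty - sol @ rhs
            if ypy <= 0:
                return np.inf
            return ((n - p) * np.log(ypy) + logdetC
                    - q_u * np.log(lam_u) - q_pe * np.log(lam_pe))

        res = opt.minimize(neg2_reml, x0=np.log([1.0, 1.0]),
                           method="Nelder-Mead",
                           options={"fatol": tol, "xatol": 1e-5,
                                    "maxfev": max_evals})
        converged = bool(res.success)
        objective = float(res.fun)
        lam_u, lam_pe = np.exp(res.x)
        C, rhs, order = assemble(lam_u, lam_pe)
        sol, cf, _ = solve(C, rhs)
        se2 = float((yty - sol @ rhs) / (n - p))
        varcomp = {"sigma_u2": se2 / lam_u, "sigma_pe2": se2 / lam_pe,
                   "sigma_e2": se2}
        su2, spe2 = varcomp["sigma_u2"], varcomp["sigma_pe2"]

    b = sol[:p]
    off = p
    u = np.zeros(q_u)
    if use_u:
        u = sol[off:off + q_u]
        off += q_u
    pe = np.zeros(q_pe)
    if use_pe:
        pe = sol[off:off + q_pe]

    resid = y - X @ b - u[rec_anim] - pe[rec_pe]

    # standard errors of the inbreeding covariates from C^-1
    beta_vals, se_vals = {}, {}
    if f_names:
        cols = [names.index(fc) for fc in f_names]
        E = np.zeros((C.shape[0], len(cols)))
        for k, c in enumerate(cols):
            E[c, k] = 1.0
        Cinv_cols = la.cho_solve(cf, E, check_finite=False)
        for k, fc in enumerate(f_names):
            beta_vals[fc] = float(b[names.index(fc)])
            se_vals[fc] = float(np.sqrt(varcomp["sigma_e2"]
                                        * Cinv_cols[cols[k], k]))

    return MixedModelFit(
        b=pd.Series(b, index=names),
        u=pd.Series(u, index=list(pedigree["animal"]), name="EBV"),
        pe=pd.Series(pe, index=pheno_animals, name="pe"),
        varcomp=varcomp,
        beta=pd.Series(beta_vals, dtype=float),
        se=pd.Series(se_vals, dtype=float),
        residuals=resid,
        record_animals=d["animal"].to_numpy(),
        converged=converged,
        n_evals=n_evals,
        reml_objective=objective,
    )


def z_test(beta_hat: float, se: float):
    """z statistic, two-sided normal p and significance stars for a
    regression coefficient."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta_hat / se
    pval = 2.0 * norm.sf(abs(z))
    star = ("***" if pval < 0.001 else "**" if pval < 0.01
            else "*" if pval < 0.05 else "ns")
    return z, pval, star
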