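"""Two-stage ROH-based genome-wide association scan.

Stage one fits the repeated-records animal model without inbreeding
covariates and collapses each bull's records to an adjusted phenotype
y_adj = u_hat + pe_hat + mean residual.  Stage two regresses y_adj on each
SNP jointly on its allele dosage x_k and its ROH state h_k (1 when the SNP
lies inside an ROH of the analyzed length class) in a mixed model with a
pedigree polygenic term, variance components estimated once under the null
and held fixed across SNPs.  Only SNPs with more than 20 ROH carriers are
scanned; genome-wide significant and suggestive thresholds are 0.05/nSNP
and 1/nSNP, and passing SNPs are merged into regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.optimize as opt

from .depression_model import MixedModelFit, z_test
from .io_formats import GenotypeMatrix


def adjust_phenotypes(fit: MixedModelFit, data: pd.DataFrame | None = None
                      ) -> pd.Series:
    """Per-animal adjusted phenotype u_hat + pe_hat + mean residual.

    ``fit`` must come from the model WITHOUT inbreeding covariates.  The
    record-to-animal alignment stored on the fit is used; ``data`` is only
    accepted for interface symmetry.
    """
    if len(fit.beta):
        raise ValueError("adjusted phenotypes require a fit without "
                         "inbreeding covariates")
    res = pd.DataFrame({"animal": fit.record_animals, "e": fit.residuals})
    mean_e = res.groupby("animal")["e"].mean()
    animals = fit.pe.index
    missing = [a for a in animals if a not in fit.u.index]
    if missing:
        raise ValueError(f"animal {missing[0]!r} has records but no EBV")
    out = fit.u.loc[animals] + fit.pe.loc[animals].to_numpy() \
        + mean_e.loc[animals].to_numpy()
    out.name = "y_adj"
    return out


def eligible_snps(H: np.ndarray, min_carriers: int = 21) -> np.ndarray:
    """Indices of SNPs whose ROH-state column sum is > 20 (>= min_carriers)."""
    return np.flatnonzero(H.sum(axis=0) >= min_carriers)


def _reml_polygenic(y: np.ndarray, X: np.ndarray, A: np.ndarray):
    """REML (sigma_u2, sigma_e2) for y = X beta + u + eps, u ~ sigma_u2 A.

    The variance ratio h = sigma_u2/sigma_e2 is profiled over a bounded
    log-scale search; the residual variance follows in closed form.
    """
    n, p = X.shape

    def crit(log_h, want_se2=False):
        h = np.exp(log_h)
        Hm = h * A + np.eye(n)
        try:
            cf = la.cho_factor(Hm, lower=True, check_finite=False)
        except la.LinAlgError:
            return np.inf
        logdetH = 2.0 * np.log(np.diag(cf[0])).sum()
        Hi_y = la.cho_solve(cf, y, check_finite=False)
        Hi_X = la.cho_solve(cf, X, check_finite=False)
        XtHiX = X.T @ Hi_X
        sign, logdetX = np.linalg.slogdet(XtHiX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
        r = y - X @ beta
        ypy = float(r @ la.cho_solve(cf, r, check_finite=False))
        if want_se2:
            return ypy / (n - p)
        return (n - p) * np.log(ypy) + logdetH + logdetX

    res = opt.minimize_scalar(crit, bounds=(-10.0, 6.0), method="bounded",
                              options={"xatol": 1e-6})
    h = float(np.exp(res.x))
    se2 = crit(res.x, want_se2=True)
    return h * se2, se2


def null_variances(y_adj: np.ndarray, A: np.ndarray):
    """REML variance components (sigma_u2, sigma_e2) of the intercept-only
    polygenic model y_adj = mu + u + eps with u ~ (0, sigma_u2 A)."""
    return _reml_polygenic(np.asarray(y_adj, dtype=float),
                           np.ones((len(y_adj), 1)), A)


def scan(y_adj: pd.Series, geno: GenotypeMatrix, H: np.ndarray,
         A: np.ndarray, variances: tuple | None = None,
         min_carriers: int = 21,
         variance_mode: str = "null_fixed") -> pd.DataFrame:
    """Per-SNP joint dosage + ROH-state mixed-model scan.

    ``A`` is the numerator-relationship block for the animals of ``y_adj``
    (same order as ``geno.samples``).  For each eligible SNP the GLS fit of
    y_adj = mu + alpha_k x_k + beta_k h_k + u + eps yields beta_k, its SE, z
    and two-sided p.  With ``variance_mode="null_fixed"`` (default) the
    variance components are estimated once under the null model mu + u + eps
    and held fixed across SNPs; ``"per_snp"`` re-estimates them for every
    SNP's own design.  Collinear SNPs are emitted with NA effects and
    excluded from thresholding.
    """
    if variance_mode not in ("null_fixed", "per_snp"):
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    if list(y_adj.index) != list(geno.samples):
        y_adj = y_adj.loc[geno.samples]
    y = y_adj.to_numpy(dtype=float)
    n = len(y)
    if H.shape != (n, geno.n_snps):
        raise ValueError("ROH-state matrix shape mismatch")
    if variances is None:
        variances = null_variances(y, A)
    su2, se2 = variances
    V = su2 * A + se2 * np.eye(n)
    cf = la.cho_factor(V, lower=True, check_finite=False)
    Vi_y = la.cho_solve(cf, y, check_finite=False)
    ones = np.ones(n)
    Vi_1 = la.cho_solve(cf, ones, check_finite=False)

    keep = eligible_snps(H, min_carriers)
    Xg = geno.codes[:, keep].astype(float)
    Hg = H[:, keep].astype(float)
    Vi_X = la.cho_solve(cf, Xg, check_finite=False)
    Vi_H = la.cho_solve(cf, Hg, check_finite=False)

    rows = []
    m = geno.snp_map
    for c, j in enumerate(keep):
        x = Xg[:, c]
        h = Hg[:, c]
        D = np.column_stack([ones, x, h])
        if variance_mode == "per_snp":
            su2_k, se2_k = _reml_polygenic(y, D, A)
            Vk = su2_k * A + se2_k * np.eye(n)
            cfk = la.cho_factor(Vk, lower=True, check_finite=False)
            ViD = la.cho_solve(cfk, D, check_finite=False)
            Vi_y = la.cho_solve(cfk, y, check_finite=False)
        else:
            ViD = np.column_stack([Vi_1, Vi_X[:, c], Vi_H[:, c]])
        M = D.T @ ViD
        rhs = ViD.T @ y
        n_car = int(h.sum())
        try:
            cond_ok = np.linalg.cond(M) < 1e10
        except np.linalg.LinAlgError:
            cond_ok = False
        if not cond_ok:
            rows.append((m["snp_id"].iloc[j], int(m["chrom"].iloc[j]),
                         int(m["pos_bp"].iloc[j]), n_car,
                         np.nan, np.nan, np.nan, np.nan, np.nan, True))
            continue
        Minv = la.inv(M, check_finite=False)
        est = Minv @ rhs
        se_b = float(np.sqrt(Minv[2, 2]))
        z, pval, _ = z_test(float(est[2]), se_b)
        rows.append((m["snp_id"].iloc[j], int(m["chrom"].iloc[j]),
                     int(m["pos_bp"].iloc[j]), n_car,
                     float(est[1]), float(est[2]), se_b, z, pval, False))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos_bp",
                                       "n_carriers", "alpha", "beta_roh",
                                       "se", "z", "p", "collinear"])


def thresholds(n_snp_scanned: int):
    """(genome-wide significant, suggestive) p-value thresholds
    0.05/n and min(1, 1/n)."""
    if n_snp_scanned < 1:
        raise ValueError("need at least one scanned SNP")
    return 0.05 / n_snp_scanned, min(1.0, 1.0 / n_snp_scanned)


def summarize_regions(rows: pd.DataFrame, thresh: tuple, trait: str = "",
                      length_class: str = "",
                      merge_gap_mb: float = 1.0) -> pd.DataFrame:
    """Group suggestive SNPs into regions per chromosome.

    Consecutive passing SNPs closer than ``merge_gap_mb`` join one region;
    single-SNP regions are allowed.  A region is tier "significant" when its
    minimum p clears the Bonferroni threshold, else "suggestive".
    """
    significant_p, suggestive_p = thresh
    collinear = (rows["collinear"].astype(bool) if "collinear" in rows.columns
                 else pd.Series(False, index=rows.index))
    ok = rows[(~collinear) & (rows["p"] <= suggestive_p)]
    regions = []
    gap_bp = merge_gap_mb * 1e6
    for chrom, grp in ok.groupby("chrom"):
        grp = grp.sort_values("pos_bp")
        start = prev = None
        members = []
        for r in grp.itertuples(index=False):
            if prev is not None and r.pos_bp - prev > gap_bp:
                regions.append(_region_row(members, trait, length_class,
                                           significant_p))
                members = []
            members.append(r)
            prev = r.pos_bp
        if members:
            regions.append(_region_row(members, trait, length_class,
                                       significant_p))
    return pd.DataFrame(regions, columns=["trait", "length_class", "chrom",
                                          "start_bp", "end_bp", "start_snp",
                                          "end_snp", "n_snp", "min_p",
                                          "tier"])


def _region_row(members, trait, length_class, significant_p):
    min_p = min(r.p for r in members)
    tier = "significant" if min_p <= significant_p else "suggestive"
    return (trait, length_class, members[0].chrom, members[0].pos_bp,
            members[-1].pos_bp, members[0].snp_id, members[-1].snp_id,
            len(members), min_p, tier)
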