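"""Discovery engine: per-SNP interaction regressions and the genome-wide scan.

Each SNP is fitted by ordinary least squares with an additive dosage term and
a multiplicative dosage×exposure interaction alongside the covariate set.
Three tests are reported per SNP: the Wald test of the SNP main effect
(β_main = 0), of the gene–environment interaction (β_int = 0), and the 2-df
joint Wald chi-square of both (β_main = 0 and β_int = 0).  Genome-wide
calibration is summarized by the genomic-control λ, the ratio of the observed
median of the 2-df joint statistics to the null chi-square(2) median.

The scan streams SNP-by-SNP over a pre-factorized covariate-only design
(Frisch–Waugh residualization), which is algebraically identical to the naive
per-SNP fit; the ``engine="naive"`` path exists to assert that contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .cohort import build_design
from .simulate import GenotypePanel, panel_maf

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 2 degrees of freedom
#: (= 2 ln 2); the denominator of the genomic-control lambda.
CHI2_2DF_MEDIAN = float(stats.chi2.ppf(0.5, 2))

#: Smallest reported p-value; Wald p-values are clipped into (0, 1].
_P_FLOOR = 5e-324

RESULT_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "maf",
    "n_used",
    "beta_main",
    "se_main",
    "beta_int",
    "se_int",
    "cov_main_int",
    "p_main",
    "p_int",
    "chi2_joint",
    "p_joint",
    "untestable",
    "rank_main",
    "rank_int",
    "rank_joint",
]


class UntestableSNP(ValueError):
    """The per-SNP design is rank deficient (e.g. a constant dosage)."""


def compute_maf(dosages) -> float:
    """Minor-allele frequency min(f, 1−f) with f = mean(dosage)/2.

    Missing entries (NaN) are ignored; any non-missing dosage outside [0, 2]
    raises.
    """
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("all dosages missing")
    if (d[ok] < 0).any() or (d[ok] > 2).any():
        raise ValueError("dosage outside [0, 2]")
    f = float(d[ok].mean()) / 2.0
    return min(f, 1.0 - f)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def lambda_gc(chi2_values) -> float:
    """Genomic-control lambda: median(observed 2-df chi-squares) / 2 ln 2."""
    v = np.asarray(chi2_values, dtype=float)
    if v.size == 0:
        raise ValueError("no chi-square statistics supplied")
    return float(np.median(v)) / CHI2_2DF_MEDIAN


def joint_test(beta_main: float, beta_int: float, cov: np.ndarray) -> tuple[float, float]:
    """2-df joint Wald test of (β_main, β_int) = (0, 0).

    ``cov`` is the symmetric positive-definite 2×2 covariance block of the two
    estimates.  Returns (chi-square statistic, upper-tail p on 2 df).
    """
    V = np.asarray(cov, dtype=float)
    if V.shape != (2, 2):
        raise ValueError("covariance block must be 2x2")
    if not np.isclose(V[0, 1], V[1, 0], rtol=1e-8, atol=1e-12):
        raise ValueError("covariance block must be symmetric")
    b = np.array([beta_main, beta_int], dtype=float)
    try:
        c = linalg.cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance block: {exc}") from exc
    except linalg.LinAlgError as exc:  # scipy's own exception type
        raise ValueError(f"singular covariance block: {exc}") from exc
    chi2 = float(b @ linalg.cho_solve(c, b))
    p = max(float(stats.chi2.sf(chi2, 2)), _P_FLOOR)
    return chi2, p


def _wald_p(z: np.ndarray, dof: int, use_t: bool) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if use_t:
            p = 2.0 * stats.t.sf(np.abs(z), dof)
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, _P_FLOOR, 1.0)


def ols_fit(y: np.ndarray, X: np.ndarray, use_t: bool = False) -> dict:
    """Plain OLS with classical covariance σ̂²(XᵀX)⁻¹ and Wald p per column.

    Raises :class:`UntestableSNP` on a rank-deficient design.  Returns beta,
    se, the full coefficient covariance, per-coefficient two-sided Wald
    p-values (normal reference by default, t with ``use_t``), rss, dof.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match design rows")
    if n <= p:
        raise UntestableSNP(f"not enough observations ({n}) for {p} parameters")
    # QR solve: the uncentered epidemiological design (raw heights, weights,
    # dosage x exposure products) is too ill-conditioned for normal equations.
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.max() == 0 or rdiag.min() / rdiag.max() < 1e-10:
        raise UntestableSNP("rank-deficient design")
    R_inv = linalg.solve_triangular(R, np.eye(p))
    XtX_inv = R_inv @ R_inv.T
    beta = R_inv @ (Q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    cov = sigma2 * XtX_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return {
        "beta": beta,
        "se": se,
        "cov": cov,
        "p": _wald_p(z, dof, use_t),
        "rss": rss,
        "dof": dof,
        "sigma2": sigma2,
        "n_used": n,
    }


def fit_snp(
    y: np.ndarray,
    X: np.ndarray,
    main_index: int = -2,
    int_index: int = -1,
    use_t: bool = False,
) -> dict:
    """OLS fit of one SNP's full design; Wald and 2-df joint tests.

    ``main_index``/``int_index`` locate the dosage and dosage×exposure columns
    (by convention the last two).  Raises :class:`UntestableSNP` on a
    rank-deficient design.
    """
    X = np.asarray(X, dtype=float)
    fit = ols_fit(y, X, use_t=use_t)
    beta, se, cov = fit["beta"], fit["se"], fit["cov"]
    rss, dof, sigma2 = fit["rss"], fit["dof"], fit["sigma2"]
    p = X.shape[1]
    mi, ii = range(p)[main_index], range(p)[int_index]
    p_main, p_int = fit["p"][mi], fit["p"][ii]
    V2 = cov[np.ix_([mi, ii], [mi, ii])]
    b2 = np.array([beta[mi], beta[ii]])
    if sigma2 > 0:
        chi2_joint, p_joint = joint_test(b2[0], b2[1], V2)
    else:  # noiseless degenerate fit
        chi2_joint = np.inf if np.any(b2 != 0) else 0.0
        p_joint = _P_FLOOR if np.any(b2 != 0) else 1.0
    return {
        "beta": beta,
        "beta_main": float(beta[mi]),
        "se_main": float(se[mi]),
        "beta_int": float(beta[ii]),
        "se_int": float(se[ii]),
        "cov_main_int": float(cov[mi, ii]),
        "p_main": float(p_main),
        "p_int": float(p_int),
        "chi2_joint": float(chi2_joint),
        "p_joint": float(p_joint),
        "rss": rss,
        "dof": dof,
        "n_used": fit["n_used"],
    }


@dataclass
class ScanSummary:
    """Genome-scan level summary: counts, calibration, and hits."""

    n_snps_input: int
    n_snps_tested: int
    n_filtered_maf: int
    n_untestable: int
    lambda_gc: float
    genomewide_alpha: float
    hits: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_snps_input": int(self.n_snps_input),
            "n_snps_tested": int(self.n_snps_tested),
            "n_filtered_maf": int(self.n_filtered_maf),
            "n_untestable": int(self.n_untestable),
            "lambda_gc": float(self.lambda_gc),
            "genomewide_alpha": float(self.genomewide_alpha),
            "n_hits": int(len(self.hits)),
            "hit_snps": list(self.hits["snp_id"]),
        }


def _ranks(p: np.ndarray, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Ascending ranks 1..M with ties broken by (chromosome, position)."""
    chrom_codes = pd.factorize(chrom, sort=True)[0]
    order = np.lexsort((pos, chrom_codes, p))
    ranks = np.empty(len(p), dtype=float)
    ranks[order] = np.arange(1, len(p) + 1)
    return ranks


def genome_scan(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    model_variant: str = "full",
    maf_floor: float = 0.05,
    genomewide_alpha: float = 5e-8,
    use_t: bool = False,
    extra_covariates: tuple[str, ...] = (),
    engine: str = "fast",
) -> tuple[pd.DataFrame, ScanSummary]:
    """MAF-filter, fit and rank every SNP; summarize calibration and hits.

    ``panel`` and ``cohort`` must be row-aligned.  Subjects with a missing
    dosage are dropped per SNP (complete-case per test).  Returns the per-SNP
    result table (one row per SNP surviving the MAF filter) and a
    :class:`ScanSummary`.
    """
    if engine not in ("fast", "naive"):
        raise ValueError("engine must be 'fast' or 'naive'")
    if panel.n_subjects != len(cohort):
        raise ValueError("panel and cohort are not row-aligned")
    n = len(cohort)
    maf = panel_maf(panel.dosages)
    keep = np.flatnonzero(maf >= maf_floor)
    n_filtered = panel.n_snps - keep.size
    if keep.size == 0:
        raise ValueError(f"no SNPs survive the MAF filter at floor {maf_floor}")
    logger.info(
        "scan: %d subjects, %d SNPs read, %d filtered at MAF < %g, %d to test",
        n, panel.n_snps, n_filtered, maf_floor, keep.size,
    )

    y = cohort["annual_decline"].to_numpy(float)
    exposure = cohort["cumulative_exposure"].to_numpy(float)
    G = panel.dosages[:, keep]

    stat_names = [
        "n_used", "beta_main", "se_main", "beta_int", "se_int",
        "cov_main_int", "p_main", "p_int", "chi2_joint", "p_joint",
    ]
    stats_arr = {k: np.full(keep.size, np.nan) for k in stat_names}
    untestable = np.zeros(keep.size, dtype=bool)

    has_nan = np.isnan(G).any(axis=0)
    if engine == "fast":
        Z, _ = build_design(
            cohort, dosage=None, model_variant=model_variant,
            extra_covariates=extra_covariates,
        )
        pz = Z.shape[1]
        Q, _ = np.linalg.qr(Z)
        full = np.flatnonzero(~has_nan)
        if full.size:
            Gf = G[:, full]
            GE = Gf * exposure[:, None]
            a = Gf - Q @ (Q.T @ Gf)
            b = GE - Q @ (Q.T @ GE)
            yr = y - Q @ (Q.T @ y)
            saa = np.einsum("ij,ij->j", a, a)
            sbb = np.einsum("ij,ij->j", b, b)
            sab = np.einsum("ij,ij->j", a, b)
            say = a.T @ yr
            sby = b.T @ yr
            det = saa * sbb - sab**2
            bad = (saa < n * 1e-16) | (det < 1e-12 * saa * sbb)
            good = ~bad
            with np.errstate(divide="ignore", invalid="ignore"):
                bm = (sbb * say - sab * sby) / det
                bi = (saa * sby - sab * say) / det
                rss = np.maximum(yr @ yr - bm * say - bi * sby, 0.0)
                dof = n - (pz + 2)
                sigma2 = rss / dof
                se_m = np.sqrt(sigma2 * sbb / det)
                se_i = np.sqrt(sigma2 * saa / det)
                cov_mi = -sigma2 * sab / det
                chi2_j = (bm**2 * saa + 2 * bm * bi * sab + bi**2 * sbb) / sigma2
            idx = full[good]
            stats_arr["n_used"][idx] = n
            stats_arr["beta_main"][idx] = bm[good]
            stats_arr["se_main"][idx] = se_m[good]
            stats_arr["beta_int"][idx] = bi[good]
            stats_arr["se_int"][idx] = se_i[good]
            stats_arr["cov_main_int"][idx] = cov_mi[good]
            stats_arr["p_main"][idx] = _wald_p(bm[good] / se_m[good], dof, use_t)
            stats_arr["p_int"][idx] = _wald_p(bi[good] / se_i[good], dof, use_t)
            stats_arr["chi2_joint"][idx] = chi2_j[good]
            stats_arr["p_joint"][idx] = np.clip(
                stats.chi2.sf(chi2_j[good], 2), _P_FLOOR, 1.0
            )
            untestable[full[bad]] = True
        per_snp = np.flatnonzero(has_nan)
    else:
        per_snp = np.arange(keep.size)

    for j in per_snp:
        d = G[:, j]
        ok = ~np.isnan(d)
        sub = cohort.iloc[np.flatnonzero(ok)].reset_index(drop=True)
        try:
            X, _ = build_design(
                sub, dosage=d[ok], model_variant=model_variant,
                extra_covariates=extra_covariates,
            )
            res = fit_snp(y[ok], X, use_t=use_t)
        except UntestableSNP:
            untestable[j] = True
            continue
        for k in stat_names:
            stats_arr[k][j] = res[k]

    meta = panel.snp_meta.iloc[keep].reset_index(drop=True)
    results = pd.DataFrame(
        {
            "snp_id": meta["snp_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "maf": maf[keep],
            **stats_arr,
            "untestable": untestable,
        }
    )
    testable = ~untestable
    if not testable.any():
        raise ValueError("no testable SNPs after filtering")
    for tag in ("main", "int", "joint"):
        col = f"p_{tag}"
        ranks = np.full(keep.size, np.nan)
        t = np.flatnonzero(testable)
        ranks[t] = _ranks(
            results[col].to_numpy(float)[t],
            results["chrom"].to_numpy()[t],
            results["pos"].to_numpy()[t],
        )
        results[f"rank_{tag}"] = ranks
    lam = lambda_gc(results.loc[testable, "chi2_joint"].to_numpy(float))
    hits = (
        results[testable & (results["p_int"] < genomewide_alpha)]
        .sort_values("p_int", kind="mergesort")
        .reset_index(drop=True)
    )
    summary = ScanSummary(
        n_snps_input=panel.n_snps,
        n_snps_tested=int(testable.sum()),
        n_filtered_maf=int(n_filtered),
        n_untestable=int(untestable.sum()),
        lambda_gc=lam,
        genomewide_alpha=genomewide_alpha,
        hits=hits,
    )
    logger.info(
        "scan: %d tested, %d untestable, lambda_gc=%.4f, %d hits at alpha=%g",
        summary.n_snps_tested, summary.n_untestable, lam,
        len(hits), genomewide_alpha,
    )
    return results, summary
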