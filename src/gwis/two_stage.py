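"""Replication and post-hoc stages of the two-stage interaction study.

Stage one (the discovery scan) nominates candidates; this module carries them
forward: candidate selection with LD pruning, replication testing against a
Bonferroni level for the number of candidates, covariate-sensitivity refits,
and genotype-stratified exposure-slope estimation (major-allele homozygotes
versus minor-allele carriers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import build_design
from .ld import hard_call, pairwise_ld
from .scan import UntestableSNP, bonferroni_threshold, fit_snp, ols_fit
from .simulate import GenotypePanel

#: Normal multiplier for the 95% confidence intervals reported alongside
#: replication coefficients.
CI_MULTIPLIER = 1.96

REPLICATION_COLUMNS = [
    "variant", "snp_id", "n", "coefficient", "ci_low", "ci_high", "se",
    "p_int", "passed",
]


def select_candidates(
    scan_results: pd.DataFrame,
    panel: GenotypePanel | None = None,
    genomewide_alpha: float = 5e-8,
    maf_floor: float = 0.05,
    r2_ceiling: float = 0.95,
    max_candidates: int | None = None,
) -> list[str]:
    """Candidates to carry into replication.

    Always returns the SNP with the smallest interaction p-value; adds further
    SNPs that are genome-wide significant, have MAF at or above ``maf_floor``,
    and sit below ``r2_ceiling`` pairwise r² with every SNP already selected
    (LD computed from ``panel``; required when pruning can apply).
    """
    res = scan_results
    if "untestable" in res.columns:
        res = res[~res["untestable"].astype(bool)]
    if len(res) == 0:
        raise ValueError("empty scan results")
    res = res.sort_values(["p_int", "chrom", "pos"], kind="mergesort")
    selected = [str(res.iloc[0]["snp_id"])]
    for _, row in res.iloc[1:].iterrows():
        if max_candidates is not None and len(selected) >= max_candidates:
            break
        if not (row["p_int"] < genomewide_alpha and row["maf"] >= maf_floor):
            continue
        if panel is None:
            raise ValueError("panel required for LD pruning of extra candidates")
        r2_with_selected = [
            pairwise_ld(panel, str(row["snp_id"]), s).r2 for s in selected
        ]
        if max(r2_with_selected) < r2_ceiling:
            selected.append(str(row["snp_id"]))
    return selected


def replicate(
    candidates: list[str],
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    model_variant: str = "full",
    k: int | None = None,
    alpha: float = 0.05,
    extra_covariates: tuple[str, ...] = (),
    use_t: bool = False,
) -> pd.DataFrame:
    """Fit the interaction model per candidate in an independent sample.

    Reports the SNP×exposure coefficient (mL/sec/yr per allele per μg/m³),
    its 95% CI (estimate ± 1.96·SE), p_int, and pass/fail at the Bonferroni
    level alpha/k (k defaults to the number of candidates).
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    if k is None:
        k = len(candidates)
    threshold = bonferroni_threshold(alpha, k)
    y = cohort["annual_decline"].to_numpy(float)
    rows = []
    for sid in candidates:
        try:
            j = panel.snp_index(sid)
        except KeyError:
            raise KeyError(
                f"candidate {sid!r} is not genotyped in the replication panel"
            ) from None
        d = panel.dosages[:, j]
        ok = ~np.isnan(d)
        sub = cohort.iloc[np.flatnonzero(ok)].reset_index(drop=True)
        X, _ = build_design(
            sub, dosage=d[ok], model_variant=model_variant,
            extra_covariates=extra_covariates,
        )
        fit = fit_snp(y[ok], X, use_t=use_t)
        coef, se = fit["beta_int"], fit["se_int"]
        rows.append(
            {
                "variant": model_variant,
                "snp_id": sid,
                "n": fit["n_used"],
                "coefficient": coef,
                "ci_low": coef - CI_MULTIPLIER * se,
                "ci_high": coef + CI_MULTIPLIER * se,
                "se": se,
                "p_int": fit["p_int"],
                "passed": bool(fit["p_int"] < threshold),
            }
        )
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)


def sensitivity_suite(
    candidates: list[str],
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    variants: list[str],
    alpha: float = 0.05,
    k: int | None = None,
    extra_covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Replication-style fits across covariate-adjustment variants.

    One row per (variant, candidate), ordered by the supplied variant list.
    """
    frames = [
        replicate(
            candidates, panel, cohort, model_variant=v, k=k, alpha=alpha,
            extra_covariates=extra_covariates,
        )
        for v in variants
    ]
    return pd.concat(frames, ignore_index=True)


def pool_samples(
    panels: list[GenotypePanel], cohorts: list[pd.DataFrame]
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Stack samples (e.g. discovery + replication) for combined analyses.

    Panels must share the SNP set.  Adds a ``sample_indicator`` column (the
    sample index) to the pooled cohort so combined models can absorb mean
    differences between samples.
    """
    if len(panels) != len(cohorts) or not panels:
        raise ValueError("need matching non-empty panel/cohort lists")
    base_ids = list(panels[0].snp_meta["snp_id"])
    for p in panels[1:]:
        if list(p.snp_meta["snp_id"]) != base_ids:
            raise ValueError("panels do not share a SNP set")
    dosages = np.vstack([p.dosages for p in panels])
    sample_ids: list[str] = []
    for p, c in zip(panels, cohorts):
        sample_ids.extend(p.sample_ids or list(c["subject_id"]))
    meta = panels[0].snp_meta.copy()
    meta["maf"] = np.minimum(
        np.nanmean(dosages, axis=0) / 2.0, 1 - np.nanmean(dosages, axis=0) / 2.0
    )
    pooled_panel = GenotypePanel(dosages, meta, sample_ids)
    parts = []
    for i, c in enumerate(cohorts):
        part = c.copy()
        part["sample_indicator"] = float(i)
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    return pooled_panel, pooled


def stratified_analysis(
    snp_id: str,
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    model_variant: str = "full",
    extra_covariates: tuple[str, ...] = (),
    use_t: bool = False,
) -> pd.DataFrame:
    """Exposure slope within genotype strata of one SNP.

    Subjects are hard-called (dosages rounded; entries > 0.1 from an integer
    dropped) and split into major-allele homozygotes versus carriers of at
    least one minor allele.  Within each stratum the covariate model is
    refitted *without* SNP terms and the cumulative-exposure coefficient, its
    95% CI and p-value are reported.  An empty stratum yields a flagged row
    with n = 0 and undefined estimates.
    """
    j = panel.snp_index(snp_id)
    d = panel.dosages[:, j]
    g, keep = hard_call(d)
    f_alt = np.nanmean(d[keep]) / 2.0 if keep.any() else np.nan
    minor_is_alt = f_alt <= 0.5
    minor_count = g if minor_is_alt else 2 - g
    strata = {
        "major_homozygote": keep & (minor_count == 0),
        "minor_allele_carrier": keep & (minor_count >= 1),
    }
    y = cohort["annual_decline"].to_numpy(float)
    rows = []
    for label, mask in strata.items():
        n = int(mask.sum())
        if n == 0:
            rows.append(
                {
                    "snp_id": snp_id, "stratum": label, "n": 0,
                    "exposure_slope": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan, "empty": True,
                }
            )
            continue
        sub = cohort.iloc[np.flatnonzero(mask)].reset_index(drop=True)
        X, names = build_design(
            sub, dosage=None, model_variant=model_variant,
            extra_covariates=extra_covariates,
        )
        ei = names.index("cumulative_exposure")
        try:
            fit = ols_fit(y[mask], X, use_t=use_t)
        except UntestableSNP:
            rows.append(
                {
                    "snp_id": snp_id, "stratum": label, "n": n,
                    "exposure_slope": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p": np.nan, "empty": True,
                }
            )
            continue
        slope, se = float(fit["beta"][ei]), float(fit["se"][ei])
        rows.append(
            {
                "snp_id": snp_id, "stratum": label, "n": n,
                "exposure_slope": slope,
                "ci_low": slope - CI_MULTIPLIER * se,
                "ci_high": slope + CI_MULTIPLIER * se,
                "p": float(fit["p"][ei]),
                "empty": False,
            }
        )
    return pd.DataFrame(rows)
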