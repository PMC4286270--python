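"""Synthetic cohort generator.

Emulates the statistical structure the interaction scan assumes: LD-blocked
biallelic genotypes drawn from finite haplotype pools, residential histories
over an annual exposure grid, covariates on the scale of an adult European
cohort, and an annual lung-function-decline phenotype with optional planted
SNP main and SNP×exposure effects.

Linkage disequilibrium arises from a finite haplotype-pool model: within a
block every subject's two haplotypes are drawn independently from the block's
pool (which also yields Hardy–Weinberg genotype pairing), while different
blocks are independent.  All randomness flows from a single seed through
per-component sub-streams, so changing e.g. the exposure parameters does not
perturb the genotypes.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import ExposureGrid, assign_cumulative_exposure, season_terms

__all__ = [
    "ConfigError",
    "ExposureGridSpec",
    "SimConfig",
    "GenotypePanel",
    "SimulatedCohort",
    "build_haplotype_pools",
    "simulate_genotypes",
    "simulate_exposure",
    "simulate_covariates",
    "simulate_phenotype",
    "simulate_cohort",
    "default_covariate_effects",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def default_covariate_effects() -> dict[str, float]:
    """Default generating coefficients (mL/sec per year per covariate unit).

    Chosen so the mean decline is ≈ −35 mL/sec/yr with a modest adverse
    exposure slope (−0.05 mL/sec/yr per μg/m³ cumulative exposure).
    """
    return {
        "intercept": -60.0,
        "age": -0.6,
        "sex": -6.0,
        "height": 0.4,
        "never_smoker": 4.0,
        "weight_change": -0.8,
        "cumulative_exposure": -0.05,
    }


@dataclass(frozen=True)
class ExposureGridSpec:
    """Dimensions and statistics of the synthetic annual exposure grid.

    ``annual_means`` gives one mean (μg/m³) per follow-up calendar year; None
    selects the default linearly declining trend 27.4 → 17.2 μg/m³ whose
    11-year sum is ≈ 245 μg/m³.  ``spatial_sd`` is the SD of the per-cell
    Normal deviation around the annual trend (negative cell means truncated
    at 0).
    """

    n_cells: int = 400
    annual_means: tuple[float, ...] | None = None
    spatial_sd: float = 7.3
    start_year: int = 1991

    def resolve_means(self, n_years: int) -> np.ndarray:
        if self.annual_means is None:
            return np.linspace(27.4, 17.2, n_years)
        means = np.asarray(self.annual_means, dtype=float)
        if means.size == 1:
            return np.full(n_years, float(means[0]))
        if means.size != n_years:
            raise ConfigError(
                f"annual_means has {means.size} entries; follow-up needs {n_years}"
            )
        return means


@dataclass
class SimConfig:
    """All generator parameters.

    ``beta_main_true`` is in mL/sec/yr per minor allele; ``beta_int_true`` in
    mL/sec/yr per allele per μg/m³ cumulative exposure; ``noise_sd`` in
    mL/sec/yr.  Identical seeds reproduce identical outputs bit-for-bit.
    """

    n_subjects: int = 763
    n_snps: int = 1000
    block_size: int = 10
    haplotype_pool_size: int = 16
    maf_min: float = 0.05
    maf_max: float = 0.5
    causal_index: int | None = None
    beta_main_true: float = 0.0
    beta_int_true: float = 0.0
    covariate_effects: Mapping[str, float] = field(
        default_factory=default_covariate_effects
    )
    noise_sd: float = 35.0
    exposure_grid_spec: ExposureGridSpec = field(default_factory=ExposureGridSpec)
    followup_years: int = 11
    missing_rate: float = 0.0
    n_centers: int = 8
    allow_monomorphic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_snps < 1:
            raise ConfigError("n_subjects and n_snps must be positive")
        if self.block_size < 1:
            raise ConfigError("block_size must be positive")
        if self.block_size > self.n_snps:
            raise ConfigError(
                f"block_size ({self.block_size}) exceeds n_snps ({self.n_snps})"
            )
        if self.haplotype_pool_size < 1 or (
            self.haplotype_pool_size < 2 and not self.allow_monomorphic
        ):
            raise ConfigError(
                "haplotype_pool_size must be >= 2 (a monomorphic single-haplotype "
                "pool must be requested explicitly via allow_monomorphic=True)"
            )
        if not (0.0 <= self.maf_min <= self.maf_max <= 0.5):
            raise ConfigError("require 0 <= maf_min <= maf_max <= 0.5")
        if self.causal_index is not None and not (
            0 <= self.causal_index < self.n_snps
        ):
            raise ConfigError("causal_index out of range")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.n_centers < 1:
            raise ConfigError("n_centers must be positive")
        if self.exposure_grid_spec.n_cells < 1:
            raise ConfigError("exposure grid needs at least one cell")
        if self.exposure_grid_spec.spatial_sd < 0:
            raise ConfigError("spatial_sd must be non-negative")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Independent sub-streams per generator component."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genotypes", "exposure", "covariates", "noise")
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class GenotypePanel:
    """Subjects × SNPs dosage matrix with per-SNP metadata.

    Dosages count minor/alternate alleles in [0, 2]; hard calls are integer,
    imputed dosages fractional, missing entries NaN.  ``snp_meta`` columns:
    snp_id, chrom, pos, ref, alt, maf (sample MAF computed from the dosages).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta length does not match dosage columns")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        maf = panel_maf(self.dosages)
        if not np.allclose(
            maf, self.snp_meta["maf"].to_numpy(float), atol=1e-12, rtol=0
        ):
            raise ValueError("snp_meta MAF does not match sample MAF from dosages")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero((self.snp_meta["snp_id"] == snp_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not present in panel")
        return int(idx[0])


def panel_maf(dosages: np.ndarray) -> np.ndarray:
    """Column-wise sample minor-allele frequency, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(np.asarray(dosages, dtype=float), axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def build_haplotype_pools(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Per-block haplotype pools (each an (pool_size, block_width) 0/1 array).

    Per SNP a target minor-allele frequency is drawn uniformly from
    [maf_min, maf_max] and rounded to a whole number of pool haplotypes (at
    least one of each allele), so the pool frequency matches the target as
    closely as the pool size permits.
    """
    if rng is None:
        rng = config.rngs()["genotypes"]
    H = config.haplotype_pool_size
    pools: list[np.ndarray] = []
    for start in range(0, config.n_snps, config.block_size):
        width = min(config.block_size, config.n_snps - start)
        if H == 1:
            pools.append(np.zeros((1, width), dtype=np.int8))
            continue
        p = rng.uniform(config.maf_min, config.maf_max, size=width)
        k = np.clip(np.rint(p * H).astype(int), 1, H - 1)
        block = np.zeros((H, width), dtype=np.int8)
        for j in range(width):
            block[rng.choice(H, size=k[j], replace=False), j] = 1
        pools.append(block)
    return pools


def simulate_genotypes(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    pools: list[np.ndarray] | None = None,
) -> GenotypePanel:
    """Draw a genotype panel; pass ``pools`` to sample a second cohort (e.g.
    a replication sample) from the same source population."""
    if rng is None:
        rng = config.rngs()["genotypes"]
    if pools is None:
        pools = build_haplotype_pools(config, rng)
    n = config.n_subjects
    blocks = []
    for pool in pools:
        h = rng.integers(0, pool.shape[0], size=(n, 2))
        blocks.append(pool[h[:, 0]] + pool[h[:, 1]])
    dosages = np.concatenate(blocks, axis=1).astype(float)
    if config.missing_rate > 0:
        dosages[rng.random(dosages.shape) < config.missing_rate] = np.nan
    m = config.n_snps
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(m)],
            "chrom": "1",
            "pos": 4000 * (np.arange(m) + 1),
            "ref": "A",
            "alt": "G",
            "maf": panel_maf(dosages),
        }
    )
    return GenotypePanel(dosages, meta)


def simulate_exposure(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, ExposureGrid]:
    """Residential histories plus the annual exposure grid.

    The exposure window is the fixed calendar span
    [Jan 1 start_year, Jan 1 start_year + followup_years) shared by all
    subjects.  Each subject holds 1–3 residence periods covering the window
    without gaps or overlaps, each geocoded to one grid cell.
    """
    if rng is None:
        rng = config.rngs()["exposure"]
    spec = config.exposure_grid_spec
    n_years = int(config.followup_years)
    years = spec.start_year + np.arange(n_years)
    means = spec.resolve_means(n_years)
    dev = rng.normal(0.0, spec.spatial_sd, size=spec.n_cells) if spec.spatial_sd > 0 else np.zeros(spec.n_cells)
    values = np.maximum(means[None, :] + dev[:, None], 0.0)
    cells = [f"c{i:04d}" for i in range(spec.n_cells)]
    grid = ExposureGrid(values, cells, years)

    w_start = datetime.date(spec.start_year, 1, 1).toordinal()
    w_end = datetime.date(spec.start_year + n_years, 1, 1).toordinal()
    n = config.n_subjects
    n_res = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])
    rows = []
    for i in range(n):
        sid = f"S{i:05d}"
        cuts = np.unique(rng.integers(w_start + 1, w_end - 1, size=n_res[i] - 1))
        bounds = np.concatenate(([w_start], cuts, [w_end]))
        res_cells = rng.integers(0, spec.n_cells, size=len(bounds) - 1)
        for a, b, c in zip(bounds[:-1], bounds[1:], res_cells):
            rows.append(
                (
                    sid,
                    datetime.date.fromordinal(int(a)),
                    datetime.date.fromordinal(int(b)),
                    cells[c],
                )
            )
    history = pd.DataFrame(
        rows, columns=["subject_id", "start_date", "end_date", "cell"]
    )
    return history, grid


def simulate_covariates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Covariate table on the scale of an adult population cohort.

    Scale realism only (age ≈ N(41, 11) years, height ≈ N(169.5, 9) cm,
    weight change ≈ N(5.5, 6) kg, 43% never-smokers), not a claim of
    distributional fidelity to any real cohort.
    """
    if rng is None:
        rng = config.rngs()["covariates"]
    n = config.n_subjects
    never = rng.random(n) < 0.43
    pack_b = np.where(never, 0.0, rng.gamma(1.2, 14.0, size=n))
    pack_f = np.where(never, 0.0, rng.gamma(1.0, 6.0, size=n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "center": rng.choice(
                [f"C{j + 1}" for j in range(config.n_centers)], size=n
            ),
            "age": np.clip(rng.normal(41.0, 11.0, size=n), 18.0, 62.0),
            "sex": (rng.random(n) < 0.51).astype(int),
            "height": rng.normal(169.5, 9.0, size=n),
            "weight_baseline": np.clip(rng.normal(68.0, 12.6, size=n), 40.0, None),
            "weight_change": rng.normal(5.5, 6.0, size=n),
            "never_smoker": never.astype(int),
            "pack_years_baseline": pack_b,
            "pack_years_followup": pack_f,
        }
    )


_GENERATED_COLUMNS = {
    "intercept",
    "age",
    "sex",
    "height",
    "never_smoker",
    "weight_baseline",
    "weight_change",
    "weight_baseline_x_change",
    "pack_years_baseline",
    "pack_years_followup",
    "cumulative_exposure",
    "sin_day_baseline",
    "cos_day_baseline",
    "sin_day_followup",
    "cos_day_followup",
}


def _generation_column(cohort: pd.DataFrame, name: str) -> np.ndarray:
    n = len(cohort)
    if name == "intercept":
        return np.ones(n)
    if name == "weight_baseline_x_change":
        return (
            cohort["weight_baseline"].to_numpy(float)
            * cohort["weight_change"].to_numpy(float)
        )
    if name.startswith(("sin_day_", "cos_day_")):
        tag = name.split("_day_")[1]
        terms = np.array(
            [season_terms(d) for d in cohort[f"exam_day_{tag}"].to_numpy(float)]
        )
        return terms[:, 0] if name.startswith("sin") else terms[:, 1]
    return cohort[name].to_numpy(float)


def simulate_phenotype(
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Annual decline (mL/sec/yr): linear covariate effects plus optional
    planted SNP main and SNP×exposure effects plus Normal noise."""
    if rng is None:
        rng = config.rngs()["noise"]
    if panel.n_subjects != len(cohort):
        raise ValueError(
            f"panel has {panel.n_subjects} subjects but cohort has {len(cohort)} rows"
        )
    n = len(cohort)
    y = np.zeros(n)
    for name, coef in config.covariate_effects.items():
        if name not in _GENERATED_COLUMNS:
            raise ConfigError(f"unknown covariate_effects key {name!r}")
        y += coef * _generation_column(cohort, name)
    if config.causal_index is not None:
        g = panel.dosages[:, config.causal_index]
        if np.isnan(g).any():  # mean-impute missing causal dosages for generation
            g = np.where(np.isnan(g), np.nanmean(g), g)
        e = cohort["cumulative_exposure"].to_numpy(float)
        y += config.beta_main_true * g + config.beta_int_true * g * e
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=n)
    return y


@dataclass
class SimulatedCohort:
    """Bundle of everything one simulated sample comprises."""

    config: SimConfig
    panel: GenotypePanel
    cohort: pd.DataFrame
    history: pd.DataFrame
    grid: ExposureGrid
    pools: list[np.ndarray]


def simulate_cohort(
    config: SimConfig,
    pools: list[np.ndarray] | None = None,
    id_prefix: str = "S",
) -> SimulatedCohort:
    """Full cohort draw: genotypes, exposure, covariates, phenotype.

    ``pools`` shares the haplotype source population across samples (the
    discovery/replication split); ``id_prefix`` keeps subject identifiers
    disjoint between samples.
    """
    rngs = config.rngs()
    if pools is None:
        pools = build_haplotype_pools(config, rngs["genotypes"])
    panel = simulate_genotypes(config, rngs["genotypes"], pools)
    history, grid = simulate_exposure(config, rngs["exposure"])
    cohort = simulate_covariates(config, rngs["covariates"])

    n = config.n_subjects
    rng_c = rngs["covariates"]
    window_days = int(round(config.followup_years * 365.25))
    start_year = config.exposure_grid_spec.start_year
    base_ord = datetime.date(start_year, 1, 1).toordinal() + rng_c.integers(
        0, 365, size=n
    )
    # follow-up visits are scheduled with a few months of jitter; without it
    # the two exams' seasonal terms would be collinear in the design
    follow_ord = base_ord + window_days + rng_c.integers(-90, 91, size=n)
    cohort["exam_date_baseline"] = [
        datetime.date.fromordinal(int(o)) for o in base_ord
    ]
    cohort["exam_date_followup"] = [
        datetime.date.fromordinal(int(o)) for o in follow_ord
    ]
    cohort["exam_day_baseline"] = [
        d.timetuple().tm_yday - 1 for d in cohort["exam_date_baseline"]
    ]
    cohort["exam_day_followup"] = [
        d.timetuple().tm_yday - 1 for d in cohort["exam_date_followup"]
    ]
    cohort["followup_years"] = (follow_ord - base_ord) / 365.25

    cumexp = assign_cumulative_exposure(history, grid)
    cohort["cumulative_exposure"] = cumexp.loc[cohort["subject_id"]].to_numpy()

    decline = simulate_phenotype(panel, cohort, config, rngs["noise"])
    cohort["baseline_value"] = np.clip(
        rng_c.normal(3500.0, 1100.0, size=n), 300.0, None
    )
    cohort["followup_value"] = (
        cohort["baseline_value"] + decline * cohort["followup_years"]
    )
    cohort["annual_decline"] = (
        cohort["followup_value"] - cohort["baseline_value"]
    ) / cohort["followup_years"]

    if id_prefix != "S":
        new_ids = [id_prefix + s[1:] for s in cohort["subject_id"]]
        mapping = dict(zip(cohort["subject_id"], new_ids))
        cohort["subject_id"] = new_ids
        history = history.assign(
            subject_id=[mapping[s] for s in history["subject_id"]]
        )
    panel.sample_ids = list(cohort["subject_id"])
    return SimulatedCohort(config, panel, cohort, history, grid, pools)
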