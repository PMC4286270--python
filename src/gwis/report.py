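"""Format readers/writers, plot-data exports and run configuration.

Genotypes travel as VCF v4.2 (GT hard calls plus a DS dosage FORMAT field;
reading prefers DS when both are present) or as a wide dosage TSV.  All result
tables are tab-separated with one header row; general floats serialized with
6 significant digits, p-values with 3 significant digits in scientific
notation.  The plotting surface is data-only: QQ and Manhattan coordinate
tables, not rendered images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .simulate import GenotypePanel, panel_maf

logger = logging.getLogger(__name__)

_P_COLUMNS = {"p_main", "p_int", "p_joint", "p"}


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def _fmt_ds(x: float) -> str:
    if np.isnan(x):
        return "."
    if float(x).is_integer():
        return str(int(x))
    return format(x, ".10g")


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a biallelic panel as VCF v4.2 with GT and DS per sample.

    Positions are 1-based per the VCF standard (internal coordinates are kept
    1-based throughout, so no shift happens at this boundary).
    """
    if panel.sample_ids is None:
        raise ValueError("panel has no sample_ids; cannot write VCF")
    meta = panel.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Alternate allele dosage">\n'
        )
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j in range(panel.n_snps):
            row = meta.iloc[j]
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["snp_id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT:DS",
            ]
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    g = int(np.clip(np.rint(d), 0, 2))
                    fields.append(f"{_GT_STRINGS[g]}:{_fmt_ds(d)}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read a biallelic VCF into a panel; DS wins over GT when both present."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_rows, meta_rows = [], []
    for var in vcf:
        if var.ALT is None or len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic site at {var.CHROM}:{var.POS} "
                f"({var.REF} -> {var.ALT}); only biallelic sites are supported"
            )
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d = np.where((d < 0) | (d > 2), np.nan, d)
        else:
            gt = np.asarray(var.gt_types)
            d = np.select(
                [gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan
            )
        dosage_rows.append(d)
        meta_rows.append(
            (var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM), int(var.POS),
             var.REF, var.ALT[0])
        )
    if not dosage_rows:
        raise ValueError(f"no variants found in {path}")
    dosages = np.column_stack(dosage_rows)
    meta = pd.DataFrame(meta_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    meta["maf"] = panel_maf(dosages)
    logger.info("read %d variants x %d samples from %s", len(meta), len(samples), path)
    return GenotypePanel(dosages, meta, samples)


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    """Wide dosage matrix: SNP metadata columns then one column per subject."""
    if panel.sample_ids is None:
        raise ValueError("panel has no sample_ids; cannot write dosage table")
    meta = panel.snp_meta[["snp_id", "chrom", "pos", "ref", "alt"]]
    dosages = pd.DataFrame(panel.dosages.T, columns=panel.sample_ids)
    pd.concat([meta.reset_index(drop=True), dosages], axis=1).to_csv(
        path, sep="\t", index=False
    )


def read_dosage_tsv(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta_cols]
    dosages = df[samples].to_numpy(float).T
    meta = df[meta_cols].copy()
    meta["maf"] = panel_maf(dosages)
    return GenotypePanel(dosages, meta, samples)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypePanel:
    """Dispatch on format: 'vcf' or 'dosage-tsv' (default: by file suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "dosage-tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage-tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def align_panel_cohort(
    panel: GenotypePanel, cohort: pd.DataFrame
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Intersect panel samples with cohort subjects and normalize order.

    Subjects are matched by identifier; the output keeps the cohort's row
    order restricted to the intersection.  Disjoint sets raise with the set
    difference; partial overlap is logged.
    """
    if panel.sample_ids is None:
        raise ValueError("panel has no sample identifiers to align on")
    pids = set(panel.sample_ids)
    cids = list(cohort["subject_id"])
    common = [s for s in cids if s in pids]
    if not common:
        raise ValueError(
            "no overlap between genotype samples and cohort subjects; "
            f"only in panel: {sorted(pids - set(cids))[:5]}..., "
            f"only in cohort: {sorted(set(cids) - pids)[:5]}..."
        )
    dropped_p = len(pids) - len(common)
    dropped_c = len(cids) - len(common)
    if dropped_p or dropped_c:
        logger.info(
            "alignment dropped %d panel-only and %d cohort-only subjects",
            dropped_p, dropped_c,
        )
    row_of = {s: i for i, s in enumerate(panel.sample_ids)}
    idx = [row_of[s] for s in common]
    meta = panel.snp_meta.copy()
    dosages = panel.dosages[idx, :]
    meta["maf"] = panel_maf(dosages)
    new_panel = GenotypePanel(dosages, meta, common)
    new_cohort = (
        cohort.set_index("subject_id").loc[common].reset_index()
    )
    return new_panel, new_cohort


# ---------------------------------------------------------------------------
# Cohort / exposure tables
# ---------------------------------------------------------------------------

_DATE_COLUMNS = ("exam_date_baseline", "exam_date_followup", "start_date", "end_date")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer for cohort/history/grid tables; dates serialized ISO-8601."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "center": str})
    for col in _DATE_COLUMNS:
        if col in df.columns:
            df[col] = [pd.Timestamp(v).date() for v in df[col]]
    return df


def format_results(df: pd.DataFrame) -> pd.DataFrame:
    """String-format a result table: 6 significant digits, p-values %.3e."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        fmt = "%.3e" if col in _P_COLUMNS else "%.6g"
        out[col] = [("" if np.isnan(v) else fmt % v) for v in out[col]]
    return out


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    format_results(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Plot-data exports
# ---------------------------------------------------------------------------

def qq_data(p_values) -> pd.DataFrame:
    """Observed vs expected −log10 p for a QQ plot.

    Expected quantiles are −log10((i − 0.5)/M).  Rows are ordered by
    increasing −log10 (largest p first).  p = 0 is clipped to the smallest
    positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.maximum(p, 5e-324)
    m = p.size
    p_desc = np.sort(p)[::-1]
    expected = (np.arange(m, 0, -1) - 0.5) / m
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p_desc)}
    )


def manhattan_data(
    results: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    genomewide_alpha: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Cumulative plot coordinates and −log10 p_int per SNP.

    The coordinate offsets each chromosome by the summed lengths of the
    preceding ones (lengths default to the largest observed position).
    Returns (table, metadata); metadata carries the threshold line when
    ``genomewide_alpha`` is given.
    """
    df = results[["chrom", "pos", "p_int"]].copy()
    chroms = list(pd.unique(df["chrom"].astype(str)))

    def _key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    chroms.sort(key=_key)
    if chrom_lengths is None:
        chrom_lengths = {
            c: int(df.loc[df["chrom"].astype(str) == c, "pos"].max()) for c in chroms
        }
    offsets, running = {}, 0
    for c in chroms:
        offsets[c] = running
        running += int(chrom_lengths[c])
    df["coordinate"] = [
        offsets[str(c)] + int(p) for c, p in zip(df["chrom"], df["pos"])
    ]
    df["neglog10_p_int"] = -np.log10(np.maximum(df["p_int"].to_numpy(float), 5e-324))
    meta: dict = {"chrom_offsets": offsets, "chrom_lengths": dict(chrom_lengths)}
    if genomewide_alpha is not None:
        meta["threshold_neglog10"] = float(-np.log10(genomewide_alpha))
    return df, meta


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline settings, serializable as YAML."""

    genotypes: str = ""
    cohort: str = ""
    out_dir: str = "results"
    model_variant: str = "full"
    genomewide_alpha: float = 5e-8
    replication_alpha: float = 0.05
    replication_tests: int = 2
    maf_floor: float = 0.05
    ld_r2_threshold: float = 0.85
    ld_dprime_threshold: float = 0.9
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("genomewide_alpha", "replication_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ValueError(f"maf_floor must be in [0, 0.5), got {self.maf_floor}")
        if self.replication_tests < 1:
            raise ValueError("replication_tests must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_summary_yaml(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
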