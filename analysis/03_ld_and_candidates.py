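#!/usr/bin/env python
"""LD structure of the hit region and replication-candidate selection.

Annotates the top interaction signals with pairwise LD (EM haplotype
frequencies, D', r^2) and greedy strong-LD group labels, then selects the
candidates carried into replication: the top p_int SNP plus genome-wide
significant SNPs not in strong LD with an already-selected candidate.
Writes results/candidates/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from gwis import pairwise_ld, select_candidates, strong_ld_groups  # noqa: E402
from gwis import report  # noqa: E402

DATA = ROOT / "results" / "data"
SCAN = ROOT / "results" / "scan"
OUT = ROOT / "results" / "candidates"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = report.read_genotypes(DATA / "discovery_dosages.tsv")
    results = pd.read_csv(SCAN / "scan_results.tsv", sep="\t",
                          dtype={"chrom": str})
    tested = results[~results["untestable"].astype(bool)]
    top = tested.sort_values("p_int").head(15)

    labels = strong_ld_groups(list(top["snp_id"]), panel,
                              r2_threshold=0.85, dprime_threshold=0.9)
    annotated = top[["snp_id", "maf", "p_main", "p_int", "p_joint",
                     "rank_int"]].copy()
    annotated["ld_group"] = [labels[s] for s in annotated["snp_id"]]
    report.write_results_tsv(annotated, OUT / "top_hits_ld_groups.tsv")

    candidates = select_candidates(tested, panel, genomewide_alpha=5e-8,
                                   maf_floor=0.05, r2_ceiling=0.95,
                                   max_candidates=3)
    (OUT / "candidates.txt").write_text("\n".join(candidates) + "\n")

    print("top interaction signals with strong-LD groups:")
    print(annotated.to_string(index=False))
    print(f"\nselected replication candidates: {', '.join(candidates)}")
    if len(candidates) > 1:
        for a in candidates:
            for b in candidates:
                if a < b:
                    res = pairwise_ld(panel, a, b)
                    print(f"  LD {a} x {b}: r2={res.r2:.3f}, "
                          f"D'={res.d_prime:.3f}")
    print(f"wrote candidate tables to {OUT}")


if __name__ == "__main__":
    main()
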