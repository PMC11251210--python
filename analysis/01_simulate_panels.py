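"""Simulate the two reference germplasm panels and write their VCFs.

A small closed breeding program (census 60) and a larger diversity collection
(census 200), both predominantly selfing with GBS-like missingness and
spurious-het noise. VCFs and truth sidecars go to scratch/panels/ (they are
regenerated, not archived); a one-line summary per panel goes to
results/panel_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from svedne import make_fixture, variant_stats
from svedne.study_panels import diverse_panel, elite_panel
from svedne.genotype_io import read_vcf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out_vcf_dir = ROOT / "scratch" / "panels"
    out_vcf_dir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for name, cfg in (("elite", elite_panel()), ("diverse", diverse_panel())):
        vcf_path, truth_path = make_fixture(cfg, out_vcf_dir / f"{name}.vcf")
        G = read_vcf(vcf_path)
        stats = variant_stats(G)
        rows.append(
            {
                "panel": name,
                "census_n": cfg.n_diploid,
                "selfing_rate": cfg.selfing_rate,
                "nominal_ne": round(cfg.n_diploid / (1 + cfg.selfing_rate / (2 - cfg.selfing_rate)), 1),
                "n_samples": G.n_samples,
                "n_segregating": G.n_variants,
                "mean_maf": round(float(stats["maf"].mean()), 4),
                "mean_het_rate": round(float(stats["het_rate"].mean()), 4),
                "mean_missing_rate": round(float(stats["missing_rate"].mean()), 4),
                "vcf": str(vcf_path.relative_to(ROOT)),
            }
        )
        print(
            f"{name}: census {cfg.n_diploid}, {G.n_variants} segregating SNPs, "
            f"mean het {rows[-1]['mean_het_rate']:.3f}, wrote {vcf_path.name}"
        )

    table = pd.DataFrame(rows)
    table.to_csv(results / "panel_summary.tsv", sep="\t", index=False)
    print(f"wrote {results / 'panel_summary.tsv'}")


if __name__ == "__main__":
    sys.exit(main())
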