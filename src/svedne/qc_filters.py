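"""Marker-level QC: MAF, missingness and heterozygosity filters with attrition report.

The three filters mirror standard GBS panel curation for selfing crops:
markers with minor allele frequency below 5%, more than 20% missing calls, or
more than 20% heterozygous calls are removed. Boundary semantics are literal:
MAF uses a strict lower bound (retain maf >= maf_min), missingness and
heterozygosity use strict upper bounds (retain rate <= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import GenotypeMatrix

__all__ = ["QCReport", "variant_stats", "apply_filters"]


@dataclass
class QCReport:
    """Per-filter attrition counts plus the per-variant stats table.

    A variant failing several filters is counted once in each per-filter count
    but only once in ``n_input - n_retained``. Variants with every genotype
    missing have undefined MAF/het (NaN) and are removed and counted in
    ``n_undefined``.
    """

    n_input: int
    n_failed_maf: int
    n_failed_missing: int
    n_failed_het: int
    n_undefined: int
    n_retained: int
    per_variant_stats: pd.DataFrame

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_variant_stats.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def variant_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant (maf, missing_rate, het_rate) over non-missing genotypes.

    MAF is allele-count based: p = (2*hom_alt + het) / (2*n_called),
    maf = min(p, 1-p). A variant with all calls missing gets NaN maf/het
    (undefined, distinct from zero) and missing_rate 1.
    """
    D = G.dosage
    called = D >= 0
    n_called = called.sum(axis=0)
    n = G.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, D, 0).sum(axis=0)
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
        maf = np.minimum(p, 1.0 - p)
        het = np.where(n_called > 0, (D == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame(
        {
            "chrom": G.chroms,
            "pos": G.positions,
            "maf": maf,
            "missing_rate": 1.0 - n_called / n,
            "het_rate": het,
            "n_called": n_called,
        }
    )


def apply_filters(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
    het_max: float = 0.20,
) -> tuple[GenotypeMatrix, QCReport]:
    """Retain variants with maf >= maf_min, missing_rate <= missing_max and
    het_rate <= het_max; jointly, in one pass on the input stats.

    Joint application is order-independent and idempotent: stats are computed
    once on the input, never recomputed between filters.
    """
    for name, t in (("maf_min", maf_min), ("missing_max", missing_max), ("het_max", het_max)):
        if not 0.0 <= t <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {t}")

    stats = variant_stats(G)
    defined = stats["maf"].notna().to_numpy()
    fail_maf = defined & (stats["maf"].to_numpy() < maf_min)
    fail_missing = stats["missing_rate"].to_numpy() > missing_max
    fail_het = defined & (stats["het_rate"].to_numpy() > het_max)
    retained = defined & ~fail_maf & ~fail_missing & ~fail_het

    table = stats.copy()
    table["fail_maf"] = fail_maf
    table["fail_missing"] = fail_missing
    table["fail_het"] = fail_het
    table["retained"] = retained

    report = QCReport(
        n_input=G.n_variants,
        n_failed_maf=int(fail_maf.sum()),
        n_failed_missing=int(fail_missing.sum()),
        n_failed_het=int(fail_het.sum()),
        n_undefined=int((~defined).sum()),
        n_retained=int(retained.sum()),
        per_variant_stats=table,
    )
    return G.subset_variants(retained), report
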