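"""Pairwise LD (r²) within a physical window, decay curves, and windowed LD scores.

r² is the squared Pearson correlation of allele dosages (genotypic r²), the
phase-free statistic computed over samples non-missing at both sites. In a
highly selfed panel this converges to the haplotype-frequency r². Pairs are
intra-chromosomal only and restricted to a maximum physical distance
(default 750 kb, matching the study design the pipeline reproduces).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_map import GeneticMap
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LDPairTable",
    "DecayCurve",
    "LDScoreTrack",
    "pairwise_r2",
    "fill_genetic_distance",
    "decay_curve",
    "ld_scores",
]

_PAIR_COLUMNS = ["chrom", "idx_i", "idx_j", "pos_i", "pos_j", "bp_dist", "r2", "c"]


@dataclass
class LDPairTable:
    """All intra-chromosomal variant pairs within ``max_bp``, with r² and,
    once filled, the genetic distance c (Morgans)."""

    table: pd.DataFrame  # columns: chrom, idx_i, idx_j, pos_i, pos_j, bp_dist, r2, c
    max_bp: int
    n_skipped: int = 0  # pairs skipped: monomorphic site or <2 shared calls

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.rename(
            columns={
                "chrom": "CHR",
                "pos_i": "POS_A",
                "pos_j": "POS_B",
                "bp_dist": "BP_DIST",
                "c": "C_MORGAN",
                "r2": "R2",
            }
        )[["CHR", "POS_A", "POS_B", "BP_DIST", "C_MORGAN", "R2"]]
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


@dataclass
class DecayCurve:
    """Mean r² per physical-distance bin; only occupied bins are kept."""

    table: pd.DataFrame  # columns: bin_left_bp, bin_right_bp, mean_r2, n_pairs
    bin_width_bp: int
    scope: str  # "genome" or a chromosome label

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.table.copy()
        out.insert(0, "scope", self.scope)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


@dataclass
class LDScoreTrack:
    """Per-variant mean r² against neighbors within a physical window."""

    table: pd.DataFrame  # columns: chrom, pos, mean_r2, n_neighbors
    window_bp: int
    r2_cutoff: float

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    def to_bed(self, path: str | Path) -> Path:
        """BED export: 0-based half-open single-base intervals, score = mean r²."""
        path = Path(path)
        t = self.table
        bed = pd.DataFrame(
            {
                "chrom": t["chrom"],
                "start": t["pos"] - 1,
                "end": t["pos"],
                "name": [f"snp_{i}" for i in range(len(t))],
                "score": t["mean_r2"],
            }
        )
        bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
        return path


def _pair_block(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """r² of column x against each column of Y under pairwise-complete deletion.

    Returns (r2, good): r2 is NaN where a pair is skipped; good marks pairs
    with >= 2 shared calls and both sites polymorphic among shared samples.
    """
    vx = x >= 0
    V = vx[:, None] & (Y >= 0)
    n = V.sum(axis=0).astype(float)
    xf = x.astype(float)
    Yf = Y.astype(float)
    xm = np.where(V, xf[:, None], 0.0)
    ym = np.where(V, Yf, 0.0)
    sx = xm.sum(axis=0)
    sy = ym.sum(axis=0)
    sxx = (xm * xm).sum(axis=0)
    syy = (ym * ym).sum(axis=0)
    sxy = (xm * ym).sum(axis=0)
    var_x = n * sxx - sx * sx
    var_y = n * syy - sy * sy
    cov = n * sxy - sx * sy
    good = (n >= 2) & (var_x > 0) & (var_y > 0)
    r2 = np.full(Y.shape[1], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2[good] = (cov[good] * cov[good]) / (var_x[good] * var_y[good])
    # clip float fuzz just above 1
    np.minimum(r2, 1.0, out=r2)
    return r2, good


def pairwise_r2(G: GenotypeMatrix, max_bp: int = 750_000) -> LDPairTable:
    """Genotypic r² for every intra-chromosomal pair with bp_dist <= max_bp.

    Streams per chromosome in position-sorted blocks; results are identical to
    an all-at-once computation. Pairs where either site is monomorphic among
    the shared non-missing samples (or with < 2 shared calls) are skipped and
    counted. An input with no computable pair yields an empty table (warning,
    not an error).
    """
    if max_bp < 1:
        raise ValidationError(f"max_bp must be >= 1, got {max_bp}")
    frames = []
    n_skipped = 0
    for chrom, block in G.chrom_blocks():
        pos = G.positions[block]
        D = G.dosage[:, block]
        m = len(pos)
        for i in range(m - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_bp, side="right"))
            if j_hi <= i + 1:
                continue
            r2, good = _pair_block(D[:, i], D[:, i + 1 : j_hi])
            n_skipped += int((~good).sum())
            if not good.any():
                continue
            jj = np.arange(i + 1, j_hi)[good]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "idx_i": block.start + i,
                        "idx_j": block.start + jj,
                        "pos_i": pos[i],
                        "pos_j": pos[jj],
                        "bp_dist": pos[jj] - pos[i],
                        "r2": r2[good],
                        "c": np.nan,
                    }
                )
            )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        logger.warning("pairwise_r2: no computable pairs (empty LD table)")
        table = pd.DataFrame(columns=_PAIR_COLUMNS)
    return LDPairTable(table=table, max_bp=int(max_bp), n_skipped=n_skipped)


def fill_genetic_distance(T: LDPairTable, M: GeneticMap) -> LDPairTable:
    """Return a copy of T with c (Morgans) filled from per-chromosome cM/Mb ratios."""
    table = T.table.copy()
    if len(table):
        ratios = np.array([M.ratio(ch) for ch in table["chrom"]], dtype=float)
        table["c"] = table["bp_dist"].to_numpy(dtype=float) / 1e6 * ratios / 100.0
    return LDPairTable(table=table, max_bp=T.max_bp, n_skipped=T.n_skipped)


def decay_curve(T: LDPairTable, bin_width_bp: int, scope: str = "genome") -> DecayCurve:
    """Group pairs into [k*w, (k+1)*w) physical-distance bins and average r²."""
    if bin_width_bp <= 0:
        raise ValidationError(f"bin_width_bp must be positive, got {bin_width_bp}")
    if len(T.table) == 0:
        raise ValidationError("decay_curve needs a non-empty pair table")
    t = T.table if scope == "genome" else T.table[T.table["chrom"] == scope]
    if len(t) == 0:
        raise ValidationError(f"no pairs for scope {scope!r}")
    k = (t["bp_dist"].to_numpy() // bin_width_bp).astype(np.int64)
    g = pd.DataFrame({"k": k, "r2": t["r2"].to_numpy()}).groupby("k")["r2"].agg(["mean", "size"])
    table = pd.DataFrame(
        {
            "bin_left_bp": g.index.to_numpy() * bin_width_bp,
            "bin_right_bp": (g.index.to_numpy() + 1) * bin_width_bp,
            "mean_r2": g["mean"].to_numpy(),
            "n_pairs": g["size"].to_numpy(),
        }
    ).reset_index(drop=True)
    return DecayCurve(table=table, bin_width_bp=int(bin_width_bp), scope=scope)


def ld_scores(
    G: GenotypeMatrix,
    window_bp: int = 1_000_000,
    r2_cutoff: float = 0.0,
    pairs: LDPairTable | None = None,
) -> LDScoreTrack:
    """Per-variant mean r² against same-chromosome neighbors within ±window_bp.

    Self is excluded; only neighbor pairs with r² >= r2_cutoff contribute.
    Variants with no qualifying neighbor get NaN. A precomputed pair table may
    be supplied (its max_bp must cover window_bp); otherwise pairs are computed
    at window_bp.
    """
    if pairs is None:
        pairs = pairwise_r2(G, max_bp=window_bp)
    elif pairs.max_bp < window_bp:
        raise ValidationError(
            f"supplied pair table max_bp={pairs.max_bp} < window_bp={window_bp}"
        )
    t = pairs.table
    if len(t):
        sel = (t["bp_dist"].to_numpy() <= window_bp) & (t["r2"].to_numpy() >= r2_cutoff)
        t = t[sel]
    sums = np.zeros(G.n_variants)
    counts = np.zeros(G.n_variants, dtype=np.int64)
    if len(t):
        for col in ("idx_i", "idx_j"):
            idx = t[col].to_numpy(dtype=np.int64)
            np.add.at(sums, idx, t["r2"].to_numpy())
            np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {"chrom": G.chroms, "pos": G.positions, "mean_r2": mean, "n_neighbors": counts}
    )
    return LDScoreTrack(table=table, window_bp=int(window_bp), r2_cutoff=float(r2_cutoff))
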