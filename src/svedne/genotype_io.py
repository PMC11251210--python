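"""Read and write biallelic SNP genotypes as a samples x variants dosage matrix.

The :class:`GenotypeMatrix` is the pipeline's central container: an int8
matrix of alternate-allele counts (0/1/2, ``MISSING`` = -1) with variant
coordinates sorted by (chrom, pos). VCF input is parsed with cyvcf2;
multiallelic and non-SNP records are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from cyvcf2 import VCF

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING = -1

_NUCLEOTIDES = frozenset("ACGT")
_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome label, 1-based position, REF/ALT bases."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"REF and ALT must differ at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Dosage matrix (n_samples x n_variants) with sorted variant coordinates.

    Invariants enforced at construction: at least two samples, dosages only in
    {-1, 0, 1, 2}, and per-chromosome positions strictly increasing.
    """

    variants: list[VariantRecord]
    samples: list[str]
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if len(self.samples) < 2:
            raise ValidationError(
                f"a GenotypeMatrix needs >= 2 samples, got {len(self.samples)}"
            )
        expected = (len(self.samples), len(self.variants))
        if self.dosage.shape != expected:
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != (n_samples, n_variants) {expected}"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("dosage values must be in {-1, 0, 1, 2}")
        chroms = self.chroms
        pos = self.positions
        for c in dict.fromkeys(chroms):  # preserves order, unique
            p = pos[chroms == c]
            if not np.all(np.diff(p) > 0):
                raise ValidationError(
                    f"positions on {c} must be strictly increasing (sorted, no duplicates)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given variant indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in index],
            samples=list(self.samples),
            dosage=self.dosage[:, index],
        )

    def chrom_blocks(self) -> Iterator[tuple[str, slice]]:
        """Yield (chrom, column slice) for each contiguous chromosome block."""
        chroms = self.chroms
        start = 0
        for j in range(1, self.n_variants + 1):
            if j == self.n_variants or chroms[j] != chroms[start]:
                yield str(chroms[start]), slice(start, j)
                start = j


def _has_gt_format(vcf: VCF) -> bool:
    for h in vcf.header_iter():
        try:
            info = h.info()
        except Exception:  # pragma: no cover - defensive against odd headers
            continue
        if info.get("HeaderType") == "FORMAT" and info.get("ID") == "GT":
            return True
    return False


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix.

    Diploid GTs map to alt-allele counts (0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2,
    ./. -> MISSING); half-calls are treated as missing. Multiallelic records,
    non-SNP records and duplicate (chrom, pos) records are dropped with logged
    counts. Output is sorted by (chrom, pos).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValidationError(f"VCF must carry >= 2 samples, got {len(samples)}")
    if not _has_gt_format(vcf):
        raise ValidationError(f"VCF has no GT FORMAT field: {path}")

    rows: list[tuple[str, int, str | None, str, str, np.ndarray]] = []
    n_multiallelic = 0
    n_non_snp = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1:
            n_multiallelic += 1
            continue
        ref, alt = v.REF.upper(), alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            n_non_snp += 1
            continue
        dos = np.empty(len(samples), dtype=np.int8)
        for k, g in enumerate(v.genotypes):
            alleles = g[:-1]  # last element is the phased flag
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                dos[k] = MISSING
            else:
                dos[k] = int(alleles[0] > 0) + int(alleles[1] > 0)
        vid = v.ID if v.ID not in (None, ".") else None
        rows.append((v.CHROM, v.POS, vid, ref, alt, dos))

    if n_multiallelic or n_non_snp:
        logger.info(
            "read_vcf(%s): dropped %d multiallelic and %d non-SNP records",
            path, n_multiallelic, n_non_snp,
        )

    rows.sort(key=lambda r: (r[0], r[1]))
    # duplicate (chrom, pos) records would break the strict-ordering invariant
    seen: set[tuple[str, int]] = set()
    n_dup = 0
    kept = []
    for r in rows:
        key = (r[0], r[1])
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        kept.append(r)
    if n_dup:
        logger.warning("read_vcf(%s): dropped %d duplicate-position records", path, n_dup)

    variants = [VariantRecord(chrom=c, pos=p, ref=r, alt=a, id=i) for c, p, i, r, a, _ in kept]
    if kept:
        dosage = np.stack([d for *_, d in kept], axis=1)
    else:
        dosage = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage)


def write_vcf(G: GenotypeMatrix, path: str | Path) -> Path:
    """Write a GenotypeMatrix as a VCF 4.2 file with GT-only FORMAT."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", "##source=svedne"]
    for chrom in dict.fromkeys(v.chrom for v in G.variants):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(G.samples))
    for j, v in enumerate(G.variants):
        gts = "\t".join(_GT_STRINGS[int(d)] for d in G.dosage[:, j])
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
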