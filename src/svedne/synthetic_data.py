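"""Forward-time Wright–Fisher simulator with selfing and recombination.

Generates GBS-like biallelic SNP panels with known ground truth for validating
the LD-based Ne estimator. The model is a closed population of N diploids
reproducing in discrete generations from standing variation (no mutation,
selection or migration): each offspring draws two gametes, with probability
``selfing_rate`` both from one uniformly chosen parent, otherwise from two
distinct parents; each gamete recombines its parent's haplotypes with a
Poisson number of crossovers at uniform positions. After burn-in (default 2N
generations, long enough to approach the E(r²) ≈ 1/(1+4Nc) quasi-equilibrium)
a sample of individuals is drawn, monomorphic sites are dropped (mirroring a
SNP panel), and optional per-genotype corruption (missingness, spurious
heterozygote calls) exercises the QC filters without touching the underlying
LD.

Selfing at rate s raises the equilibrium inbreeding coefficient to
F = s/(2−s) and lowers effective size to roughly N/(1+F); this nominal value
is recorded in SimTruth as the recovery target, not asserted exactly, because
LD-based estimates under high selfing are additionally confounded by reduced
effective recombination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .genotype_io import MISSING, GenotypeMatrix, VariantRecord, write_vcf

__all__ = ["SimConfig", "SimTruth", "simulate", "make_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults give a small equilibrated random-mating
    panel suitable for estimator recovery checks."""

    n_diploid: int = 100
    selfing_rate: float = 0.0
    n_chrom: int = 2
    chrom_len_bp: int = 10_000_000
    cm_per_mb: float = 1.0
    n_loci: int = 300  # segregating sites per chromosome at generation 0
    init_freq_bounds: tuple[float, float] = (0.1, 0.9)  # uniform law for p0
    n_generations: int | None = None  # default: 2 * n_diploid (burn-in to equilibrium)
    n_sample: int = 50
    missing_rate: float = 0.0
    het_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_diploid < 2:
            raise ValidationError("n_diploid must be >= 2")
        if not 2 <= self.n_sample <= self.n_diploid:
            raise ValidationError("need 2 <= n_sample <= n_diploid")
        for name in ("selfing_rate", "missing_rate", "het_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.init_freq_bounds
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("init_freq_bounds must satisfy 0 < lo <= hi < 1")
        if self.n_generations is not None and self.n_generations < 1:
            raise ValidationError("n_generations must be >= 1")
        if self.n_chrom < 1 or self.n_loci < 1 or self.chrom_len_bp < 2:
            raise ValidationError("need n_chrom >= 1, n_loci >= 1, chrom_len_bp >= 2")
        if self.cm_per_mb <= 0:
            raise ValidationError("cm_per_mb must be positive")

    @property
    def generations(self) -> int:
        return self.n_generations if self.n_generations is not None else 2 * self.n_diploid


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated panel."""

    config: SimConfig
    realized_ne_nominal: float  # N / (1 + F) with F = s / (2 - s)
    n_segregating_out: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["config"]["init_freq_bounds"] = list(self.config.init_freq_bounds)
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _init_chromosome(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Positions (sorted, unique) and initial haplotypes (2N x L) for one chromosome."""
    n_pos = 0
    while n_pos < cfg.n_loci:  # redraw on collision; ranges are huge so rare
        pos = np.unique(rng.integers(1, cfg.chrom_len_bp + 1, size=cfg.n_loci))
        n_pos = len(pos)
    lo, hi = cfg.init_freq_bounds
    freqs = rng.uniform(lo, hi, size=cfg.n_loci)
    H = (rng.random((2 * cfg.n_diploid, cfg.n_loci)) < freqs).astype(np.int8)
    return pos, H


def _make_gametes(
    rng: np.random.Generator,
    H: np.ndarray,
    parents: np.ndarray,
    pos: np.ndarray,
    morgans: float,
    chrom_len_bp: int,
) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` from haplotype pool H.

    Crossover count per gamete is Poisson(morgans); positions are uniform on
    the chromosome. Zero-crossover gametes (the bulk at typical map lengths)
    copy one parental haplotype wholesale, which keeps this fast.
    """
    n_gam = len(parents)
    n_cross = rng.poisson(morgans, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    out = np.empty((n_gam, H.shape[1]), dtype=np.int8)
    plain = n_cross == 0
    out[plain] = H[2 * parents[plain] + start[plain]]
    for g in np.flatnonzero(~plain):
        cuts = np.sort(rng.uniform(0, chrom_len_bp, size=n_cross[g]))
        # haplotype index at each locus flips at every crossover to its left
        hap_idx = (start[g] + np.searchsorted(cuts, pos)) % 2
        p = parents[g]
        out[g] = np.where(hap_idx == 0, H[2 * p], H[2 * p + 1])
    return out


def _next_generation(
    rng: np.random.Generator,
    haplos: list[np.ndarray],
    positions: list[np.ndarray],
    cfg: SimConfig,
) -> list[np.ndarray]:
    """Advance all chromosomes one generation with a shared pedigree."""
    N = cfg.n_diploid
    selfed = rng.random(N) < cfg.selfing_rate
    mothers = rng.integers(0, N, size=N)
    fathers = np.where(
        selfed, mothers, (mothers + 1 + rng.integers(0, N - 1, size=N)) % N
    )  # distinct second parent under outcrossing
    morgans_per_chrom = cfg.chrom_len_bp / 1e6 * cfg.cm_per_mb / 100.0
    new = []
    for H, pos in zip(haplos, positions):
        child = np.empty_like(H)
        child[0::2] = _make_gametes(rng, H, mothers, pos, morgans_per_chrom, cfg.chrom_len_bp)
        child[1::2] = _make_gametes(rng, H, fathers, pos, morgans_per_chrom, cfg.chrom_len_bp)
        new.append(child)
    return new


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run the simulator and return a QC-ready GenotypeMatrix plus ground truth.

    Deterministic for a fixed config (the seed is part of SimConfig).
    """
    rng = np.random.default_rng(cfg.seed)
    positions, haplos = [], []
    for _ in range(cfg.n_chrom):
        pos, H = _init_chromosome(rng, cfg)
        positions.append(pos)
        haplos.append(H)

    for _ in range(cfg.generations):
        haplos = _next_generation(rng, haplos, positions, cfg)

    sample = rng.choice(cfg.n_diploid, size=cfg.n_sample, replace=False)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for k, (pos, H) in enumerate(zip(positions, haplos)):
        dos = (H[2 * sample] + H[2 * sample + 1]).astype(np.int8)  # n_sample x L
        alt = dos.sum(axis=0)
        seg = (alt > 0) & (alt < 2 * cfg.n_sample)
        chrom = f"chr{k + 1}"
        for p in pos[seg]:
            variants.append(VariantRecord(chrom=chrom, pos=int(p), ref="A", alt="T"))
        cols.append(dos[:, seg])
    dosage = np.concatenate(cols, axis=1) if cols else np.zeros((cfg.n_sample, 0), np.int8)

    if cfg.het_error_rate > 0:
        flip = rng.random(dosage.shape) < cfg.het_error_rate
        dosage = np.where(flip, np.int8(1), dosage)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(miss, np.int8(MISSING), dosage)

    G = GenotypeMatrix(
        variants=variants,
        samples=[f"ind_{i:04d}" for i in range(cfg.n_sample)],
        dosage=dosage,
    )
    F = cfg.selfing_rate / (2.0 - cfg.selfing_rate)
    truth = SimTruth(
        config=cfg,
        realized_ne_nominal=cfg.n_diploid / (1.0 + F),
        n_segregating_out=G.n_variants,
    )
    return G, truth


def make_fixture(cfg: SimConfig, path: str | Path) -> tuple[Path, Path]:
    """Simulate and write a VCF fixture plus a JSON truth sidecar."""
    path = Path(path)
    G, truth = simulate(cfg)
    vcf_path = write_vcf(G, path)
    truth_path = path.with_suffix(".truth.json")
    truth.to_json(truth_path)
    return vcf_path, truth_path
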