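"""End-to-end pipeline: VCF + map config -> QC report, LD tables, decay curves,
LD-score tracks and the Ne estimate, with per-stage logging and attrition counts.

Populations are analyzed independently end-to-end; the pipeline never pools
VCFs. Re-running on identical inputs yields byte-identical numeric outputs.
"""

from __future__ import annotations

import contextlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PipelineError
from .genetic_map import GeneticMap, load_map
from .genotype_io import read_vcf
from .ld_engine import decay_curve, fill_genetic_distance, ld_scores, pairwise_r2
from .ne_estimator import bin_mean_r2, estimate_ne
from .qc_filters import apply_filters

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults reproduce the study design: MAF >= 5%,
    missingness and het <= 20%, LD within 750 kb, LD scores in 1000 kb windows
    with r² cutoff 0, two-stage ('paper') Ne estimation."""

    vcf: str | Path
    out_dir: str | Path
    map_config: str | Path | None = None
    cm_per_mb: float = 1.0  # genome-wide default when no map config is given
    maf_min: float = 0.05
    missing_max: float = 0.20
    het_max: float = 0.20
    max_bp: int = 750_000
    ldscore_window_bp: int = 1_000_000
    ldscore_r2_cutoff: float = 0.0
    decay_bin_width_bp: int = 50_000
    mode: str = "paper"
    c_round_digits: int = 6
    sample_size_correction: bool = False
    log_level: str = "INFO"


@contextlib.contextmanager
def _stage(name: str, out_dir: Path):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"{name}: {exc}\n")
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %s: done", name)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute read -> QC -> pairwise LD -> distance conversion -> binning ->
    stage-1 -> Ne, writing every intermediate table under cfg.out_dir.

    Returns a report dict with the in-memory results and output paths. Any
    stage failure propagates as PipelineError tagged with the stage name;
    outputs written before the failure are retained next to a FAILED marker.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("svedne")
    root.addHandler(handler)
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))

    report: dict = {"out_dir": str(out_dir)}
    try:
        with _stage("read", out_dir):
            G = read_vcf(cfg.vcf)
            logger.info("read %d variants x %d samples from %s", G.n_variants, G.n_samples, cfg.vcf)

        with _stage("qc", out_dir):
            G_qc, qc = apply_filters(
                G, maf_min=cfg.maf_min, missing_max=cfg.missing_max, het_max=cfg.het_max
            )
            qc.to_tsv(out_dir / "qc_report.tsv")
            logger.info(
                "qc: %d -> %d variants (maf %d, missing %d, het %d, undefined %d)",
                qc.n_input, qc.n_retained, qc.n_failed_maf, qc.n_failed_missing,
                qc.n_failed_het, qc.n_undefined,
            )
            report["qc"] = qc

        with _stage("ld", out_dir):
            if G_qc.n_variants < 2:
                raise ValueError(
                    f"only {G_qc.n_variants} variants survive QC; need >= 2 for LD"
                )
            pairs = pairwise_r2(G_qc, max_bp=cfg.max_bp)
            logger.info("ld: %d pairs within %d bp (%d skipped)", len(pairs), cfg.max_bp, pairs.n_skipped)

        with _stage("map", out_dir):
            gmap = (
                load_map(cfg.map_config)
                if cfg.map_config is not None
                else GeneticMap(default_ratio=cfg.cm_per_mb)
            )
            pairs = fill_genetic_distance(pairs, gmap)
            pairs.to_tsv(out_dir / "ld_pairs.tsv")
            report["pairs"] = pairs

        with _stage("decay", out_dir):
            gw = decay_curve(pairs, bin_width_bp=cfg.decay_bin_width_bp, scope="genome")
            gw.to_tsv(out_dir / "decay_genomewide.tsv")
            report["decay_genome"] = gw
            per_chrom = {}
            for chrom in dict.fromkeys(pairs.table["chrom"]):
                dc = decay_curve(pairs, bin_width_bp=cfg.decay_bin_width_bp, scope=chrom)
                dc.to_tsv(out_dir / f"decay_{chrom}.tsv")
                per_chrom[chrom] = dc
            report["decay_by_chrom"] = per_chrom

        with _stage("ldscore", out_dir):
            track = ld_scores(
                G_qc, window_bp=cfg.ldscore_window_bp, r2_cutoff=cfg.ldscore_r2_cutoff
            )
            track.to_tsv(out_dir / "ld_scores.tsv")
            track.to_bed(out_dir / "ld_scores.bed")
            report["ld_scores"] = track

        with _stage("bins", out_dir):
            bins = bin_mean_r2(pairs, c_round_digits=cfg.c_round_digits)
            bins.to_tsv(out_dir / "distance_bins.tsv")
            logger.info("bins: %d distinct c values, %d pairs at c=0 dropped",
                        len(bins), bins.n_dropped_zero_c)
            report["bins"] = bins

        with _stage("ne", out_dir):
            est = estimate_ne(
                bins,
                mode=cfg.mode,
                n_samples=G_qc.n_samples if cfg.sample_size_correction else None,
            )
            est.to_json(out_dir / "ne_estimate.json")
            logger.info("ne: %.4g (mode=%s, %d points, %d dropped)",
                        est.ne, est.mode, est.n_points, est.dropped_nonpositive)
            report["ne"] = est

        (out_dir / "pipeline_config.json").write_text(
            json.dumps(
                {k: str(v) if isinstance(v, Path) else v for k, v in vars(cfg).items()},
                indent=2,
            )
            + "\n"
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return report
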