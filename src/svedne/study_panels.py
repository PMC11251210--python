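"""Two reference simulation panels emulating the contrasting germplasm types
the pipeline is built for.

Both are predominantly selfing (selfing rate 0.9, typical of pea) with
GBS-like genotype corruption so the QC filters have real work to do:

``elite_panel``
    A small closed breeding program: census 60, burn-in 2N generations. High
    LD, small Ne.
``diverse_panel``
    A larger diversity collection: census 200. Lower LD, larger Ne.

Under selfing at rate s the equilibrium inbreeding coefficient is
F = s/(2-s) and the nominal effective size is N/(1+F); the LD-based estimate
is additionally pulled down by the reduced effective recombination of selfers,
so recovered values sit below census size by design.
"""

from __future__ import annotations

from .synthetic_data import SimConfig

_SHARED = dict(
    selfing_rate=0.9,
    n_chrom=2,
    chrom_len_bp=10_000_000,
    cm_per_mb=1.0,
    n_loci=300,
    n_sample=50,
    missing_rate=0.10,
    het_error_rate=0.02,
)


def elite_panel(seed: int = 101) -> SimConfig:
    """Small closed breeding-program panel (census 60)."""
    return SimConfig(n_diploid=60, seed=seed, **_SHARED)


def diverse_panel(seed: int = 202) -> SimConfig:
    """Larger diversity-collection panel (census 200)."""
    return SimConfig(n_diploid=200, seed=seed, **_SHARED)
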