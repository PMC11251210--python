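"""Physical-to-genetic distance conversion via per-chromosome cM/Mb ratios.

A constant ratio per chromosome is assumed (no piecewise recombination map):
c [Morgan] = bp / 1e6 * (cM/Mb) / 100. Ratios come from user configuration, a
plain-text key-value file with a ``default`` entry and optional per-chromosome
overrides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = ["GeneticMap", "load_map", "bp_to_morgans"]

_SPLIT = re.compile(r"[=:\s]+")


@dataclass(frozen=True)
class GeneticMap:
    default_ratio: float | None = None
    ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, r in self.ratios.items():
            if not np.isfinite(r) or r <= 0:
                raise ValidationError(f"cM/Mb ratio for {chrom!r} must be positive, got {r}")
        if self.default_ratio is not None and (
            not np.isfinite(self.default_ratio) or self.default_ratio <= 0
        ):
            raise ValidationError(f"default cM/Mb ratio must be positive, got {self.default_ratio}")

    def ratio(self, chrom: str) -> float:
        if chrom in self.ratios:
            return self.ratios[chrom]
        if self.default_ratio is None:
            raise ValidationError(
                f"no cM/Mb ratio configured for chromosome {chrom!r} and no default set"
            )
        return self.default_ratio


def load_map(path: str | Path) -> GeneticMap:
    """Parse a key-value ratio config: one ``chrom = cM_per_Mb`` per line,
    ``default`` for the genome-wide fallback; '#' starts a comment."""
    path = Path(path)
    default = None
    ratios: dict[str, float] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = _SPLIT.split(line, maxsplit=1)
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: cannot parse ratio line {raw!r}")
        key, value = parts[0], parts[1].strip()
        try:
            ratio = float(value)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad ratio {value!r}") from exc
        if ratio <= 0:
            raise ValidationError(f"{path}:{lineno}: ratio must be positive, got {ratio}")
        if key.lower() == "default":
            default = ratio
        else:
            ratios[key] = ratio
    if default is None and not ratios:
        raise ValidationError(f"{path}: empty genetic-map config")
    return GeneticMap(default_ratio=default, ratios=ratios)


def bp_to_morgans(M: GeneticMap, chrom: str, bp_dist) -> np.ndarray | float:
    """Convert a physical distance (bp) to Morgans on the given chromosome."""
    bp = np.asarray(bp_dist, dtype=float)
    if np.any(bp < 0):
        raise ValidationError("bp_dist must be >= 0")
    c = bp / 1e6 * M.ratio(chrom) / 100.0
    return float(c) if np.isscalar(bp_dist) else c
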