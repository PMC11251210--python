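"""Effective population size from LD via the Sved drift–recombination relation.

At drift–recombination equilibrium the expected squared correlation between
two loci a genetic distance c (Morgans) apart is

    E(r²) = 1 / (1 + 4 Ne c),

so Ne = (1/4c) (1/E(r²) − 1). The estimator here works on distance-binned
mean r²: pairs are grouped by their (rounded) genetic distance, each group's
mean r² is one observation, and Ne is the slope of the no-intercept least
squares regression of Y = 1/μ̂ − 1 on X = 4c.

Two modes are provided:

``paper``
    Two-stage scheme: an ordinary least-squares line (with intercept) is first
    fitted to mean r² versus c; its fitted values μ̂ feed the transform. This
    linearizes a hyperbolic curve, so it is an approximation, but it smooths
    binned noise.
``direct``
    The binned means themselves are used as μ̂. Exact on a noiseless Sved
    curve, hence the validation mode for simulator recovery.

Rows with μ̂ <= 0 (possible at large c under a negative fitted slope) are
dropped and counted, never clamped: 1/μ̂ is undefined there and clamping
would bias the slope.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .ld_engine import LDPairTable

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceBins",
    "Stage1Fit",
    "NeEstimate",
    "bin_mean_r2",
    "fit_stage1",
    "estimate_ne",
    "sved_expected_r2",
]


@dataclass
class DistanceBins:
    """Mean r² per distinct genetic distance, c ascending."""

    c_values: np.ndarray  # Morgans, strictly increasing, all > 0
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    n_dropped_zero_c: int = 0

    def __post_init__(self):
        self.c_values = np.asarray(self.c_values, dtype=float)
        self.mean_r2 = np.asarray(self.mean_r2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=np.int64)
        if not (len(self.c_values) == len(self.mean_r2) == len(self.n_pairs)):
            raise ValidationError("DistanceBins arrays must have equal length")
        if len(self.c_values) == 0:
            raise ValidationError("DistanceBins cannot be empty")
        if np.any(np.diff(self.c_values) <= 0):
            raise ValidationError("c_values must be strictly increasing")
        if np.any(self.c_values <= 0):
            raise ValidationError("c_values must be positive")
        if np.any((self.mean_r2 < 0) | (self.mean_r2 > 1)):
            raise ValidationError("mean_r2 must lie in [0, 1]")
        if np.any(self.n_pairs < 1):
            raise ValidationError("n_pairs must be >= 1 per bin")

    def __len__(self) -> int:
        return len(self.c_values)

    @classmethod
    def from_arrays(cls, c, mean_r2, n_pairs=None) -> "DistanceBins":
        c = np.asarray(c, dtype=float)
        if n_pairs is None:
            n_pairs = np.ones(len(c), dtype=np.int64)
        order = np.argsort(c)
        return cls(c[order], np.asarray(mean_r2, dtype=float)[order],
                   np.asarray(n_pairs)[order])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"c_morgan": self.c_values, "mean_r2": self.mean_r2, "n_pairs": self.n_pairs}
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
        return path


@dataclass
class Stage1Fit:
    """Intercept OLS of binned mean r² on c, solved by the normal equations."""

    beta0: float
    beta1: float
    mu_hat: np.ndarray  # fitted expected r², one per retained c value
    n_used: int


@dataclass
class NeEstimate:
    """Point estimate of Ne with both regression stages' diagnostics."""

    ne: float
    mode: str  # "paper" or "direct"
    stage1: Stage1Fit | None
    n_points: int  # rows entering the final no-intercept regression
    dropped_nonpositive: int  # rows with mu_hat <= 0, excluded
    degenerate: bool = False  # ne <= 0: non-decaying LD profile

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "ne": self.ne,
            "mode": self.mode,
            "n_points": self.n_points,
            "dropped_nonpositive": self.dropped_nonpositive,
            "degenerate": self.degenerate,
        }
        if self.stage1 is not None:
            payload["stage1"] = {
                "beta0": self.stage1.beta0,
                "beta1": self.stage1.beta1,
                "n_used": self.stage1.n_used,
            }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def sved_expected_r2(ne: float, c) -> np.ndarray | float:
    """Equilibrium expectation E(r²) = 1 / (1 + 4 Ne c); c in Morgans."""
    if ne <= 0:
        raise ValidationError(f"ne must be positive, got {ne}")
    carr = np.asarray(c, dtype=float)
    if np.any(carr < 0):
        raise ValidationError("c must be >= 0")
    out = 1.0 / (1.0 + 4.0 * ne * carr)
    return float(out) if np.isscalar(c) else out


def bin_mean_r2(T: LDPairTable, c_round_digits: int = 6) -> DistanceBins:
    """Group LD pairs by genetic distance rounded to ``c_round_digits`` decimals
    of a Morgan; one mean-r² observation per distinct rounded c.

    Rounding makes "group by" on floating distances well defined. Groups at
    c = 0 (pairs closer than the rounding resolution) are dropped and logged;
    a table with only such pairs is unusable.
    """
    t = T.table
    if len(t) == 0:
        raise ValidationError("bin_mean_r2 needs a non-empty pair table")
    c = t["c"].to_numpy(dtype=float)
    if np.any(~np.isfinite(c)):
        raise ValidationError("every pair must carry a genetic distance c (run fill_genetic_distance)")
    c_rounded = np.round(c, c_round_digits)
    keep = c_rounded > 0
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("bin_mean_r2: dropped %d pairs at c = 0 after rounding", n_zero)
    if not keep.any():
        raise ValidationError("all pairs rounded to c = 0: no usable genetic distances")
    g = (
        pd.DataFrame({"c": c_rounded[keep], "r2": t["r2"].to_numpy()[keep]})
        .groupby("c")["r2"]
        .agg(["mean", "size"])
        .sort_index()
    )
    return DistanceBins(
        c_values=g.index.to_numpy(),
        mean_r2=g["mean"].to_numpy(),
        n_pairs=g["size"].to_numpy(),
        n_dropped_zero_c=n_zero,
    )


def fit_stage1(B: DistanceBins) -> Stage1Fit:
    """OLS of mean r² on c with intercept, via the normal equations
    beta = (X'X)^{-1} X'Y with design X = [1, c]."""
    c = B.c_values
    if len(np.unique(c)) < 2:
        raise ValidationError("stage-1 regression needs >= 2 distinct c values (rank deficient)")
    X = np.column_stack([np.ones_like(c), c])
    Y = B.mean_r2
    beta = np.linalg.solve(X.T @ X, X.T @ Y)
    mu_hat = X @ beta
    return Stage1Fit(beta0=float(beta[0]), beta1=float(beta[1]), mu_hat=mu_hat, n_used=len(c))


def estimate_ne(
    B: DistanceBins,
    mode: str = "paper",
    n_samples: int | None = None,
) -> NeEstimate:
    """Estimate Ne as the no-intercept least-squares slope of Y = 1/μ̂ − 1 on
    X = 4c, i.e. β₁ = ΣXY / ΣX².

    ``n_samples``, if given, subtracts the finite-sample inflation 1/n from μ̂
    before the transform (off by default: the plain relation carries no
    correction, but sample r² is upward-biased by about 1/n).
    """
    if mode not in ("paper", "direct"):
        raise ValidationError(f"mode must be 'paper' or 'direct', got {mode!r}")
    if mode == "paper":
        stage1 = fit_stage1(B)
        mu = stage1.mu_hat.copy()
    else:
        stage1 = None
        mu = B.mean_r2.copy()
    if n_samples is not None:
        if n_samples < 2:
            raise ValidationError("n_samples must be >= 2 for the sample-size correction")
        mu = mu - 1.0 / n_samples

    keep = mu > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("estimate_ne: dropped %d bins with mu_hat <= 0", dropped)
    if not keep.any():
        raise EstimationError("all bins have non-positive expected r²; cannot invert")
    Y = 1.0 / mu[keep] - 1.0
    X = 4.0 * B.c_values[keep]
    beta1 = float(X @ Y) / float(X @ X)
    degenerate = beta1 <= 0
    if degenerate:
        warnings.warn(
            f"estimated Ne = {beta1:.4g} <= 0: LD profile does not decay with distance",
            RuntimeWarning,
            stacklevel=2,
        )
    return NeEstimate(
        ne=beta1,
        mode=mode,
        stage1=stage1,
        n_points=int(keep.sum()),
        dropped_nonpositive=dropped,
        degenerate=degenerate,
    )
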