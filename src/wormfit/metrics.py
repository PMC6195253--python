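"""Estimators of competitive fitness from dual-label worm counts.

A competition plate is seeded with one unmarked ("focal") worm and one
GFP-marked competitor; at the assay endpoint a sample of ``n_total`` worms is
counted, of which ``n_gfp`` fluoresce.  Three estimators of the focal strain's
competitive fitness are derived from those two counts:

* ``p`` — the focal frequency, ``(n_total - n_gfp) / n_total``;
* ``CI`` — the competitive index, the odds ``p / (1 - p)`` that a sampled
  worm is focal;
* ``log(CI)`` — the log-odds, the scale on which downstream variance
  modelling is carried out.

``CI`` is undefined at ``p = 1`` and ``log(CI)`` at ``p in {0, 1}``; those
boundary cases are represented as NaN, never as ``±inf`` sentinels, and every
downstream summary reports how many were excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlateObservation",
    "FitnessEstimate",
    "focal_frequency",
    "competitive_index",
    "log_competitive_index",
    "inverse_competitive_index",
    "focal_odds_comparison",
    "fitness_estimate",
    "add_fitness_columns",
    "OBSERVATION_COLUMNS",
    "METHODS",
]

#: Canonical column order of the plate-observation table.
OBSERVATION_COLUMNS = [
    "block_id",
    "focal_strain",
    "competitor_strain",
    "method",
    "replicate_id",
    "n_total",
    "n_gfp",
]

#: Recognised counting methods.
METHODS = ("by_eye", "cellprofiler", "sorter")


@dataclass(frozen=True)
class PlateObservation:
    """Counts and identity of a single competition plate."""

    block_id: str
    focal_strain: str
    competitor_strain: str
    method: str
    replicate_id: str
    n_total: int
    n_gfp: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_gfp < 0:
            raise ValueError("counts must be non-negative")
        if self.n_gfp > self.n_total:
            raise ValueError(
                f"n_gfp ({self.n_gfp}) exceeds n_total ({self.n_total})"
            )


@dataclass(frozen=True)
class FitnessEstimate:
    """The three fitness estimators computed from one plate's counts.

    ``ci`` and ``log_ci`` are NaN at their respective undefined boundaries
    (``p = 1`` for CI; ``p in {0, 1}`` for log CI).
    """

    p: float
    ci: float
    log_ci: float
    n_total: int

    @property
    def ci_defined(self) -> bool:
        return not math.isnan(self.ci)

    @property
    def log_ci_defined(self) -> bool:
        return not math.isnan(self.log_ci)


def focal_frequency(n_total: int, n_gfp: int) -> float:
    """Frequency of the focal (non-fluorescent) type.

    ``p = (n_total - n_gfp) / n_total``: worms visible under brightfield but
    not under fluorescence, as a fraction of all worms counted.

    Raises
    ------
    ValueError
        If ``n_total`` is zero (no worms counted: p undefined) or if
        ``n_gfp > n_total`` (data-integrity violation).
    """
    if n_total < 1:
        raise ValueError("focal frequency undefined for an empty sample (n_total = 0)")
    if n_gfp < 0 or n_gfp > n_total:
        raise ValueError(f"n_gfp ({n_gfp}) must lie in [0, n_total] = [0, {n_total}]")
    return (n_total - n_gfp) / n_total


def competitive_index(p: float) -> float:
    """Competitive index ``CI = p / (1 - p)``, the odds of sampling a focal worm.

    Returns NaN at the boundary ``p = 1`` (infinite odds).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p == 1.0:
        return math.nan
    return p / (1.0 - p)


def log_competitive_index(p: float, base: float | None = None) -> float:
    """Log competitive index ``log(p / (1 - p))`` (natural log by default).

    The log base is configurable (``base=10`` for common log); the default is
    the natural log, the standard convention for log-odds.  Returns NaN at
    either boundary (``p = 0`` or ``p = 1``), which downstream analyses must
    exclude and report.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p == 0.0 or p == 1.0:
        return math.nan
    val = math.log(p / (1.0 - p))
    if base is not None:
        val /= math.log(base)
    return val


def inverse_competitive_index(ci: float) -> float:
    """Recover ``p`` from ``CI``: ``p = CI / (1 + CI)``."""
    if ci < 0:
        raise ValueError("CI must be non-negative")
    return ci / (1.0 + ci)


def focal_odds_comparison(p_i: float, p_j: float) -> dict[str, float]:
    """Compare two focal frequencies measured against the same competitor.

    Returns both commonly used contrasts, labelled distinctly:

    * ``frequency_ratio`` — the plain ratio of proportions ``p_i / p_j``;
    * ``odds_ratio`` — the ratio of competitive indices ``CI_i / CI_j``
      (NaN if either CI is undefined or ``CI_j = 0``).
    """
    if p_j <= 0.0:
        raise ValueError("comparison undefined for p_j = 0")
    out = {"frequency_ratio": p_i / p_j}
    ci_i = competitive_index(p_i)
    ci_j = competitive_index(p_j)
    if math.isnan(ci_i) or math.isnan(ci_j) or ci_j == 0.0:
        out["odds_ratio"] = math.nan
    else:
        out["odds_ratio"] = ci_i / ci_j
    return out


def fitness_estimate(
    n_total: int, n_gfp: int, log_base: float | None = None
) -> FitnessEstimate:
    """All three estimators from one plate's counts."""
    p = focal_frequency(n_total, n_gfp)
    return FitnessEstimate(
        p=p,
        ci=competitive_index(p),
        log_ci=log_competitive_index(p, base=log_base),
        n_total=n_total,
    )


def add_fitness_columns(
    obs: pd.DataFrame, log_base: float | None = None
) -> pd.DataFrame:
    """Append ``p``, ``ci`` and ``log_ci`` columns to an observation table.

    ``p`` is always recomputed from the counts (never trusted from input) so
    the ``n_gfp <= n_total`` invariant stays enforceable.  Boundary-undefined
    CI / log CI values are NaN.  Rows with ``n_total = 0`` get NaN for all
    three estimators.
    """
    n_total = obs["n_total"].to_numpy(dtype=float)
    n_gfp = obs["n_gfp"].to_numpy(dtype=float)
    if np.any(n_gfp > n_total):
        bad = obs.index[n_gfp > n_total].tolist()
        raise ValueError(f"n_gfp > n_total at rows {bad}")
    if np.any((n_total < 0) | (n_gfp < 0)):
        raise ValueError("negative counts in observation table")

    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_total > 0, (n_total - n_gfp) / n_total, np.nan)
        ci = np.where(p < 1.0, p / (1.0 - p), np.nan)
        log_ci = np.where((p > 0.0) & (p < 1.0), np.log(p / (1.0 - p)), np.nan)
    if log_base is not None:
        log_ci = log_ci / np.log(log_base)

    out = obs.copy()
    out["p"] = p
    out["ci"] = ci
    out["log_ci"] = log_ci
    return out
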