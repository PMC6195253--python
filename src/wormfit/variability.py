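"""Within-block variability statistics and mean-variance diagnostics.

The assay design is blocked: each block is an independent temporal replicate
of all focal strain x competitor strain x method combinations.  Variability
of a fitness estimator is summarised *within* each block-group (one focal x
competitor x method cell in one block) by two measures:

* the sample standard deviation (SD, n-1 denominator);
* the Median-Levene statistic ``Md = mean(|x - median(x)|)``, a robust
  dispersion measure.

Because dispersion measures are often correlated with the mean — which
confounds comparisons of variability between groups whose means differ —
the mean-variance diagnostics below quantify that coupling for each of the
three estimators (p, CI, log CI) so that the least mean-coupled scale can be
chosen for the method comparison.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "median_levene",
    "group_summaries",
    "combination_means",
    "mean_variance_diagnostics",
    "binomial_se",
    "se_ratio",
    "variance_decomposition",
    "METRICS",
    "GROUP_KEY",
]

METRICS = ("p", "ci", "log_ci")
GROUP_KEY = ["focal_strain", "competitor_strain", "method", "block_id"]


def median_levene(values) -> float:
    """Median-Levene statistic: mean absolute deviation from the sample median.

    The median of an even-length sample is the midpoint of the two central
    order statistics.  Zero iff all values equal the median.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_levene requires at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("median_levene requires finite values")
    return float(np.mean(np.abs(x - np.median(x))))


def group_summaries(obs: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Per block-group summaries (mean, median, SD, Md) of one estimator.

    ``obs`` must carry the estimator columns (see
    :func:`wormfit.metrics.add_fitness_columns`).  Boundary-undefined values
    (NaN for ``ci`` at p=1 and ``log_ci`` at p in {0,1}) are excluded and
    counted in ``n_excluded_boundary``.  SD uses the n-1 denominator and is
    NaN (flagged via ``sd_defined``) for groups with fewer than two defined
    values.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric not in obs.columns:
        raise ValueError(
            f"column {metric!r} missing; run metrics.add_fitness_columns first"
        )

    rows = []
    for key, grp in obs.groupby(GROUP_KEY, sort=True, observed=True):
        vals = grp[metric].to_numpy(dtype=float)
        defined = vals[np.isfinite(vals)]
        n_obs = defined.size
        n_excl = vals.size - n_obs
        rec = dict(zip(GROUP_KEY, key))
        rec.update(
            metric=metric,
            n_obs=n_obs,
            n_excluded_boundary=n_excl,
            mean=float(np.mean(defined)) if n_obs else math.nan,
            median=float(np.median(defined)) if n_obs else math.nan,
            sd=float(np.std(defined, ddof=1)) if n_obs >= 2 else math.nan,
            sd_defined=n_obs >= 2,
            md=median_levene(defined) if n_obs else math.nan,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def combination_means(summaries: pd.DataFrame) -> pd.DataFrame:
    """Average block-group summaries over blocks.

    One row per focal x competitor x method combination: the block-level
    mean/SD/Md averaged across blocks, i.e. the "mean within-block" statistic
    with each data point the average of a block x combination cell.
    """
    key = ["focal_strain", "competitor_strain", "method"]
    agg = (
        summaries.groupby(key, sort=True, observed=True)
        .agg(
            n_blocks=("block_id", "nunique"),
            mean=("mean", "mean"),
            sd=("sd", "mean"),
            md=("md", "mean"),
            n_excluded_boundary=("n_excluded_boundary", "sum"),
        )
        .reset_index()
    )
    if "metric" in summaries.columns and len(summaries):
        agg["metric"] = summaries["metric"].iloc[0]
    return agg


def mean_variance_diagnostics(
    summaries_by_metric: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Pearson correlation of group mean vs. group SD and group mean vs. Md.

    Takes the per-metric block-group summary tables (all block-groups pooled
    across methods) and returns a 3 metrics x 2 dispersion-measures
    correlation table plus, per metric, the (mean, sd, md) scatter data
    behind each correlation.

    A dispersion scale whose |r| is near zero is the safest scale on which to
    compare variability between groups with unequal means.
    """
    corr_rows = []
    scatter: dict[str, pd.DataFrame] = {}
    for metric, summ in summaries_by_metric.items():
        pts = summ.loc[
            np.isfinite(summ["mean"]) & np.isfinite(summ["sd"]) & np.isfinite(summ["md"]),
            ["mean", "sd", "md"],
        ].reset_index(drop=True)
        if len(pts) < 3:
            raise ValueError(
                f"metric {metric!r}: need >=3 groups with defined mean/SD/Md, "
                f"got {len(pts)}"
            )
        scatter[metric] = pts
        r_sd = float(np.corrcoef(pts["mean"], pts["sd"])[0, 1])
        r_md = float(np.corrcoef(pts["mean"], pts["md"])[0, 1])
        corr_rows.append(
            {"metric": metric, "r_mean_sd": r_sd, "r_mean_md": r_md, "n_groups": len(pts)}
        )
    return pd.DataFrame(corr_rows), scatter


def binomial_se(p: float, n: int) -> float:
    """Binomial sampling standard error of a proportion: sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("binomial_se requires n >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    return math.sqrt(p * (1.0 - p) / n)


def se_ratio(n_small: int, n_large: int) -> float:
    """Ratio of binomial SEs for two sample sizes at equal p: sqrt(n_large/n_small)."""
    if n_small < 1 or n_large < 1:
        raise ValueError("se_ratio requires both counts >= 1")
    return math.sqrt(n_large / n_small)


def variance_decomposition(obs: pd.DataFrame) -> dict[str, float]:
    """Split the among-plate variance of p into technical and biological parts.

    For one group of replicate plates, the observed among-plate variance of p
    is (approximately) the biological variance of the true focal frequency
    plus the mean binomial counting variance.  Moment estimates:

    * ``technical`` — mean over plates of ``p(1-p)/n_total``;
    * ``biological_raw`` — among-plate sample variance of p minus technical;
    * ``biological`` — the same, floored at zero.

    The ratio ``biological / technical`` tells whether counting more worms
    per plate (smaller technical variance) or more plates (averaging over
    biological variance) buys more precision.
    """
    sub = obs.loc[obs["n_total"] > 0]
    p = ((sub["n_total"] - sub["n_gfp"]) / sub["n_total"]).to_numpy(dtype=float)
    n = sub["n_total"].to_numpy(dtype=float)
    if p.size < 3:
        raise ValueError("variance_decomposition requires >=3 plates with counts")
    technical = float(np.mean(p * (1.0 - p) / n))
    total = float(np.var(p, ddof=1))
    bio_raw = total - technical
    bio = max(0.0, bio_raw)
    return {
        "n_plates": int(p.size),
        "total_variance": total,
        "technical_variance": technical,
        "biological_variance": bio,
        "biological_variance_raw": bio_raw,
        "ratio_bio_to_technical": bio / technical if technical > 0 else math.inf,
    }
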