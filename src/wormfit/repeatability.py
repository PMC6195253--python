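"""Technical repeatability analyses.

Two kinds of repeatability are quantified:

* **Re-count repeatability** (image-based methods): the same well image is
  counted twice — by the same person a month apart, or by the same software
  on different machines — and the two passes compared.  Any disagreement is
  pure counting error; there is no sampling involved.
* **Split-sample repeatability** (worm sorter): sorter samples are ephemeral,
  so repeatability is assessed by splitting one well's worm suspension into a
  ~1/4-volume and a ~3/4-volume aliquot and counting each.  Disagreement here
  includes genuine binomial sampling variance of p on top of counting error,
  with per-aliquot SEs scaling as sqrt(p(1-p)/n).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .variability import se_ratio

__all__ = [
    "RECOUNT_COLUMNS",
    "SPLIT_COLUMNS",
    "recount_analysis",
    "split_sample_filter",
    "split_sample_analysis",
]

RECOUNT_COLUMNS = ["image_id", "n_total_1", "n_gfp_1", "n_total_2", "n_gfp_2"]
SPLIT_COLUMNS = [
    "well_id",
    "n_total_small",
    "n_gfp_small",
    "n_total_large",
    "n_gfp_large",
]


def _validate_counts(df: pd.DataFrame, total_col: str, gfp_col: str) -> None:
    if (df[gfp_col] > df[total_col]).any():
        bad = df.index[df[gfp_col] > df[total_col]].tolist()
        raise ValueError(f"{gfp_col} > {total_col} at rows {bad}")
    if (df[total_col] < 0).any() or (df[gfp_col] < 0).any():
        raise ValueError("negative counts")


def recount_analysis(records: pd.DataFrame) -> dict:
    """Agreement between two independent counting passes over the same images.

    Returns Pearson correlations between passes for the total count, the GFP
    count and p, and the mean absolute difference between the two counts
    expressed as a fraction of their average (in percent) for total and GFP
    counts.  Records where both passes counted zero total worms carry no
    information and are excluded (and reported).
    """
    for tc, gc in (("n_total_1", "n_gfp_1"), ("n_total_2", "n_gfp_2")):
        _validate_counts(records, tc, gc)

    both_zero = (records["n_total_1"] == 0) & (records["n_total_2"] == 0)
    rec = records.loc[~both_zero]
    if len(rec) < 3:
        raise ValueError("recount_analysis requires >=3 usable records")

    t1 = rec["n_total_1"].to_numpy(dtype=float)
    t2 = rec["n_total_2"].to_numpy(dtype=float)
    g1 = rec["n_gfp_1"].to_numpy(dtype=float)
    g2 = rec["n_gfp_2"].to_numpy(dtype=float)
    p1 = np.where(t1 > 0, (t1 - g1) / t1, np.nan)
    p2 = np.where(t2 > 0, (t2 - g2) / t2, np.nan)

    def _corr(a, b):
        m = np.isfinite(a) & np.isfinite(b)
        if np.std(a[m]) == 0 and np.std(b[m]) == 0:
            return 1.0  # both passes constant and equal-length: perfect agreement
        return float(np.corrcoef(a[m], b[m])[0, 1])

    def _mean_abs_rel_pct(a, b):
        avg = (a + b) / 2.0
        m = avg > 0
        return float(np.mean(np.abs(a[m] - b[m]) / avg[m]) * 100.0)

    return {
        "n_records": int(len(rec)),
        "n_excluded_zero": int(both_zero.sum()),
        "corr_total": _corr(t1, t2),
        "corr_gfp": _corr(g1, g2),
        "corr_p": _corr(p1, p2),
        "mean_abs_rel_diff_total_pct": _mean_abs_rel_pct(t1, t2),
        "mean_abs_rel_diff_gfp_pct": _mean_abs_rel_pct(g1, g2),
        "exact_match_fraction": float(
            np.mean((t1 == t2) & (g1 == g2))
        ),
    }


def split_sample_filter(
    records: pd.DataFrame,
    min_n: int = 10,
    p_lo: float = 0.01,
    p_hi: float = 0.99,
) -> tuple[pd.DataFrame, dict]:
    """Quality filter for split-sample wells.

    A well is kept iff **both** aliquots have ``n_total > min_n`` (strictly)
    and focal frequency strictly inside ``(p_lo, p_hi)``.  Wells at the
    boundaries carry little information about repeatability of p (counts too
    small, or p pinned near 0/1 where the odds are degenerate).

    Returns the kept records and a report with per-criterion drop counts
    (a well failing several criteria is counted under each).
    """
    for tc, gc in (("n_total_small", "n_gfp_small"), ("n_total_large", "n_gfp_large")):
        _validate_counts(records, tc, gc)

    def _p(total, gfp):
        t = records[total].to_numpy(dtype=float)
        g = records[gfp].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(t > 0, (t - g) / t, np.nan)

    p_small = _p("n_total_small", "n_gfp_small")
    p_large = _p("n_total_large", "n_gfp_large")

    ok_n = (records["n_total_small"] > min_n) & (records["n_total_large"] > min_n)
    with np.errstate(invalid="ignore"):
        ok_p = (
            (p_small > p_lo) & (p_small < p_hi) & (p_large > p_lo) & (p_large < p_hi)
        )
    ok_p = pd.Series(np.where(np.isfinite(p_small) & np.isfinite(p_large), ok_p, False),
                     index=records.index)
    keep = ok_n & ok_p
    kept = records.loc[keep].copy()
    report = {
        "n_input": int(len(records)),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "n_dropped_small_n": int((~ok_n).sum()),
        "n_dropped_boundary_p": int((~ok_p).sum()),
        "min_n": min_n,
        "p_lo": p_lo,
        "p_hi": p_hi,
    }
    return kept, report


def split_sample_analysis(kept: pd.DataFrame) -> dict:
    """Repeatability statistics over filtered split-sample wells.

    Reports, between the small (~1/4 volume) and large (~3/4) aliquots:

    * mean |p_small - p_large|, both in percentage points of p (headline, as
      p is itself a proportion) and as a relative % of the aliquot average;
    * the Pearson correlation of p across aliquots;
    * per-aliquot means and standard errors (SD/sqrt(n)) of p and of log CI
      (boundary-undefined log CI values excluded and counted);
    * the expected ratio of binomial SEs implied by the mean aliquot sizes,
      ``sqrt(n_large_bar / n_small_bar)``.
    """
    if len(kept) < 3:
        raise ValueError("split_sample_analysis requires >=3 kept records")

    ts = kept["n_total_small"].to_numpy(dtype=float)
    gs = kept["n_gfp_small"].to_numpy(dtype=float)
    tl = kept["n_total_large"].to_numpy(dtype=float)
    gl = kept["n_gfp_large"].to_numpy(dtype=float)
    p_s = (ts - gs) / ts
    p_l = (tl - gl) / tl

    def _mean_se(x):
        x = x[np.isfinite(x)]
        return float(np.mean(x)), float(np.std(x, ddof=1) / math.sqrt(x.size)), x.size

    with np.errstate(divide="ignore", invalid="ignore"):
        lci_s = np.where((p_s > 0) & (p_s < 1), np.log(p_s / (1 - p_s)), np.nan)
        lci_l = np.where((p_l > 0) & (p_l < 1), np.log(p_l / (1 - p_l)), np.nan)

    mean_p_s, se_p_s, _ = _mean_se(p_s)
    mean_p_l, se_p_l, _ = _mean_se(p_l)
    mean_l_s, se_l_s, n_l_s = _mean_se(lci_s)
    mean_l_l, se_l_l, n_l_l = _mean_se(lci_l)

    avg_p = (p_s + p_l) / 2.0
    return {
        "n_wells": int(len(kept)),
        "mean_abs_dp_pct_points": float(np.mean(np.abs(p_s - p_l)) * 100.0),
        "mean_abs_dp_relative_pct": float(
            np.mean(np.abs(p_s - p_l)[avg_p > 0] / avg_p[avg_p > 0]) * 100.0
        ),
        "corr_p": float(np.corrcoef(p_s, p_l)[0, 1]),
        "mean_n_small": float(np.mean(ts)),
        "mean_n_large": float(np.mean(tl)),
        "mean_p_small": mean_p_s,
        "se_p_small": se_p_s,
        "mean_p_large": mean_p_l,
        "se_p_large": se_p_l,
        "mean_log_ci_small": mean_l_s,
        "se_log_ci_small": se_l_s,
        "mean_log_ci_large": mean_l_l,
        "se_log_ci_large": se_l_l,
        "n_log_ci_excluded_small": int(len(kept) - n_l_s),
        "n_log_ci_excluded_large": int(len(kept) - n_l_l),
        "expected_se_ratio": se_ratio(
            max(1, int(round(float(np.mean(ts))))),
            max(1, int(round(float(np.mean(tl))))),
        ),
    }
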