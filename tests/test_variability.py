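import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormfit.metrics import add_fitness_columns
from wormfit.variability import (
    binomial_se,
    group_summaries,
    mean_variance_diagnostics,
    median_levene,
    se_ratio,
    variance_decomposition,
)


def brute_force_md(values):
    """Independent oracle: mean |x - median| by a naive loop."""
    xs = sorted(values)
    n = len(xs)
    med = xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2.0
    return sum(abs(x - med) for x in values) / n


@pytest.mark.parametrize(
    "values, expected",
    [([2, 2, 2], 0.0), ([1, 2, 3], 2.0 / 3.0), ([1, 2, 3, 10], 2.5)],
)
def test_median_levene_values(values, expected):
    assert median_levene(values) == pytest.approx(expected, abs=1e-12)


def test_median_levene_rejects_bad_input():
    with pytest.raises(ValueError):
        median_levene([])
    with pytest.raises(ValueError):
        median_levene([1.0, math.nan])


def test_median_levene_matches_brute_force_oracle(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        x = rng.normal(0, 10, size=n).round(3)
        assert median_levene(x) == pytest.approx(brute_force_md(list(x)), abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(
    xs=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
    shift=st.floats(-1e3, 1e3),
)
def test_dispersion_statistics_location_invariant(xs, shift):
    x = np.asarray(xs)
    assert median_levene(x + shift) == pytest.approx(median_levene(x), abs=1e-7)
    assert np.std(x + shift, ddof=1) == pytest.approx(np.std(x, ddof=1), abs=1e-7)


def _obs(ps, n=1000, method="by_eye"):
    return pd.DataFrame(
        {
            "block_id": "B1",
            "focal_strain": "N2",
            "competitor_strain": "ST2",
            "method": method,
            "replicate_id": [f"r{i}" for i in range(len(ps))],
            "n_total": n,
            "n_gfp": [int(round(n * (1 - p))) for p in ps],
        }
    )


def test_group_summaries_formulas():
    est = add_fitness_columns(_obs([0.4, 0.5, 0.6], n=1000))
    row = group_summaries(est, "p").iloc[0]
    assert row["mean"] == pytest.approx(0.5)
    assert row["median"] == pytest.approx(0.5)
    assert row["sd"] == pytest.approx(0.1)
    assert row["md"] == pytest.approx(0.2 / 3.0, abs=1e-9)
    assert row["n_excluded_boundary"] == 0


def test_group_summaries_constant_group_and_boundary_exclusion():
    est = add_fitness_columns(_obs([0.5, 0.5, 0.5]))
    row = group_summaries(est, "p").iloc[0]
    assert row["sd"] == 0.0 and row["md"] == 0.0

    est = add_fitness_columns(_obs([0.4, 1.0, 0.6]))
    row = group_summaries(est, "log_ci").iloc[0]
    assert row["n_excluded_boundary"] == 1
    assert row["n_obs"] == 2


def test_group_summaries_unknown_metric():
    est = add_fitness_columns(_obs([0.4, 0.5]))
    with pytest.raises(ValueError, match="unknown metric"):
        group_summaries(est, "odds")


def _summary_frame(means, sds, mds):
    return pd.DataFrame({"mean": means, "sd": sds, "md": mds})


def test_mean_variance_diagnostics_exact_linear_and_null(rng):
    means = np.linspace(0.2, 0.9, 12)
    perfect = {
        m: _summary_frame(means, 0.1 + 0.5 * means, 0.05 + 0.2 * means)
        for m in ("p", "ci", "log_ci")
    }
    corr, scatter = mean_variance_diagnostics(perfect)
    assert np.allclose(corr["r_mean_sd"], 1.0)
    assert np.allclose(corr["r_mean_md"], 1.0)
    assert set(scatter) == {"p", "ci", "log_ci"}

    n_groups = 400
    means = rng.uniform(0.2, 0.9, n_groups)
    null = {
        m: _summary_frame(means, rng.normal(0.3, 0.02, n_groups),
                          rng.normal(0.2, 0.02, n_groups))
        for m in ("p", "ci", "log_ci")
    }
    corr, _ = mean_variance_diagnostics(null)
    assert (corr["r_mean_sd"].abs() < 3.0 / math.sqrt(n_groups)).all()


def test_mean_variance_diagnostics_needs_three_groups():
    two = {m: _summary_frame([0.1, 0.2], [0.1, 0.2], [0.1, 0.2])
           for m in ("p", "ci", "log_ci")}
    with pytest.raises(ValueError, match=">=3 groups"):
        mean_variance_diagnostics(two)


@pytest.mark.parametrize(
    "p, n, expected",
    [(0.5, 100, 0.05), (0.0, 50, 0.0), (0.553, 143, 0.04158)],
)
def test_binomial_se_values(p, n, expected):
    assert binomial_se(p, n) == pytest.approx(expected, abs=1e-4)


def test_se_ratio_values_and_reciprocal_property():
    assert se_ratio(143, 551) == pytest.approx(1.963, abs=1e-3)
    assert se_ratio(100, 100) == 1.0
    assert se_ratio(1, 4) == 2.0
    assert se_ratio(37, 91) * se_ratio(91, 37) == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        se_ratio(0, 10)
    with pytest.raises(ValueError):
        binomial_se(0.5, 0)


def test_variance_decomposition_degenerate_identical_plates():
    out = variance_decomposition(_obs([0.5] * 10, n=100_000))
    assert out["biological_variance"] == pytest.approx(0.0, abs=1e-6)
    assert out["total_variance"] == pytest.approx(0.0, abs=1e-8)


def test_variance_decomposition_recovers_known_biological_variance(rng):
    """200 groups of 24 plates with known sigma^2_bio on the p scale."""
    sigma2_bio, n_worms, n_plates, n_groups = 0.004, 500, 24, 200
    ests = []
    for _ in range(n_groups):
        p_true = np.clip(rng.normal(0.55, math.sqrt(sigma2_bio), n_plates), 0.01, 0.99)
        n_gfp = n_worms - rng.binomial(n_worms, p_true)
        out = variance_decomposition(_obs(1 - n_gfp / n_worms, n=n_worms))
        ests.append(out["biological_variance_raw"])
    ests = np.asarray(ests)
    se = ests.std(ddof=1) / math.sqrt(n_groups)
    assert abs(ests.mean() - sigma2_bio) < 3 * se


def test_variance_decomposition_null_biology_rarely_dominates(rng):
    """With sigma^2_bio = 0, the bio/technical ratio stays small."""
    n_worms, n_plates, n_sims = 500, 24, 200
    below = 0
    for _ in range(n_sims):
        n_gfp = n_worms - rng.binomial(n_worms, 0.55, size=n_plates)
        out = variance_decomposition(_obs(1 - n_gfp / n_worms, n=n_worms))
        below += out["ratio_bio_to_technical"] < 0.5
    assert below >= 0.90 * n_sims


def test_variance_decomposition_needs_three_plates():
    with pytest.raises(ValueError):
        variance_decomposition(_obs([0.5, 0.6]))
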