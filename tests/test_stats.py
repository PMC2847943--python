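"""Correlation, paired tests, Fisher's Z, MAD, and the threshold sweep."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

from osteoct import (
    fisher_z_compare,
    mad_pair,
    paired_t,
    pearson_with_regression,
    sweep_optimal_threshold,
)


# ---------------------------------------------------------------------------
# Pearson / regression
# ---------------------------------------------------------------------------


def test_exact_line_recovers_slope_and_intercept():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    c = pearson_with_regression(x, 2 * x + 1)
    assert c.r == pytest.approx(1.0)
    assert c.slope == pytest.approx(2.0)
    assert c.intercept == pytest.approx(1.0)


def test_r_matches_hand_computed_covariance():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    c = pearson_with_regression(x, y)
    expected = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert c.r == pytest.approx(expected, abs=1e-12)


def test_pearson_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        pearson_with_regression([1, 2], [3, 4])
    with pytest.raises(ValueError, match="variance"):
        pearson_with_regression([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="finite"):
        pearson_with_regression([1, 2, np.nan, 4], [1, 2, 3, 4])


def test_pearson_p_calibrated_against_exhaustive_permutations(rng):
    """At n=5 the exact permutation p of |r| and the analytic t-based p agree
    for interior p values, and the permutation distribution is the uniform
    reference the analytic p approximates."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    for _ in range(5):
        y = rng.normal(size=5)
        r_obs = pearson_with_regression(x, y).r
        rs = np.array([pearson_with_regression(x, np.array(p)).r
                       for p in itertools.permutations(y)])
        p_perm = np.mean(np.abs(rs) >= abs(r_obs) - 1e-12)
        p_t = pearson_with_regression(x, y).p
        assert abs(p_perm - p_t) < 0.15
    # a perfectly ordered y is the most extreme of all 120 permutations
    rs = np.array([pearson_with_regression(x, np.array(p)).r
                   for p in itertools.permutations(x)])
    assert np.mean(np.abs(rs) >= 1.0 - 1e-12) == pytest.approx(2 / 120)


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------


def test_paired_t_matches_direct_formula():
    left = np.array([10.0, 12.0, 9.0, 14.0])
    right = left + np.array([1.0, 2.0, 3.0, 2.0])
    res = paired_t(left, right)
    d = right - left
    t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.t == pytest.approx(t_direct, abs=1e-12)
    assert res.p == pytest.approx(2 * sps.t.sf(abs(t_direct), len(d) - 1), abs=1e-12)
    assert res.mean_left == pytest.approx(left.mean())


def test_paired_t_rejects_zero_variance_differences():
    with pytest.raises(ValueError, match="variance"):
        paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


def test_paired_t_type_one_error_calibrated(rng):
    n, reps = 8, 10_000
    left = rng.normal(size=(reps, n))
    right = rng.normal(size=(reps, n))
    t, p = sps.ttest_rel(right, left, axis=1)
    # cross-check a handful of rows against our implementation
    for i in range(5):
        res = paired_t(left[i], right[i])
        assert res.p == pytest.approx(p[i], abs=1e-12)
    rate = float(np.mean(p < 0.05))
    assert 0.04 <= rate <= 0.06


# ---------------------------------------------------------------------------
# Fisher's Z
# ---------------------------------------------------------------------------


def test_fisher_z_closed_form_and_antisymmetry():
    res = fisher_z_compare(0.9, 20, 0.5, 20)
    Z_direct = (np.arctanh(0.9) - np.arctanh(0.5)) / np.sqrt(1 / 17 + 1 / 17)
    assert res.Z == pytest.approx(Z_direct, abs=1e-12)
    assert res.p == pytest.approx(2 * sps.norm.sf(abs(Z_direct)), abs=1e-12)
    swapped = fisher_z_compare(0.5, 20, 0.9, 20)
    assert swapped.Z == pytest.approx(-res.Z)
    assert swapped.p == pytest.approx(res.p)


@settings(max_examples=50, derandomize=True)
@given(r1=st_.floats(-0.99, 0.99), r2=st_.floats(-0.99, 0.99),
       n1=st_.integers(4, 500), n2=st_.integers(4, 500))
def test_fisher_z_antisymmetric_for_any_inputs(r1, r2, n1, n2):
    a = fisher_z_compare(r1, n1, r2, n2)
    b = fisher_z_compare(r2, n2, r1, n1)
    assert a.Z == pytest.approx(-b.Z, abs=1e-12)
    assert a.p == pytest.approx(b.p, abs=1e-12)
    assert 0.0 < a.p <= 1.0


def test_fisher_z_identity_and_guards():
    res = fisher_z_compare(0.7, 15, 0.7, 30)
    assert res.Z == 0.0 and res.p == pytest.approx(1.0)
    with pytest.raises(ValueError, match="infinite"):
        fisher_z_compare(1.0, 20, 0.5, 20)
    with pytest.raises(ValueError, match="n > 3"):
        fisher_z_compare(0.5, 3, 0.5, 20)


# ---------------------------------------------------------------------------
# MAD
# ---------------------------------------------------------------------------


def test_mad_pair(rng):
    assert mad_pair([1.0, 2.0], [1.0, 2.0]).mad == 0.0
    res = mad_pair([0.0, 0.0], [1.0, -1.0])
    assert res.mad == 1.0 and res.sd == 0.0
    left, right = rng.normal(size=30), rng.normal(size=30)
    res = mad_pair(left, right)
    assert res.mad == pytest.approx(np.abs(right - left).mean())
    assert res.sd == pytest.approx(np.abs(right - left).std(ddof=1))


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def synthetic_study(rng, grid, t_star, n_animals=11, noise=0.05,
                    measurement_cv=0.10,
                    curve=lambda t: 1.0 / (1.0 + t / 1000.0)):
    """Long-format study table where a parameter falls off with threshold and
    the reference is the measurement at t_star plus noise.

    Each (specimen, threshold) cell carries independent measurement error, so
    the reference shares idiosyncratic error only with the t_star column --
    which is what makes the generating threshold identifiable.
    """
    rows = []
    for animal in range(n_animals):
        for side in ("left", "right"):
            level = rng.uniform(1.0, 3.0)
            for t in grid:
                v = level * curve(t) * (1 + rng.normal(0, measurement_cv))
                rows.append(dict(animal=animal, side=side, site="metaphysis",
                                 modality="ct", threshold_method="fixed", threshold=t,
                                 parameter="TbN", value=v, units="/mm"))
            auto_t = float(rng.choice(grid))
            rows.append(dict(animal=animal, side=side, site="metaphysis",
                             modality="ct", threshold_method="auto_otsu", threshold=auto_t,
                             parameter="TbN", value=level * curve(auto_t), units="/mm"))
    df = pd.DataFrame(rows)
    ref = df[(df.threshold_method == "fixed") & (df.threshold == t_star)].copy()
    ref["modality"] = "histo"
    ref["threshold_method"] = "histo"
    ref["value"] = ref["value"] * (1 + rng.normal(0, noise, len(ref)))
    return pd.concat([df, ref], ignore_index=True)


def test_sweep_recovers_generating_threshold(rng):
    grid = [200.0, 400.0, 600.0, 800.0, 1000.0]
    hits = 0
    for rep in range(30):
        df = synthetic_study(rng, grid, t_star=600.0)
        sw = sweep_optimal_threshold(df, "TbN", "ct", grid=grid)
        if abs(sw.optimal_threshold - 600.0) <= 200.0:
            hits += 1
    assert hits >= 28


def test_sweep_single_threshold_grid(rng):
    grid = [500.0]
    df = synthetic_study(rng, grid, t_star=500.0)
    sw = sweep_optimal_threshold(df, "TbN", "ct", grid=grid)
    assert sw.optimal_threshold == 500.0
    assert "500" in sw.summary()


def test_sweep_rejects_constant_reference(rng):
    grid = [200.0, 400.0]
    df = synthetic_study(rng, grid, t_star=200.0, noise=0.0)
    df.loc[df.modality == "histo", "value"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        sweep_optimal_threshold(df, "TbN", "ct", grid=grid)


def test_sweep_rejects_missing_cells(rng):
    grid = [200.0, 400.0]
    df = synthetic_study(rng, grid, t_star=200.0)
    df = df[~((df.threshold == 400.0) & (df.animal == 3))]
    with pytest.raises(ValueError, match="missing"):
        sweep_optimal_threshold(df, "TbN", "ct", grid=grid)


def test_sweep_ties_break_to_lowest_threshold(rng):
    grid = [200.0, 400.0]
    rows = []
    for animal in range(6):
        for side in ("left", "right"):
            level = rng.uniform(1, 2)
            for t in grid:
                rows.append(dict(animal=animal, side=side, site="metaphysis",
                                 modality="ct", threshold_method="fixed", threshold=t,
                                 parameter="TbN", value=level, units="/mm"))
            rows.append(dict(animal=animal, side=side, site="metaphysis",
                             modality="histo", threshold_method="histo", threshold=np.nan,
                             parameter="TbN", value=level + rng.normal(0, 0.01), units="/mm"))
    sw = sweep_optimal_threshold(pd.DataFrame(rows), "TbN", "ct", grid=grid)
    assert sw.optimal_threshold == 200.0  # identical r at both -> lowest wins
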