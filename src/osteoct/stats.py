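"""Study-level statistics: correlation, paired tests, Fisher's Z, MAD, and
the fixed-optimal-threshold sweep against the histomorphometry reference.

The optimal threshold for a parameter/modality is the grid threshold whose
cross-specimen Pearson correlation with the reference modality is maximal
(ties broken toward the lowest, more inclusive threshold).  Both femora of
each animal enter as separate observations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

STUDY_COLUMNS = ["animal", "side", "site", "modality", "threshold_method",
                 "threshold", "parameter", "value", "units"]


@dataclass
class CorrStat:
    r: float
    p: float
    n: int
    slope: float
    intercept: float


@dataclass
class PairedTestResult:
    mean_left: float
    mean_right: float
    t: float
    p: float
    n: int


@dataclass
class FisherZResult:
    z1: float
    z2: float
    Z: float
    p: float


@dataclass
class MadResult:
    mad: float
    sd: float
    units: str = ""


@dataclass
class SweepResult:
    """Correlation-vs-threshold curve and the selected optimal threshold."""

    parameter: str
    modality: str
    grid: list[float]
    r_per_threshold: list[float]
    optimal_threshold: float
    r_at_optimal: float
    r_at_automatic: float
    n: int

    def summary(self) -> str:
        lines = [f"Optimal-threshold sweep: {self.parameter} ({self.modality}), n={self.n}",
                 f"  optimal threshold: {self.optimal_threshold:g} HU  "
                 f"(r = {self.r_at_optimal:.3f}; automatic r = {self.r_at_automatic:.3f})",
                 "  threshold   r"]
        for t, r in zip(self.grid, self.r_per_threshold):
            flag = " <- optimal" if t == self.optimal_threshold else ""
            lines.append(f"  {t:9g}   {r:+.3f}{flag}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def pearson_with_regression(x, y) -> CorrStat:
    """Pearson r with OLS slope/intercept and the two-sided t-test p (df = n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.linregress(x, y)
    return CorrStat(r=float(res.rvalue), p=float(res.pvalue), n=int(x.size),
                    slope=float(res.slope), intercept=float(res.intercept))


def paired_t(values_left, values_right) -> PairedTestResult:
    """Two-sided paired Student's t-test on within-animal differences."""
    left = np.asarray(values_left, dtype=float)
    right = np.asarray(values_right, dtype=float)
    if left.size != right.size or left.size < 2:
        raise ValueError("paired test needs equal-length samples with n >= 2")
    d = right - left
    if np.ptp(d) == 0:
        raise ValueError("differences have zero variance; paired t undefined")
    t, p = sps.ttest_rel(right, left)
    return PairedTestResult(mean_left=float(left.mean()), mean_right=float(right.mean()),
                            t=float(t), p=float(p), n=int(left.size))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherZResult:
    """Independent-samples comparison of two correlations via Fisher's Z.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| = 1 has infinite Fisher z; comparison undefined")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher Z comparison needs n > 3 in both samples")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    Z = (z1 - z2) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(Z))
    return FisherZResult(z1=float(z1), z2=float(z2), Z=float(Z), p=float(p))


def mad_pair(values_left, values_right, units: str = "") -> MadResult:
    """Mean and SD of the absolute right-left differences."""
    left = np.asarray(values_left, dtype=float)
    right = np.asarray(values_right, dtype=float)
    if left.size == 0 or left.size != right.size:
        raise ValueError("need equal-length non-empty samples")
    d = np.abs(right - left)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return MadResult(mad=float(d.mean()), sd=sd, units=units)


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------


def _specimen_values(study: pd.DataFrame, **filters) -> pd.Series:
    df = study
    for col, val in filters.items():
        df = df[df[col] == val]
    if df.duplicated(subset=["animal", "side"]).any():
        raise ValueError(f"multiple rows per specimen for {filters}")
    return df.set_index(["animal", "side"])["value"]


def sweep_optimal_threshold(study: pd.DataFrame, parameter: str, modality: str,
                            grid: list[float], reference: str = "histo",
                            site: str = "metaphysis",
                            reference_parameter: str | None = None) -> SweepResult:
    """Correlation-vs-threshold curve of a uCT parameter against a reference.

    ``study`` is the long-format study table.  The reference for BMD is the
    reference modality's BV/TV (density has no histologic analogue).  Returns
    the r value at each grid threshold, the optimal (argmax, lowest on ties)
    threshold, and the correlation obtained with each specimen's automatic
    threshold for comparison.
    """
    if reference_parameter is None:
        reference_parameter = "BVTV" if parameter == "BMD" else parameter
    ref = _specimen_values(study, site=site, modality=reference,
                           parameter=reference_parameter)
    if ref.size and np.ptp(ref.values) == 0:
        raise ValueError("reference values are constant; correlation undefined")

    rs: list[float] = []
    missing: list[str] = []
    for t in grid:
        sub = study[(study["site"] == site) & (study["modality"] == modality)
                    & (study["parameter"] == parameter)
                    & (study["threshold_method"] == "fixed")
                    & (study["threshold"] == t)]
        vals = sub.set_index(["animal", "side"])["value"]
        aligned = pd.concat([vals, ref], axis=1, keys=["x", "ref"])
        if aligned.isna().any().any():
            missing.append(f"{parameter}@{t}")
            rs.append(np.nan)
            continue
        try:
            rs.append(pearson_with_regression(aligned["x"], aligned["ref"]).r)
        except ValueError:
            # degenerate threshold (e.g. constant zeros above the bone range)
            rs.append(np.nan)
    if missing:
        raise ValueError(f"missing study cells for {modality}/{site}: {missing}")

    rs_arr = np.asarray(rs)
    if np.isnan(rs_arr).all():
        raise ValueError(f"no informative threshold in the grid for {parameter}/{modality}")
    k = int(np.nanargmax(rs_arr))  # first (lowest-threshold) maximizer
    auto = study[(study["site"] == site) & (study["modality"] == modality)
                 & (study["parameter"] == parameter)
                 & (study["threshold_method"] == "auto_otsu")]
    if len(auto):
        vals = auto.set_index(["animal", "side"])["value"]
        aligned = pd.concat([vals, ref], axis=1, keys=["x", "ref"]).dropna()
        try:
            r_auto = pearson_with_regression(aligned["x"], aligned["ref"]).r
        except ValueError:
            r_auto = np.nan
    else:
        r_auto = np.nan
    return SweepResult(parameter=parameter, modality=modality, grid=list(grid),
                       r_per_threshold=rs, optimal_threshold=float(grid[k]),
                       r_at_optimal=float(rs_arr[k]), r_at_automatic=float(r_auto),
                       n=int(ref.size))
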