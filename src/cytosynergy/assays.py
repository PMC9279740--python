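"""Formulas for the validation assays: relative qPCR quantification (2^-ΔΔCt),
complement-dependent cytotoxicity, geometric mean fluorescence intensity, and
the mean ± SEM / Student's t summary statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


def _ct(values, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError(f"{name}: empty Ct input")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: non-finite Ct value")
    if ((arr <= 0) | (arr >= 45)).any():
        warnings.warn(f"{name}: Ct value outside the usual (0, 45) range",
                      stacklevel=3)
    return arr


def ddct_fold_change(
    ct_target_treated,
    ct_ref_treated,
    ct_target_control,
    ct_ref_control,
    mode: str = "mean",
):
    """Relative expression by the 2^-ΔΔCt method against a reference gene.

    ΔCt = Ct_target − Ct_ref within each group, ΔΔCt = ΔCt_treated −
    ΔCt_control, fold change = 2^−ΔΔCt. With ``mode="mean"`` replicate Ct
    values are averaged per group first (scalar result); ``mode="paired"``
    pairs replicates positionally and returns a per-replicate fold change.
    """
    groups = [
        _ct(ct_target_treated, "ct_target_treated"),
        _ct(ct_ref_treated, "ct_ref_treated"),
        _ct(ct_target_control, "ct_target_control"),
        _ct(ct_ref_control, "ct_ref_control"),
    ]
    if mode == "mean":
        tt, rt, tc, rc = (g.mean() for g in groups)
        return float(2.0 ** -((tt - rt) - (tc - rc)))
    if mode == "paired":
        if len({g.size for g in groups}) != 1:
            raise ValueError("paired mode requires equal replicate counts")
        tt, rt, tc, rc = groups
        return 2.0 ** -((tt - rt) - (tc - rc))
    raise ValueError(f"unknown mode: {mode!r}")


def cytotoxicity_percent(od_control: float, od_experimental: float,
                         clamp: bool = False) -> float:
    """Percent cytotoxicity from OD450 viability readings.

    100 × (OD_control − OD_experimental) / OD_control. The control group is
    the heat-inactivated-serum well. Negative values (experimental OD above
    control) are returned as-is unless ``clamp`` is set.
    """
    if not np.isfinite(od_control) or od_control <= 0:
        raise ValueError("control OD must be positive")
    if not np.isfinite(od_experimental) or od_experimental < 0:
        raise ValueError("experimental OD must be non-negative")
    pct = 100.0 * (od_control - od_experimental) / od_control
    return max(pct, 0.0) if clamp else pct


def geometric_mean_intensity(values) -> float:
    """Geometric mean of fluorescence intensities (all values must be > 0)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty intensity vector")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("intensities must be positive and finite")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean1: float
    sem1: float
    mean2: float
    sem2: float


def two_sample_t(group1, group2) -> TTestResult:
    """Two-tailed equal-variance Student's t-test with per-group mean ± SEM."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two observations")
    pooled_var = (
        (g1.size - 1) * g1.var(ddof=1) + (g2.size - 1) * g2.var(ddof=1)
    ) / (g1.size + g2.size - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: groups are degenerate")
    res = stats.ttest_ind(g1, g2, equal_var=True)
    return TTestResult(
        t=float(res.statistic),
        df=g1.size + g2.size - 2,
        p=float(res.pvalue),
        mean1=float(g1.mean()),
        sem1=float(g1.std(ddof=1) / np.sqrt(g1.size)),
        mean2=float(g2.mean()),
        sem2=float(g2.std(ddof=1) / np.sqrt(g2.size)),
    )
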