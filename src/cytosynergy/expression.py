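"""Normalization, log2 fold-change estimation, and Poisson-exact DE testing.

The differential-expression call follows the count-based rule used for the
four-condition stimulation design: an exact conditional Poisson test (pooled
replicate counts; conditionally binomial given the two-group total) with
Benjamini–Hochberg adjustment across genes, flagging genes with fold change
> 1.5 in either direction and adjusted p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONDITIONS, CountMatrix

LN2 = np.log(2.0)


def size_factors(matrix: CountMatrix, method: str = "median-of-ratios") -> pd.Series:
    """Per-sample normalization factors, scaled to geometric mean 1.

    ``total-count`` equalizes column sums; ``median-of-ratios`` is the DESeq
    estimator: the median across genes of each sample's ratio to the per-gene
    geometric-mean reference, computed over genes expressed in every sample.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(matrix.sample_ids[zero])
        raise ValueError(f"samples with all-zero counts: {bad}")

    if method == "total-count":
        factors = totals
    elif method == "median-of-ratios":
        expressed = (counts > 0).all(axis=1)
        if not expressed.any():
            raise ValueError("no gene has nonzero counts in every sample")
        sub = counts[expressed]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    else:
        raise ValueError(f"unknown normalization method: {method!r}")

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def _normalize_factors(matrix: CountMatrix, factors: pd.Series | None) -> pd.Series:
    if factors is None:
        factors = size_factors(matrix)
    factors = pd.Series(factors).reindex(matrix.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    # Rescaling to geometric mean 1 makes downstream estimates invariant to a
    # global rescaling of the supplied factors (the pseudocount would otherwise
    # break that invariance).
    return factors / np.exp(np.mean(np.log(factors)))


def _group_means(matrix: CountMatrix, factors: pd.Series, condition: str):
    samples = matrix.samples_for(condition)
    norm = matrix.counts[samples].to_numpy(dtype=float) / factors[samples].to_numpy()
    return norm.mean(axis=1), len(samples)


def estimate_effects(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    conditions: tuple[str, str, str, str] = CONDITIONS,
) -> pd.DataFrame:
    """Log2 fold change and delta-method standard error for the three contrasts.

    For each of A, B, and AB versus control,

        log2_fch = log2((mean_t + c) / (mean_c + c))
        se^2     = (1/ln2)^2 * (1/(n_t * mu_t) + 1/(n_c * mu_c))

    where the means are size-factor-normalized group means, ``c`` the
    pseudocount, and ``mu`` the pseudocounted means. The Poisson delta method
    treats each normalized group mean as an average of Poisson draws.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    matrix.require_conditions(conditions)
    factors = _normalize_factors(matrix, factors)
    ctrl = conditions[0]
    mu_c, n_c = _group_means(matrix, factors, ctrl)
    mu_c = mu_c + pseudocount

    rows = []
    for cond in conditions[1:]:
        mu_t, n_t = _group_means(matrix, factors, cond)
        mu_t = mu_t + pseudocount
        log2_fch = np.log2(mu_t / mu_c)
        se = np.sqrt(1.0 / (n_t * mu_t) + 1.0 / (n_c * mu_c)) / LN2
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": matrix.gene_ids,
                    "contrast": f"{cond}_vs_{ctrl}",
                    "log2_fch": log2_fch,
                    "se": se,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def exact_poisson_pvalues(k_t, k_c, exposure_t: float, exposure_c: float) -> np.ndarray:
    """Two-sided exact conditional Poisson p-values for pooled group counts.

    Given the total ``k_t + k_c``, the treatment count is binomial with
    success probability ``exposure_t / (exposure_t + exposure_c)`` under the
    null of equal normalized expression. The two-sided p doubles the smaller
    tail, capped at 1; an empty total yields p = 1.
    """
    if exposure_t <= 0 or exposure_c <= 0:
        raise ValueError("group exposures must be positive")
    k_t = np.asarray(k_t, dtype=np.int64)
    k_c = np.asarray(k_c, dtype=np.int64)
    total = k_t + k_c
    p0 = exposure_t / (exposure_t + exposure_c)
    lower = stats.binom.cdf(k_t, total, p0)
    upper = stats.binom.sf(k_t - 1, total, p0)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(total == 0, 1.0, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def poisson_de_test(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    condition: str = "AB",
    reference: str = "control",
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene exact Poisson DE test of ``condition`` versus ``reference``.

    Replicates are pooled (Poisson sums are Poisson); group exposures are the
    summed size factors. Fold change is the ratio of pseudocounted normalized
    group means; ``is_de`` requires fold change > ``fc_threshold`` in either
    direction and BH-adjusted p < ``alpha``.
    """
    factors = _normalize_factors(matrix, factors)
    t_samples = matrix.samples_for(condition)
    c_samples = matrix.samples_for(reference)

    k_t = matrix.counts[t_samples].sum(axis=1).to_numpy()
    k_c = matrix.counts[c_samples].sum(axis=1).to_numpy()
    p_raw = exact_poisson_pvalues(
        k_t, k_c, factors[t_samples].sum(), factors[c_samples].sum()
    )
    p_adj = bh_adjust(p_raw)

    mu_t, _ = _group_means(matrix, factors, condition)
    mu_c, _ = _group_means(matrix, factors, reference)
    fold_change = (mu_t + pseudocount) / (mu_c + pseudocount)
    log2_fch = np.log2(fold_change)
    passes_fc = np.maximum(fold_change, 1.0 / fold_change) > fc_threshold

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "contrast": f"{condition}_vs_{reference}",
            "log2_fch": log2_fch,
            "fold_change": fold_change,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_de": passes_fc & (p_adj < alpha),
        }
    ).reset_index(drop=True)


def de_all_contrasts(
    matrix: CountMatrix,
    factors: pd.Series | None = None,
    conditions: tuple[str, str, str, str] = CONDITIONS,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`poisson_de_test` for A, B, and AB against the control."""
    matrix.require_conditions(conditions)
    if factors is None:
        factors = size_factors(matrix)
    ctrl = conditions[0]
    return pd.concat(
        [
            poisson_de_test(matrix, factors, cond, ctrl, **kwargs)
            for cond in conditions[1:]
        ],
        ignore_index=True,
    )
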