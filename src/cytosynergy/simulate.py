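"""Synthetic factorial-design count data with known interaction structure.

Emulates a four-condition cytokine-stimulation experiment (control, cytokine A,
cytokine B, A+B combination) with replicate RNA-seq count columns per condition.
Each gene carries a known interaction category so that every downstream stage —
normalization, differential expression, and synergy classification — can be
validated against ground truth without any external data.

The expected count for gene *g* in a sample of condition *c* is

    sizefactor_s * 2 ** (b_g + x_g * [c in {A, AB}] + y_g * [c in {B, AB}]
                         + i_g * [c = AB])

where ``b_g`` is the baseline log2 expression, ``x_g``/``y_g`` are the single-
cytokine log2 fold changes, and ``i_g`` is the interaction term on the log2
scale. Counts are Poisson at dispersion 0 and gamma-Poisson (negative binomial
with size 1/dispersion) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CONDITIONS, CountMatrix

#: Ground-truth gene categories, in the fixed order used for quota assignment.
TRUTH_CATEGORIES: tuple[str, ...] = (
    "null",
    "single_only",
    "additive",
    "synergistic_pos",
    "synergistic_neg",
    "antagonistic",
)

DEFAULT_FRACTIONS: Mapping[str, float] = {
    "null": 0.40,
    "single_only": 0.15,
    "additive": 0.15,
    "synergistic_pos": 0.10,
    "synergistic_neg": 0.10,
    "antagonistic": 0.10,
}

#: Map from truth categories to the classifier's call vocabulary.
TRUTH_TO_CALL: Mapping[str, str] = {
    "synergistic_pos": "synergistic_positive",
    "synergistic_neg": "synergistic_negative",
    "additive": "additive",
    "antagonistic": "antagonistic_excluded",
}


@dataclass
class SimConfig:
    """Parameters of the factorial count simulator.

    ``main_effect_log2`` and ``interaction_log2`` are (low, high) magnitude
    ranges on the log2 scale; signs are set per category. ``dispersion`` is the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2);
    0 collapses to pure Poisson, matching the Poisson-based DE test downstream.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    conditions: tuple[str, str, str, str] = CONDITIONS
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    baseline_log2_min: float | None = None
    library_size_factors: Sequence[float] | None = None
    category_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    main_effect_log2: tuple[float, float] = (1.0, 2.0)
    interaction_log2: tuple[float, float] = (1.5, 2.5)
    antagonism_shrink: float = 0.6
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.conditions) != 4 or len(set(self.conditions)) != 4:
            raise ValueError("conditions must be four distinct labels")
        unknown = set(self.category_fractions) - set(TRUTH_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.category_fractions.values()):
            raise ValueError("category_fractions must be non-negative")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if len(sf) != self.n_samples:
                raise ValueError(
                    f"expected {self.n_samples} size factors, got {len(sf)}"
                )
            if (sf <= 0).any():
                raise ValueError("library size factors must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0 < self.antagonism_shrink < 1:
            raise ValueError("antagonism_shrink must be in (0, 1)")

    @property
    def n_samples(self) -> int:
        return 4 * self.n_replicates

    @classmethod
    def strong_effect(cls, n_genes: int = 1000, seed: int = 0, **kwargs) -> "SimConfig":
        """Default strong-effect scenario: well-expressed genes, large effects.

        Baselines are drawn from N(8, 1) on the log2 scale and truncated below
        at 6 (control means >= 64 counts), with interaction magnitudes of at
        least 1.5 log2 units, so that every non-null gene is comfortably above
        the detection floor of the fold-change > 1.5 eligibility gate.
        """
        return cls(
            n_genes=n_genes,
            baseline_log2_mean=8.0,
            baseline_log2_sd=1.0,
            baseline_log2_min=6.0,
            seed=seed,
            **kwargs,
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def category_quotas(fractions: Mapping[str, float], n_genes: int) -> dict[str, int]:
    """Deterministic per-category gene counts by largest-remainder rounding.

    Guarantees quotas sum exactly to ``n_genes``; ties in the fractional parts
    are broken by the fixed category order.
    """
    cats = [c for c in TRUTH_CATEGORIES if fractions.get(c, 0.0) > 0]
    raw = {c: fractions[c] * n_genes for c in cats}
    quotas = {c: math.floor(raw[c]) for c in cats}
    shortfall = n_genes - sum(quotas.values())
    by_remainder = sorted(
        cats, key=lambda c: (-(raw[c] - quotas[c]), TRUTH_CATEGORIES.index(c))
    )
    for c in by_remainder[:shortfall]:
        quotas[c] += 1
    return quotas


def _draw_magnitude(rng: np.random.Generator, lo_hi: tuple[float, float], n: int):
    lo, hi = lo_hi
    if lo > hi:
        raise ValueError(f"invalid effect range {lo_hi}")
    return rng.uniform(lo, hi, size=n)


def _draw_effects(config: SimConfig, categories: np.ndarray, rng: np.random.Generator):
    """Per-gene (x, y, interaction) log2 effects consistent with each category."""
    n = len(categories)
    x = np.zeros(n)
    y = np.zeros(n)
    inter = np.zeros(n)

    def mask(cat: str) -> np.ndarray:
        return categories == cat

    m = mask("single_only")
    if m.any():
        k = int(m.sum())
        mag = _draw_magnitude(rng, config.main_effect_log2, k)
        sign = rng.choice([-1.0, 1.0], size=k)
        which = rng.integers(0, 2, size=k)  # 0 -> x only, 1 -> y only
        x[m] = np.where(which == 0, sign * mag, 0.0)
        y[m] = np.where(which == 1, sign * mag, 0.0)

    m = mask("additive")
    if m.any():
        k = int(m.sum())
        sign = rng.choice([-1.0, 1.0], size=k)
        x[m] = sign * _draw_magnitude(rng, config.main_effect_log2, k)
        y[m] = sign * _draw_magnitude(rng, config.main_effect_log2, k)

    for cat, s in (("synergistic_pos", 1.0), ("synergistic_neg", -1.0)):
        m = mask(cat)
        if m.any():
            k = int(m.sum())
            x[m] = s * _draw_magnitude(rng, config.main_effect_log2, k)
            y[m] = s * _draw_magnitude(rng, config.main_effect_log2, k)
            inter[m] = s * _draw_magnitude(rng, config.interaction_log2, k)

    m = mask("antagonistic")
    if m.any():
        k = int(m.sum())
        sign = rng.choice([-1.0, 1.0], size=k)
        ax = sign * _draw_magnitude(rng, config.main_effect_log2, k)
        ay = sign * _draw_magnitude(rng, config.main_effect_log2, k)
        # Combined effect is pulled back to a fraction of the larger single
        # effect, so |combined| < max(|x|, |y|): a magnitude reversal.
        combined = sign * config.antagonism_shrink * np.maximum(np.abs(ax), np.abs(ay))
        x[m] = ax
        y[m] = ay
        inter[m] = combined - (ax + ay)

    return x, y, inter


def simulate_factorial_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a four-condition count matrix plus its ground-truth table.

    Returns
    -------
    counts
        :class:`CountMatrix` with ``4 * n_replicates`` samples named
        ``<condition>_r<replicate>``.
    truth
        DataFrame with columns ``gene_id``, ``true_category``, ``true_x``,
        ``true_y``, ``true_interaction``, ``baseline_mean`` (expected control
        count at size factor 1).

    Identical configs (including seed) produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(n)]

    quotas = category_quotas(config.category_fractions, n)
    categories = np.concatenate(
        [np.full(quotas[c], c, dtype=object) for c in TRUTH_CATEGORIES if c in quotas]
    )

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    if config.baseline_log2_min is not None:
        baseline = np.maximum(baseline, config.baseline_log2_min)
    x, y, inter = _draw_effects(config, categories, rng)

    ctrl, a, b, ab = config.conditions
    sample_ids, sample_conditions = [], []
    for cond in config.conditions:
        for r in range(config.n_replicates):
            sample_ids.append(f"{cond}_r{r + 1}")
            sample_conditions.append(cond)

    if config.library_size_factors is None:
        size_factors = np.ones(config.n_samples)
    else:
        size_factors = np.asarray(config.library_size_factors, dtype=float)

    in_a = np.array([c in (a, ab) for c in sample_conditions], dtype=float)
    in_b = np.array([c in (b, ab) for c in sample_conditions], dtype=float)
    in_ab = np.array([c == ab for c in sample_conditions], dtype=float)

    log2_mu = (
        baseline[:, None]
        + np.outer(x, in_a)
        + np.outer(y, in_b)
        + np.outer(inter, in_ab)
    )
    mu = size_factors[None, :] * np.exp2(log2_mu)

    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                            columns=sample_ids),
        conditions=pd.Series(sample_conditions, index=sample_ids, name="condition"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_category": categories,
            "true_x": x,
            "true_y": y,
            "true_interaction": inter,
            "baseline_mean": np.exp2(baseline),
        }
    )
    return matrix, truth
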