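"""Synergistic / additive / antagonistic classification of factorial responses.

Given per-gene log2 fold changes for cytokine A alone (x), cytokine B alone
(y), and the combination (xy), each with standard errors, two Wald tests drive
the call:

* the sum test — H0: xy = x + y — detects departure from additivity on the
  log2 scale;
* the dominance test — H0: xy = x and H0: xy = y — asks whether the combined
  response differs from each single-cytokine response.

A gene is *synergistic* when the sum test rejects and |xy| > |x + y| (positive
synergism when the combined effect is up, negative when down); the synergy
increase is |xy| − |x + y|. A gene whose combined response is significantly
*smaller* in magnitude than a single-cytokine response is antagonistic and
excluded. A non-synergistic gene whose combined response significantly exceeds
both single responses in magnitude is *additive*. Everything else is left
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

CALL_CATEGORIES: tuple[str, ...] = (
    "synergistic_positive",
    "synergistic_negative",
    "additive",
    "antagonistic_excluded",
    "not_classified",
)

#: Categories that make up the additive-or-synergistic gene (ASG) list.
ASG_CATEGORIES: tuple[str, ...] = (
    "synergistic_positive",
    "synergistic_negative",
    "additive",
)

ELIGIBILITY_MODES = ("ab_de", "any_de", "none")


@dataclass(frozen=True)
class EffectTriplet:
    """Log2 fold changes of A, B, and A+B versus control, with standard errors."""

    gene_id: str
    x: float
    se_x: float
    y: float
    se_y: float
    xy: float
    se_xy: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "xy"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("se_x", "se_y", "se_xy"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class InteractionCall:
    gene_id: str
    category: str
    synergy_increase: float
    p_test1: float
    p_test2_x: float
    p_test2_y: float
    direction: str


def _wald_p(diff, se):
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("combined standard error must be positive")
    z = np.asarray(diff, dtype=float) / se
    return 2.0 * stats.norm.sf(np.abs(z))


def test_sum(t: EffectTriplet, alpha: float = 0.05) -> tuple[float, bool]:
    """Sum test: is the combined effect different from x + y?

    Wald z = (xy − x − y) / sqrt(se_xy² + se_x² + se_y²), two-sided normal p.
    """
    p = float(
        _wald_p(t.xy - t.x - t.y, np.sqrt(t.se_xy**2 + t.se_x**2 + t.se_y**2))
    )
    return p, p < alpha


def test_dominance(t: EffectTriplet, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Dominance test: does the combined effect differ from each single effect?

    Passes only when both Wald tests reject *and* the combined effect exceeds
    both individual effects in magnitude.
    """
    p_x = float(_wald_p(t.xy - t.x, np.hypot(t.se_xy, t.se_x)))
    p_y = float(_wald_p(t.xy - t.y, np.hypot(t.se_xy, t.se_y)))
    passes = (
        p_x < alpha
        and p_y < alpha
        and abs(t.xy) > abs(t.x)
        and abs(t.xy) > abs(t.y)
    )
    return p_x, p_y, passes


def _classify_arrays(x, se_x, y, se_y, xy, se_xy, alpha: float, adjust: bool = False):
    """Vectorized decision cascade shared by the scalar and table interfaces."""
    x, y, xy, se_x, se_y, se_xy = (
        np.asarray(v, dtype=float) for v in (x, y, xy, se_x, se_y, se_xy)
    )
    p1 = _wald_p(xy - x - y, np.sqrt(se_xy**2 + se_x**2 + se_y**2))
    p2x = _wald_p(xy - x, np.hypot(se_xy, se_x))
    p2y = _wald_p(xy - y, np.hypot(se_xy, se_y))
    if adjust:
        p1, p2x, p2y = bh_adjust(p1), bh_adjust(p2x), bh_adjust(p2y)

    abs_xy = np.abs(xy)
    synergistic = (p1 < alpha) & (abs_xy > np.abs(x + y))
    antagonistic = ~synergistic & (
        ((p2x < alpha) & (abs_xy < np.abs(x)))
        | ((p2y < alpha) & (abs_xy < np.abs(y)))
    )
    additive = (
        ~synergistic
        & ~antagonistic
        & (p2x < alpha)
        & (p2y < alpha)
        & (abs_xy > np.abs(x))
        & (abs_xy > np.abs(y))
    )
    category = np.select(
        [synergistic & (xy > 0), synergistic & (xy < 0), antagonistic, additive],
        [
            "synergistic_positive",
            "synergistic_negative",
            "antagonistic_excluded",
            "additive",
        ],
        default="not_classified",
    )
    direction = np.where(xy > 0, "up", "down")
    synergy_increase = abs_xy - np.abs(x + y)
    return category, direction, synergy_increase, p1, p2x, p2y


def classify_gene(t: EffectTriplet, alpha: float = 0.05) -> InteractionCall:
    """Apply the full decision cascade to a single effect triplet."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cat, direction, inc, p1, p2x, p2y = _classify_arrays(
        np.array([t.x]), np.array([t.se_x]),
        np.array([t.y]), np.array([t.se_y]),
        np.array([t.xy]), np.array([t.se_xy]),
        alpha,
    )
    return InteractionCall(
        gene_id=t.gene_id,
        category=str(cat[0]),
        synergy_increase=float(inc[0]),
        p_test1=float(p1[0]),
        p_test2_x=float(p2x[0]),
        p_test2_y=float(p2y[0]),
        direction=str(direction[0]),
    )


def build_triplets(effects: pd.DataFrame,
                   contrasts: tuple[str, str, str] = ("A_vs_control",
                                                      "B_vs_control",
                                                      "AB_vs_control")) -> pd.DataFrame:
    """Pivot a long effect-estimate table into one (x, y, xy) row per gene."""
    missing = set(contrasts) - set(effects["contrast"])
    if missing:
        raise ValueError(f"missing contrasts: {sorted(missing)}")
    wide = effects.pivot(index="gene_id", columns="contrast")
    out = pd.DataFrame(
        {
            "gene_id": wide.index,
            "x": wide[("log2_fch", contrasts[0])],
            "se_x": wide[("se", contrasts[0])],
            "y": wide[("log2_fch", contrasts[1])],
            "se_y": wide[("se", contrasts[1])],
            "xy": wide[("log2_fch", contrasts[2])],
            "se_xy": wide[("se", contrasts[2])],
        }
    ).reset_index(drop=True)
    return out


def classify_all(
    triplets: pd.DataFrame,
    de_results: pd.DataFrame | None = None,
    alpha: float = 0.05,
    eligibility: str = "ab_de",
    adjust_tests: bool = False,
    ab_contrast: str = "AB_vs_control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every eligible gene and tabulate category x direction counts.

    ``eligibility`` selects which genes enter the cascade: ``ab_de`` (default)
    keeps genes differentially expressed in the combination-vs-control
    contrast, ``any_de`` keeps genes DE in any contrast, ``none`` keeps all.
    Returns the per-gene call table and a summary of counts per category split
    by the direction of the combined effect.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if eligibility not in ELIGIBILITY_MODES:
        raise ValueError(f"eligibility must be one of {ELIGIBILITY_MODES}")

    if eligibility == "none":
        eligible_ids = set(triplets["gene_id"])
    else:
        if de_results is None:
            raise ValueError(f"eligibility {eligibility!r} requires DE results")
        unknown = set(de_results["gene_id"]) - set(triplets["gene_id"])
        if unknown:
            raise ValueError(
                f"DE results contain gene ids absent from the triplet table: "
                f"{sorted(unknown)[:5]}"
            )
        de = de_results[de_results["is_de"]]
        if eligibility == "ab_de":
            de = de[de["contrast"] == ab_contrast]
        eligible_ids = set(de["gene_id"])

    sub = triplets[triplets["gene_id"].isin(eligible_ids)].sort_values("gene_id")
    if len(sub):
        cat, direction, inc, p1, p2x, p2y = _classify_arrays(
            sub["x"].to_numpy(), sub["se_x"].to_numpy(),
            sub["y"].to_numpy(), sub["se_y"].to_numpy(),
            sub["xy"].to_numpy(), sub["se_xy"].to_numpy(),
            alpha, adjust=adjust_tests,
        )
    else:
        cat = direction = inc = p1 = p2x = p2y = np.array([])
    calls = sub.assign(
        p_test1=p1, p_test2_x=p2x, p_test2_y=p2y,
        category=cat, direction=direction, synergy_increase=inc,
    ).reset_index(drop=True)
    return calls, summarize_calls(calls)


def summarize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Category x direction counts, with every category present (zeros kept)."""
    summary = pd.DataFrame(0, index=list(CALL_CATEGORIES), columns=["up", "down"])
    if len(calls):
        tab = calls.groupby(["category", "direction"]).size()
        for (cat, direction), n in tab.items():
            summary.loc[cat, direction] = n
    summary["total"] = summary["up"] + summary["down"]
    summary.index.name = "category"
    return summary
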