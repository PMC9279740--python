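"""Scoring classifier output against simulator ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import TRUTH_TO_CALL


def recovery_scores(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    truth_categories: tuple[str, ...] = ("synergistic_pos", "synergistic_neg",
                                         "additive"),
) -> pd.DataFrame:
    """Per-category precision/recall of interaction calls against SimTruth.

    Genes absent from the call table (ineligible) count as ``not_classified``.
    Returns one row per truth category plus a ``macro`` row with the
    unweighted means.
    """
    merged = truth.merge(calls[["gene_id", "category"]], on="gene_id", how="left")
    merged["category"] = merged["category"].fillna("not_classified")

    rows = []
    for tc in truth_categories:
        cc = TRUTH_TO_CALL[tc]
        tp = ((merged["true_category"] == tc) & (merged["category"] == cc)).sum()
        fp = ((merged["true_category"] != tc) & (merged["category"] == cc)).sum()
        fn = ((merged["true_category"] == tc) & (merged["category"] != cc)).sum()
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        rows.append((tc, int(tp), int(fp), int(fn), precision, recall))
    out = pd.DataFrame(
        rows, columns=["category", "tp", "fp", "fn", "precision", "recall"]
    )
    macro = pd.DataFrame(
        [("macro", out["tp"].sum(), out["fp"].sum(), out["fn"].sum(),
          out["precision"].mean(), out["recall"].mean())],
        columns=out.columns,
    )
    return pd.concat([out, macro], ignore_index=True)
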