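"""Gene-set over-representation and ligand–receptor co-regulation reports.

Over-representation follows the standard one-sided hypergeometric model: with
a universe of M tested genes, a set containing n of them, and a query of N
genes overlapping the set in k, the enrichment p-value is P(X >= k) for
X ~ Hypergeometric(M, n, N), BH-adjusted across sets. Gene identifiers are
matched case-insensitively as opaque strings; any ortholog mapping is the
caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .interaction import ASG_CATEGORIES

logger = logging.getLogger(__name__)


def _norm(gene: str) -> str:
    return str(gene).strip().lower()


@dataclass
class GeneSetCollection:
    """Named gene sets intersected with the universe of tested genes.

    Sets are restricted to the universe on construction; sets left empty by
    the intersection are dropped (logged). Identifier matching is
    case-insensitive.
    """

    sets: dict[str, frozenset] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __init__(self, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        self.universe = frozenset(_norm(g) for g in universe)
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.sets = {}
        for name, members in sets.items():
            kept = frozenset(_norm(g) for g in members) & self.universe
            if kept:
                self.sets[name] = kept
            else:
                logger.info("dropping gene set %r: no members in universe", name)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g.strip()]
    return sets


def ora_test(
    query: Iterable[str],
    collection: GeneSetCollection,
    strict: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    In strict mode a query gene outside the universe is an error; in lenient
    mode such genes are dropped with a log message. Results are ranked by
    p-value with BH adjustment across sets.
    """
    query_set = {_norm(g) for g in query}
    outside = query_set - collection.universe
    if outside:
        if strict:
            raise ValueError(
                f"query genes absent from universe: {sorted(outside)}"
            )
        logger.warning("dropping %d query genes absent from universe", len(outside))
        query_set -= outside

    m = len(collection.universe)
    n_query = len(query_set)
    rows = []
    for name, members in collection.sets.items():
        k = len(query_set & members)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy()) if len(out) else []
    return out.sort_values(["p_raw", "set_name"], kind="stable").reset_index(drop=True)


def pair_coregulation(calls: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Joint regulation status of ligand–receptor pairs among classified genes.

    A pair whose two members are both in the additive-or-synergistic gene list
    is ``both_up``, ``both_down``, or ``discordant`` according to the two
    combined-effect directions; pairs with a missing member are ``incomplete``.
    """
    for col in ("ligand", "receptor"):
        if col not in pairs.columns:
            raise ValueError(f"pair table must have a {col!r} column")
    asg = calls[calls["category"].isin(ASG_CATEGORIES)]
    direction = {_norm(g): d for g, d in zip(asg["gene_id"], asg["direction"])}

    rows = []
    for _, row in pairs.iterrows():
        lig, rec = str(row["ligand"]), str(row["receptor"])
        label = row.get("pair", f"{lig}-{rec}")
        d_l = direction.get(_norm(lig))
        d_r = direction.get(_norm(rec))
        if d_l is None or d_r is None:
            status = "incomplete"
        elif d_l == d_r:
            status = "both_up" if d_l == "up" else "both_down"
        else:
            status = "discordant"
        rows.append((label, lig, rec, d_l or "absent", d_r or "absent", status))
    return pd.DataFrame(
        rows,
        columns=["pair", "ligand", "receptor", "ligand_direction",
                 "receptor_direction", "status"],
    )
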