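"""High/low-substitution extremes and functional-class log2 odds.

Filtered homolog pairs are ranked by identical match ratio; the lowest
15% (by default) form the high-substitution ("conserved" in the sense of
conservative substitutions) class and the highest 15% the low-substitution
("identical") class.  Selected genes are assigned one functional class
each (best annotation hit under a strict E-value ceiling) and the per-class
contrast is summarised as log2(conserved_count / identical_count), with an
all-one-class flag where a class contains only one kind of gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import HomologPair


@dataclass
class SplitResult:
    """The two ratio extremes of a ranked pair list."""

    high_substitution: list[str]   # lowest ratios
    low_substitution: list[str]    # highest ratios
    n_total: int
    n_per_side: int


def rank_and_split(pairs, split_fraction: float = 0.15) -> SplitResult:
    """Stable-sort pairs ascending by (ratio, query id) and take both tails.

    n_per_side = floor(split_fraction * n_total) — this rounding reproduces
    a 476 + 476 selection from 3,177 ranked pairs at 15%.
    """
    if isinstance(pairs, pd.DataFrame):
        table = pairs[["query_id", "ratio"]].copy()
    else:
        table = pd.DataFrame(
            {"query_id": [p.query_id for p in pairs],
             "ratio": [p.ratio for p in pairs]})
    if table["ratio"].isna().any():
        raise ValueError("all pairs must carry a defined ratio")
    n_total = len(table)
    n_per_side = int(math.floor(split_fraction * n_total))
    if n_per_side == 0:
        raise ValueError(
            f"{n_total} pairs give an empty {split_fraction:.0%} tail; "
            "provide a larger input")
    ranked = table.sort_values(["ratio", "query_id"], kind="stable")
    high = ranked["query_id"].head(n_per_side).tolist()
    low = ranked["query_id"].tail(n_per_side).tolist()
    return SplitResult(high, low, n_total, n_per_side)


def classify_by_function(split: SplitResult, annotation: pd.DataFrame,
                         max_evalue: float = 1e-10
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tally selected genes into functional classes.

    ``annotation`` rows carry gene_id, function, category, evalue.  A gene
    is assigned to exactly one function: its best (smallest) E-value hit,
    ties broken by lexicographic function name, and only when that E-value
    is strictly below ``max_evalue``.  Returns the per-function count table
    and the number of unassigned genes per side.
    """
    best: dict[str, tuple[float, str, str]] = {}
    for row in annotation.itertuples(index=False):
        ev = float(row.evalue)
        key = (ev, row.function)
        if row.gene_id not in best or key < (best[row.gene_id][0], best[row.gene_id][1]):
            best[row.gene_id] = (ev, row.function, row.category)

    def assign(gene: str):
        hit = best.get(gene)
        if hit is None or not hit[0] < max_evalue:
            return None
        return hit[1], hit[2]

    counts: dict[tuple[str, str], list[int]] = {}
    unassigned = {"high_substitution": 0, "low_substitution": 0}
    for side, genes in (("high_substitution", split.high_substitution),
                        ("low_substitution", split.low_substitution)):
        idx = 0 if side == "high_substitution" else 1
        for gene in genes:
            hit = assign(gene)
            if hit is None:
                unassigned[side] += 1
                continue
            counts.setdefault(hit, [0, 0])[idx] += 1
    rows = [{"function": f, "category": c,
             "conserved_count": v[0], "identical_count": v[1]}
            for (f, c), v in sorted(counts.items())]
    return pd.DataFrame(
        rows, columns=["function", "category", "conserved_count",
                       "identical_count"]), unassigned


def log2_odds_table(function_table: pd.DataFrame) -> pd.DataFrame:
    """Fill log2(conserved/identical) per function.

    Finite only when both counts are positive; an all_one_class flag marks
    functions whose genes all fell on one side (rendered "*" in heat-plot
    output).  Rows with both counts zero are omitted.
    """
    df = function_table.copy()
    df = df[(df.conserved_count > 0) | (df.identical_count > 0)].copy()
    both = (df.conserved_count > 0) & (df.identical_count > 0)
    with np.errstate(divide="ignore"):
        df["log2_odds"] = np.where(
            both, np.log2(df.conserved_count.replace(0, np.nan) /
                          df.identical_count.replace(0, np.nan)), np.nan)
    df["all_one_class"] = ~both
    # direction of the contrast: +1 toward the high-substitution class,
    # -1 toward the low-substitution class; an all-one-class row is an
    # infinite-odds case and keeps the sign of its non-zero side
    df["sign"] = np.where(
        df["all_one_class"],
        np.where(df.conserved_count > 0, 1, -1),
        np.sign(df["log2_odds"]))
    return df.reset_index(drop=True)


def category_rollup(function_table: pd.DataFrame) -> pd.DataFrame:
    """Sum function counts into categories, with the same zero handling."""
    if (function_table["category"].astype(str) == "").any() or \
            function_table["category"].isna().any():
        bad = function_table.loc[
            (function_table["category"].astype(str) == "") |
            function_table["category"].isna(), "function"].tolist()
        raise ValueError(f"function(s) with unknown category: {bad}")
    agg = (function_table.groupby("category", as_index=False)
           [["conserved_count", "identical_count"]].sum())
    return log2_odds_table(agg)
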