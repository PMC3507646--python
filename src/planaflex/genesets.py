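"""Ontology-driven gene-set extraction with descendant roll-up.

Gene sets are defined by a handful of root subcategory terms (for the CNS
analysis: 'central nervous system development' subcategories such as brain
development).  Genes annotated with any descendant of a root are rolled up
into that root, one row per (gene, root) pair, so a multifunctional gene
legitimately contributes several matches while still counting once as a
distinct gene.  The ontology is consumed as an explicit parent -> child
edge list; the full Gene Ontology is never bundled or downloaded.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def rollup_descendants(edges, subcategory_roots: list[str]
                       ) -> dict[str, set[str]]:
    """Map every term to the root subcategories it falls under.

    ``edges`` is an iterable of (parent, child) pairs or a DataFrame with
    parent/child columns.  A term under several roots maps to all of them;
    a cycle in the ontology is an error.
    """
    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges["parent"], edges["child"]))
    else:
        pairs = [(p, c) for p, c, *_ in (tuple(e) for e in edges)]
    graph = nx.DiGraph(pairs)
    graph.add_nodes_from(subcategory_roots)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    mapping: dict[str, set[str]] = {}
    for root in subcategory_roots:
        for term in {root} | nx.descendants(graph, root):
            mapping.setdefault(term, set()).add(root)
    return mapping


def extract_gene_set(gene_terms: pd.DataFrame,
                     rollup_map: dict[str, set[str]],
                     root_order: list[str] | None = None) -> pd.DataFrame:
    """One row per (gene, root subcategory) pair.

    ``gene_terms`` rows carry gene_id, term, protein_name, evalue.  A gene
    annotated with several terms under the same root yields a single row
    for that root; annotation under different roots duplicates the gene
    across rows.  Rows are ordered by subcategory (``root_order`` if given)
    then by first appearance in the input.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for order, row in enumerate(gene_terms.itertuples(index=False)):
        for root in sorted(rollup_map.get(row.term, ())):
            key = (row.gene_id, root)
            if key in seen:
                continue
            seen.add(key)
            rows.append({
                "subcategory": root,
                "unigene_id": row.gene_id,
                "protein_name": getattr(row, "protein_name", ""),
                "evalue": getattr(row, "evalue", float("nan")),
                "_order": order,
            })
    df = pd.DataFrame(rows, columns=["subcategory", "unigene_id",
                                     "protein_name", "evalue", "_order"])
    if root_order:
        rank = {r: k for k, r in enumerate(root_order)}
        df["_rank"] = df["subcategory"].map(rank)
        df = df.sort_values(["_rank", "_order"], kind="stable").drop(columns="_rank")
    else:
        df = df.sort_values(["subcategory", "_order"], kind="stable")
    return df.drop(columns="_order").reset_index(drop=True)


def count_matches_and_genes(gene_set_table: pd.DataFrame
                            ) -> tuple[pd.Series, int, int]:
    """(matches per subcategory, total matches, distinct genes).

    Matches are rows; a gene listed under several subcategories counts one
    match per subcategory but once as a distinct gene.
    """
    per_subcategory = gene_set_table.groupby("subcategory").size()
    total = len(gene_set_table)
    distinct = gene_set_table["unigene_id"].nunique()
    assert per_subcategory.sum() == total
    return per_subcategory, total, distinct
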