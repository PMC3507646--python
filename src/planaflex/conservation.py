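"""Presence/absence conservation calls across target datasets.

A gene is called conserved (present) in a target dataset when at least one
homology-search channel — genome mapping, predicted-protein search or
transcript search — passes that dataset's E-value ceiling (the OR rule).
"Passing" means evalue <= ceiling: a smaller E-value is stronger evidence.
The per-dataset summary counts distinct genes of a gene set, so a gene
appearing under several subcategories still counts once per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import DATASET_COLUMNS

CHANNELS = ("genome_map", "predicted_proteins", "transcript_search")


@dataclass
class ConservationMatrix:
    """Gene x dataset presence calls with winning-channel evidence."""

    calls: pd.DataFrame                      # bool, genes x datasets
    thresholds: dict[str, float]
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def datasets(self) -> list[str]:
        return list(self.calls.columns)

    def to_marks(self) -> pd.DataFrame:
        """Render calls as the "+"/"" cells of the published table layout."""
        return self.calls.map(lambda v: "+" if v else "")


def call_conservation(evidence: pd.DataFrame,
                      thresholds: dict[str, float],
                      genes: list[str] | None = None) -> ConservationMatrix:
    """Apply the OR rule over channels for every gene x dataset cell.

    ``evidence`` rows carry gene_id, dataset, channel, evalue.  A gene with
    no evidence row for a dataset is absent there.  Evidence referencing a
    dataset without a configured threshold is an error.  The winning
    channel (smallest E-value among passing channels) is retained per call
    for audit.
    """
    unknown = set(evidence["dataset"]) - set(thresholds)
    if unknown:
        raise ValueError(f"evidence references unknown dataset(s): {sorted(unknown)}")
    if (evidence["evalue"] <= 0).any():
        raise ValueError("evidence evalues must be positive")
    gene_index = list(genes) if genes is not None else \
        sorted(evidence["gene_id"].unique())
    datasets = sorted(thresholds)
    calls = pd.DataFrame(False, index=gene_index, columns=datasets)
    winners = []
    for (gene, dataset), group in evidence.groupby(["gene_id", "dataset"]):
        if gene not in calls.index:
            continue
        passing = group[group["evalue"] <= thresholds[dataset]]
        if len(passing):
            calls.loc[gene, dataset] = True
            win = passing.loc[passing["evalue"].idxmin()]
            winners.append({"gene_id": gene, "dataset": dataset,
                            "channel": win["channel"],
                            "evalue": win["evalue"]})
    return ConservationMatrix(calls, dict(thresholds),
                              pd.DataFrame(winners, columns=["gene_id", "dataset",
                                                             "channel", "evalue"]))


def matrix_from_marks(gene_set_table: pd.DataFrame,
                      dataset_columns: list[str] = DATASET_COLUMNS
                      ) -> ConservationMatrix:
    """Build a matrix from a published-style table with "+" presence cells.

    A gene marked "+" in any of its subcategory rows is present in that
    dataset (marks within one table are consistent per gene by
    construction of the source analysis).
    """
    present = gene_set_table[["unigene_id", *dataset_columns]].copy()
    grouped = present.groupby("unigene_id")[dataset_columns].agg(
        lambda col: (col == "+").any())
    return ConservationMatrix(grouped, {c: float("nan") for c in dataset_columns})


def summarize_matrix(matrix: ConservationMatrix,
                     gene_set_table: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct-gene conservation counts per dataset, plus per-subcategory tallies.

    Fractions are also rendered as whole percentages, the display convention
    of the source analysis (e.g. 75/82 -> 91%).
    """
    genes = gene_set_table["unigene_id"].unique()
    missing = [g for g in genes if g not in matrix.calls.index]
    if missing:
        raise ValueError(f"gene set gene(s) missing from matrix: {missing}")
    n_set = len(genes)
    rows = []
    for dataset in matrix.datasets:
        present = int(matrix.calls.loc[genes, dataset].sum())
        rows.append({
            "dataset": dataset,
            "present": present,
            "total": n_set,
            "fraction": present / n_set,
            "percent": round(100 * present / n_set),
        })
    per_dataset = pd.DataFrame(rows)
    sub_rows = []
    for subcat, group in gene_set_table.groupby("subcategory"):
        sub_genes = group["unigene_id"].unique()
        for dataset in matrix.datasets:
            sub_rows.append({
                "subcategory": subcat,
                "dataset": dataset,
                "present": int(matrix.calls.loc[sub_genes, dataset].sum()),
                "total": len(sub_genes),
            })
    return per_dataset, pd.DataFrame(sub_rows)
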