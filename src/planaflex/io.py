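"""Readers and writers for the pipeline's file formats.

Sequences travel as FASTA (via Biopython), tables as TSV (via pandas).
Coordinates are 0-based half-open in memory and 1-based inclusive in files
and reports.  Every report written here carries the run-configuration
snapshot (thresholds and seed) as ``#`` header lines so a result can always
be traced back to the exact filter settings that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("planaflex")

#: IUPAC nucleotide codes accepted in input sequences (U is mapped to T).
VALID_NT = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with a unique identifier.

    The sequence is stored uppercased with U mapped to T; ambiguity codes
    are kept and only resolved (to X) at translation time.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.seq):
            if ch not in VALID_NT:
                raise ValueError(
                    f"{self.id}: illegal character {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; duplicate identifiers and illegal characters are
    rejected with the offending id/position named.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(rec.id, _normalize(str(rec.seq)), rec.description)
        )
    logger.info("read_fasta %s: %d records", path, len(records))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


@dataclass
class RunConfig:
    """Thresholds and scoring settings for one pipeline run.

    Defaults are the published filter settings for the full-scale species
    comparison: query unigene >= 600 bp, pair E-value <= 1e-30, conserved
    region >= 80 bp, a 15% split per tail, annotation E-value < 1e-10, and
    conservation ceilings of 1e-10 (schistosome channels) / 1e-30
    (S. mediterranea channels).  Desk-scale synthetic runs override the
    length threshold to match their shorter simulated genes.
    """

    min_query_len_nt: int = 600
    max_evalue_pair: float = 1e-30
    min_region_nt: int = 80
    split_fraction: float = 0.15
    max_evalue_function: float = 1e-10
    max_evalue_conservation: dict[str, float] = field(default_factory=dict)
    gap_open: int = 11
    gap_extend: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 0.5:
            raise ValueError("split_fraction must lie in (0, 0.5)")
        for name in ("min_query_len_nt", "min_region_nt", "gap_open", "gap_extend"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")

    def header_lines(self) -> list[str]:
        items = []
        for key, val in asdict(self).items():
            items.append(f"# {key}={val}")
        return items

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or flat ``key=value`` lines."""
        text = Path(path).read_text()
        if "=" in text.splitlines()[0] and ":" not in text.splitlines()[0]:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = yaml.safe_load(val.strip())
        else:
            data = yaml.safe_load(text) or {}
        return cls(**data)


def write_report(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a TSV report, prefixed with the RunConfig snapshot."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            for line in config.header_lines():
                fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                       na_values=[""])


# ---------------------------------------------------------------- tables

#: named TSV schemas: column -> dtype caster (None = string)
TABLE_SCHEMAS: dict[str, dict[str, object]] = {
    "annotation": {"gene_id": str, "label": str, "evalue": float},
    "function_annotation": {
        "gene_id": str, "function": str, "category": str, "evalue": float,
    },
    "gene_terms": {"gene_id": str, "term": str, "protein_name": str, "evalue": float},
    "ontology_edges": {"parent": str, "child": str, "label": str},
    "evidence": {"gene_id": str, "dataset": str, "channel": str, "evalue": float},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a tab-separated table against a named schema.

    Missing required columns raise; rows whose numeric fields fail to parse
    raise with the (1-based, header-inclusive) line number named.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     comment="#")
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col, caster in spec.items():
        if caster is float:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[parsed.isna() & (df[col] != "")]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric {col!r} at line {bad[0] + 2}"
                )
            df[col] = parsed
            negative = df.index[parsed < 0]
            if len(negative):
                raise ValueError(
                    f"{path}: negative {col!r} at line {negative[0] + 2}"
                )
    logger.info("read_table %s (%s): %d rows", path, schema, len(df))
    return df


def read_alignment_table(path: str | Path) -> pd.DataFrame:
    """Read externally produced homology-search results.

    BLAST-style tabular columns extended with the two aligned sequence
    strings, so the column-classification stage can run without the internal
    aligner.  Aligned strings must be equal length per row.
    """
    cols = [
        "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "score",
        "aligned_query", "aligned_subject",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, dtype=str, keep_default_na=False)
    for col in ("evalue", "score"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("qstart", "qend", "sstart", "send", "length"):
        df[col] = df[col].astype(int)
    for idx, row in df.iterrows():
        if len(row.aligned_query) != len(row.aligned_subject):
            raise ValueError(
                f"{path}: unequal aligned-string lengths at line {idx + 1}"
            )
        if row.evalue <= 0:
            raise ValueError(f"{path}: non-positive evalue at line {idx + 1}")
    return df


# ------------------------------------------------------- packaged fixture

GENE_SET_COLUMNS = [
    "subcategory", "unigene_id", "protein_name", "evalue",
    "smed_genome", "smed_mrna", "schisto_genome", "schisto_mrna",
]

#: presence/absence columns of the packaged comparative table
DATASET_COLUMNS = ["smed_genome", "smed_mrna", "schisto_genome", "schisto_mrna"]


def load_cns_gene_table() -> pd.DataFrame:
    """Load the packaged CNS-development gene-set table.

    96 rows of (GO subcategory, unigene, putative protein, E-value) with
    four presence columns ("+" = found in that dataset) covering the
    S. mediterranea and schistosome genome/mRNA searches.  Note one printed
    E-value is exactly zero (a search-tool underflow), so this table's
    evalue column is validated as >= 0 rather than > 0.
    """
    with resources.files("planaflex.data").joinpath(
        "cns_gene_sets_table.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    assert list(df.columns) == GENE_SET_COLUMNS
    if (df["evalue"].astype(float) < 0).any():
        raise ValueError("negative evalue in packaged gene-set table")
    df["evalue"] = df["evalue"].astype(float)
    return df
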