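"""Reading and writing the pipeline's plain-text formats.

Hit tables are TSV with BLAST outfmt-6-compatible core columns
(read_id, taxon_id, pct_identity, aln_length, bit_score) plus a
sample_id; a configurable column mapping accepts raw outfmt-6 headers
(qseqid, sseqid, pident, length, bitscore). Lineage maps, count tables,
truth tables and distance matrices are TSV; configs are YAML or JSON;
FASTQ (for read lengths) goes through Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import HIT_COLUMNS, CountTable, LineageTable, ValidationError

#: Default mapping from raw BLAST outfmt-6 headers to the internal schema.
BLAST6_COLUMN_MAP = {
    "qseqid": "read_id",
    "sseqid": "taxon_id",
    "pident": "pct_identity",
    "length": "aln_length",
    "bitscore": "bit_score",
}


def read_hits(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a hit table TSV, renaming columns via ``column_map`` if given."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"hit table {path} missing columns {missing}")
    return df


def write_hits(df: pd.DataFrame, path: str | Path, core_only: bool = True) -> None:
    """Write a hit table TSV (core columns plus read_length when present)."""
    cols = [c for c in HIT_COLUMNS if c in df.columns]
    if "read_length" in df.columns:
        cols = cols + ["read_length"]
    out = df[cols] if core_only else df
    out.to_csv(path, sep="\t", index=False)


def read_lineage(path: str | Path) -> LineageTable:
    return LineageTable(pd.read_csv(path, sep="\t", dtype=str))


def write_lineage(lineage: LineageTable, path: str | Path) -> None:
    lineage.df.reset_index().to_csv(path, sep="\t", index=False)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write taxa rows x sample columns, with rank/normalized in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# rank={table.rank} normalized={str(table.normalized).lower()}\n")
        table.data.rename_axis(table.rank).to_csv(fh, sep="\t")


def read_count_table(path: str | Path) -> CountTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: missing count-table header comment")
        fields = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.columns.name = "sample_id"
    return CountTable(df, rank=fields["rank"], normalized=fields["normalized"] == "true")


def write_long_csv(table: CountTable, path: str | Path) -> None:
    """Long-format CSV (taxon, sample_id, count) — the pivot-table-friendly export."""
    long = (
        table.data.rename_axis(table.rank)
        .reset_index()
        .melt(id_vars=table.rank, var_name="sample_id", value_name="count")
    )
    long.to_csv(path, index=False)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "participant_id", "compartment"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata {path} missing columns {sorted(missing)}")
    return df


def write_fastq(df: pd.DataFrame, path: str | Path) -> None:
    """Write length-bearing placeholder FASTQ records (N-runs, flat quality).

    Sequence content is synthetic: only read ids and lengths are
    meaningful, which is all the size-selection filter consumes.
    """
    if "read_length" not in df.columns:
        raise ValidationError("write_fastq needs a read_length column")
    records = (
        SeqRecord(
            Seq("N" * int(n)),
            id=str(rid),
            description="",
            letter_annotations={"phred_quality": [20] * int(n)},
        )
        for rid, n in zip(df["read_id"], df["read_length"])
    )
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq_lengths(path: str | Path) -> pd.Series:
    """read_id -> sequence length from a FASTQ file."""
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fastq")}
    return pd.Series(lengths, name="read_length")


def attach_read_lengths(hits: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Join FASTQ-derived lengths onto a hit table (NaN where absent)."""
    out = hits.copy()
    out["read_length"] = out["read_id"].map(lengths)
    return out


def load_config(path: str | Path) -> dict:
    """Load a run config from YAML or JSON by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
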