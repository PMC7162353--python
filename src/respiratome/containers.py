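"""Core in-memory containers shared across the pipeline.

Per-read hits live in pandas DataFrames with a fixed column schema
(:data:`HIT_COLUMNS`), taxonomic lineages in a :class:`LineageTable`,
aggregated counts in a :class:`CountTable` (taxa rows x sample columns),
and one participant's per-compartment species counts in a
:class:`ParticipantProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Core columns of a per-read hit table (BLAST outfmt-6-compatible subset,
#: plus the sample the read came from).
HIT_COLUMNS = ("read_id", "taxon_id", "pct_identity", "aln_length", "bit_score", "sample_id")

#: Optional columns a hit table may carry (read_length comes from FASTQ).
OPTIONAL_HIT_COLUMNS = ("read_length",)

#: Taxonomic ranks supported by the profiler, most to least resolved.
RANKS = ("species", "genus", "family", "phylum")

#: Respiratory compartments, ordered from the lung outward.
COMPARTMENTS = ("LAV", "throat", "mouth", "nose")

#: Name bucket for reads whose taxon id has no lineage entry.
UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def validate_hits(df: pd.DataFrame, require_length: bool = False) -> pd.DataFrame:
    """Check a hit DataFrame against the HitRecord invariants.

    Identity must lie in (0, 100], alignment length must be positive and
    bit score non-negative. Returns the frame unchanged on success.
    """
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"hit table missing columns: {missing}")
    if require_length and "read_length" not in df.columns:
        raise ValidationError("hit table has no read_length column")
    if len(df) == 0:
        return df
    if not ((df["pct_identity"] > 0) & (df["pct_identity"] <= 100)).all():
        raise ValidationError("pct_identity must be in (0, 100]")
    if not (df["aln_length"] > 0).all():
        raise ValidationError("aln_length must be positive")
    if not (df["bit_score"] >= 0).all():
        raise ValidationError("bit_score must be non-negative")
    return df


class LineageTable:
    """Taxon id -> (species, genus, family, phylum) lookup.

    Wraps a DataFrame indexed by ``taxon_id`` with one column per rank.
    Construction validates that the hierarchy is consistent: a species
    maps to exactly one genus, a genus to exactly one family and phylum.
    """

    def __init__(self, df: pd.DataFrame):
        required = set(RANKS)
        if not required.issubset(df.columns):
            raise ValidationError(f"lineage table needs columns {sorted(required)}")
        if df.index.name != "taxon_id":
            if "taxon_id" in df.columns:
                df = df.set_index("taxon_id")
            else:
                raise ValidationError("lineage table needs a taxon_id index or column")
        if df.index.has_duplicates:
            raise ValidationError("duplicate taxon_id in lineage table")
        # no polyphyletic names: each child name maps to exactly one parent
        for child, parent in (("species", "genus"), ("genus", "family"), ("genus", "phylum")):
            n_parents = df.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"{child} mapped to multiple {parent} values: {list(bad.index[:5])}"
                )
        self.df = df[list(RANKS)].copy()

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, str]]) -> "LineageTable":
        return cls(pd.DataFrame(list(records)))

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.df.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.df.index

    def names_at(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        return self.df[rank]

    def map_taxa(self, taxon_ids: pd.Series, rank: str, strict: bool = False) -> pd.Series:
        """Map taxon ids to names at ``rank``; unknown ids -> 'unclassified'.

        In strict mode an unknown id raises instead.
        """
        mapped = taxon_ids.map(self.names_at(rank))
        unknown = mapped.isna()
        if unknown.any():
            if strict:
                bad = sorted(taxon_ids[unknown].unique())[:5]
                raise ValidationError(f"unknown taxon ids: {bad}")
            mapped = mapped.fillna(UNCLASSIFIED)
        return mapped

    def parent_of(self, rank: str, parent_rank: str) -> pd.Series:
        """Unique child-name -> parent-name mapping (e.g. genus -> phylum)."""
        return self.df.drop_duplicates(subset=[rank]).set_index(rank)[parent_rank]


@dataclass
class CountTable:
    """Taxa x samples matrix of read counts at one taxonomic rank.

    ``data`` holds taxa as rows and samples as columns. Raw tables are
    integer-valued; normalized/proportion tables are real-valued with
    ``normalized=True``.
    """

    data: pd.DataFrame
    rank: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValidationError(f"unknown rank {self.rank!r}")
        if len(self.data) and (self.data.values < 0).any():
            raise ValidationError("counts must be non-negative")
        if not self.normalized and len(self.data):
            vals = self.data.to_numpy(dtype=float)
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("raw count tables must be integer-valued")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def total(self) -> float:
        return float(self.data.to_numpy().sum())

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def pooled(self) -> pd.Series:
        """Counts pooled across samples, per taxon."""
        return self.data.sum(axis=1)

    def copy(self) -> "CountTable":
        return replace(self, data=self.data.copy())


@dataclass
class ParticipantProfile:
    """One participant's per-compartment counts at one rank.

    ``counts`` has taxa as rows and compartments (a subset of
    :data:`COMPARTMENTS`) as columns. After total-sum scaling,
    ``normalized`` is True and ``target_depth`` records the common total.
    """

    participant_id: str
    counts: pd.DataFrame
    rank: str = "species"
    normalized: bool = False
    target_depth: float | None = None

    def __post_init__(self) -> None:
        unknown = [c for c in self.counts.columns if c not in COMPARTMENTS]
        if unknown:
            raise ValidationError(f"unknown compartments {unknown}")
        if self.normalized and self.target_depth is not None and len(self.counts):
            totals = self.counts.sum(axis=0)
            if not np.allclose(totals, self.target_depth, atol=1e-6):
                raise ValidationError("normalized compartment totals differ from target depth")

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def has(self, *compartments: str) -> bool:
        return all(c in self.counts.columns for c in compartments)


def participant_sample_id(participant_id: str, compartment: str) -> str:
    """Canonical sample id for one participant/compartment pair."""
    return f"{participant_id}_{compartment}"
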