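"""Multi-rank taxonomic profiling of per-read assignments.

Aggregates one-hit-per-read tables into taxa x samples count matrices at
species/genus/family/phylum rank, and derives the community summaries a
respiratory profiling study reports: relative abundances, the dominant
phyla and their read coverage, per-group species richness, and the top
genera within a phylum.

Reads whose taxon id has no lineage entry are bucketed as "unclassified"
rather than dropped, so read totals are conserved across ranks.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import RANKS, UNCLASSIFIED, CountTable, LineageTable, ValidationError

logger = logging.getLogger(__name__)


def aggregate_counts(
    hits: pd.DataFrame, lineage: LineageTable, rank: str, strict: bool = False
) -> CountTable:
    """Tally assigned reads into a taxa x samples count table at ``rank``."""
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    if len(hits) == 0:
        return CountTable(pd.DataFrame(), rank=rank)
    names = lineage.map_taxa(hits["taxon_id"], rank, strict=strict)
    n_unclassified = int((names == UNCLASSIFIED).sum())
    if n_unclassified:
        logger.warning("%d reads with unknown taxon id bucketed as unclassified", n_unclassified)
    table = (
        pd.crosstab(names.rename(rank), hits["sample_id"])
        .sort_index()
        .sort_index(axis=1)
        .astype(int)
    )
    table.columns.name = "sample_id"
    return CountTable(table, rank=rank)


def relative_abundance(table: CountTable) -> CountTable:
    """Convert counts to per-sample proportions (columns sum to 1).

    Zero-total samples cannot be normalized and are excluded with a warning.
    """
    if len(table.data) == 0:
        return CountTable(table.data.copy(), rank=table.rank, normalized=True)
    totals = table.sample_totals()
    empty = totals[totals == 0]
    if len(empty):
        logger.warning("excluding zero-total samples from relative abundance: %s",
                       list(empty.index))
    kept = table.data.loc[:, totals > 0]
    return CountTable(kept / kept.sum(axis=0), rank=table.rank, normalized=True)


def dominant_phyla(table: CountTable, k: int = 5) -> tuple[list[str], float]:
    """The k phyla with the largest pooled counts and their pooled coverage.

    Ties break lexicographically. With fewer than k phyla, all are
    returned with coverage 1.
    """
    if table.rank != "phylum":
        raise ValidationError("dominant_phyla needs a phylum-rank table")
    pooled = table.pooled()
    total = pooled.sum()
    if total == 0 or len(pooled) == 0:
        return list(pooled.index[:k]), 1.0
    ranked = pooled.sort_index().sort_values(ascending=False, kind="mergesort")
    top = ranked.iloc[:k]
    coverage = 1.0 if len(pooled) <= k else float(top.sum() / total)
    return list(top.index), coverage


def species_richness(table: CountTable, lineage: LineageTable) -> dict[str, pd.Series]:
    """Distinct detected species per genus and per phylum.

    A species is detected when its pooled count is positive; unclassified
    reads carry no species identity and are ignored here.
    """
    if table.rank != "species":
        raise ValidationError("species_richness needs a species-rank table")
    pooled = table.pooled()
    detected = [s for s in pooled.index[pooled > 0] if s != UNCLASSIFIED]
    out = {}
    for group_rank in ("genus", "phylum"):
        parent = lineage.parent_of("species", group_rank)
        groups = parent.reindex(detected).dropna()
        out[group_rank] = groups.groupby(groups).size().rename("n_species")
    return out


def top_genera(
    table: CountTable, lineage: LineageTable, within_phylum: str, n: int = 15
) -> pd.DataFrame:
    """Rank the genera of one phylum by pooled count, truncated to n.

    Returns a frame with pooled counts and within-phylum relative
    abundance; genera beyond the top n are pooled as "other". Ties break
    lexicographically. An unknown phylum yields an empty result with a
    warning.
    """
    if table.rank != "genus":
        raise ValidationError("top_genera needs a genus-rank table")
    phylum_of = lineage.parent_of("genus", "phylum")
    members = phylum_of.index[phylum_of == within_phylum]
    if len(members) == 0:
        logger.warning("phylum %r not present in lineage table", within_phylum)
        return pd.DataFrame(columns=["pooled_count", "relative_abundance"])
    pooled = table.pooled().reindex(members, fill_value=0)
    total = pooled.sum()
    ranked = pooled.sort_index().sort_values(ascending=False, kind="mergesort")
    top = ranked.iloc[:n]
    rows = top.to_frame("pooled_count")
    if len(ranked) > n:
        rows.loc["other"] = ranked.iloc[n:].sum()
    rows["relative_abundance"] = rows["pooled_count"] / total if total > 0 else 0.0
    return rows
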