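"""Read-level QA/QC for long-read rRNA operon hit tables.

Three windows gate a read into the analysis: a size-selection window on
read length (3.7-5.7 kb, the near-full-length operon amplicon), a percent
identity window of 70-95% against the reference database, and a minimum
16S alignment length of more than 1,200 bp. The identity ceiling excludes
near-perfect hits that are likely database self-matches or short
conserved-region artefacts; the floor excludes unalignable reads. After
filtering, each read keeps only its best database hit, and reagent
(kitome) contamination is estimated from PCR-negative libraries.

Length and identity bounds are inclusive; the alignment bound is strictly
exclusive (the window is stated as ">1,200 bp").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """QA/QC windows, in bp and percent on the 0-100 scale."""

    len_min: float = 3700.0
    len_max: float = 5700.0
    id_min: float = 70.0
    id_max: float = 95.0
    aln_min: float = 1200.0

    def __post_init__(self) -> None:
        if not self.len_min < self.len_max:
            raise ValidationError("len_min must be < len_max")
        if not (0 < self.id_min < self.id_max <= 100):
            raise ValidationError("need 0 < id_min < id_max <= 100")
        if not self.aln_min > 0:
            raise ValidationError("aln_min must be positive")


def filter_read_lengths(
    hits: pd.DataFrame, qc: QCConfig | None = None, strict: bool = False
) -> pd.DataFrame:
    """Keep reads whose length lies in [len_min, len_max] (size selection).

    Records without a read length (no column, or NaN) pass with a logged
    warning; in strict mode they raise instead. Row order is preserved and
    the operation is idempotent.
    """
    qc = qc or QCConfig()
    if "read_length" not in hits.columns:
        if strict:
            raise ValidationError("read_length required for length filtering in strict mode")
        if len(hits):
            logger.warning(
                "%d records lack read_length; passing length filter unchecked", len(hits)
            )
        return hits.copy()
    lengths = hits["read_length"]
    missing = lengths.isna()
    if missing.any():
        if strict:
            raise ValidationError(f"{int(missing.sum())} records missing read_length")
        logger.warning(
            "%d records missing read_length; passing length filter unchecked",
            int(missing.sum()),
        )
    keep = missing | ((lengths >= qc.len_min) & (lengths <= qc.len_max))
    return hits.loc[keep].copy()


def filter_hits(hits: pd.DataFrame, qc: QCConfig | None = None) -> pd.DataFrame:
    """Keep hits with id_min <= identity <= id_max and alignment > aln_min."""
    qc = qc or QCConfig()
    if len(hits) == 0:
        return hits.copy()
    keep = (
        (hits["pct_identity"] >= qc.id_min)
        & (hits["pct_identity"] <= qc.id_max)
        & (hits["aln_length"] > qc.aln_min)
    )
    return hits.loc[keep].copy()


def select_top_hit(hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce a multi-hit table to one best hit per read.

    The best hit maximizes bit score, then percent identity, then alignment
    length; any remaining tie goes to the lexicographically smallest
    taxon_id. Output rows appear in order of each read's first occurrence
    in the input, making the operation fully deterministic.
    """
    if len(hits) == 0:
        return hits.copy()
    ranked = hits.sort_values(
        ["bit_score", "pct_identity", "aln_length", "taxon_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates(subset="read_id", keep="first")
    order = hits.loc[~hits["read_id"].duplicated(), "read_id"]
    return best.set_index("read_id").loc[order].reset_index()[list(hits.columns)]


@dataclass(frozen=True)
class KitomeResult:
    """Reagent-contamination estimate from paired PCR-negative/positive runs."""

    contamination_pct: float
    fold_difference: float | None
    neg_count: int
    pos_count: int


def kitome_contamination(neg_count: int, pos_count: int) -> KitomeResult:
    """Estimate kitome contamination from library read counts.

    Returns the negative-library read count as a percentage of the
    positive-library count, plus the positive/negative fold-difference
    (None when the negative library is empty).
    """
    if pos_count <= 0:
        raise ValidationError("positive-library read count must be > 0")
    if neg_count < 0:
        raise ValidationError("negative-library read count must be >= 0")
    pct = 100.0 * neg_count / pos_count
    fold = pos_count / neg_count if neg_count > 0 else None
    return KitomeResult(pct, fold, int(neg_count), int(pos_count))


def qc_summary(
    raw: pd.DataFrame, after_length: pd.DataFrame, after_hits: pd.DataFrame
) -> dict:
    """Per-sample in/out counts for each filter stage (JSON-serialisable)."""

    def per_sample(df: pd.DataFrame) -> dict:
        if len(df) == 0:
            return {}
        return {k: int(v) for k, v in df.groupby("sample_id").size().items()}

    return {
        "reads_in": len(raw),
        "reads_after_length_filter": len(after_length),
        "reads_after_hit_filter": len(after_hits),
        "per_sample": {
            "in": per_sample(raw),
            "after_length_filter": per_sample(after_length),
            "after_hit_filter": per_sample(after_hits),
        },
    }
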