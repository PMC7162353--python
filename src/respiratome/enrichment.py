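"""Lung-enrichment calling and compartment-gradient classification.

The core computation: per participant, compartment counts are put on a
common read-count scale by total-sum scaling, the mouth and nose counts
are subtracted from the lavage counts, and a species is called
lung-enriched when BOTH differences exceed a conservative read-difference
threshold (default 150 reads — the scale at which replicate long-read
counts are reliably distinguishable). The throat, sampled between the
end-member compartments, is not part of the enrichment definition; it
verifies the direction of each species' gradient: abundance rising from
the outer pool through the throat to the lung is an inside-out
(colonization) pattern, falling is outside-in (passive transport plus
clearance).

Normalization scales each compartment to the participant's median raw
compartment depth by default, keeping values on a read-count-like scale
so the read-difference threshold retains its meaning. Differences are
kept as reals; nothing is rounded before thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    COMPARTMENTS,
    CountTable,
    ParticipantProfile,
    ValidationError,
    participant_sample_id,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 150.0

#: Compartments the enrichment definition requires (throat is optional,
#: used only for gradient verification).
ENRICHMENT_COMPARTMENTS = ("LAV", "mouth", "nose")


class MissingCompartmentError(ValidationError):
    """A participant lacks a compartment required by the requested analysis."""


def build_profiles(table: CountTable, metadata: pd.DataFrame) -> dict[str, ParticipantProfile]:
    """Split a count table into per-participant compartment profiles.

    ``metadata`` maps sample_id -> (participant_id, compartment); only
    ``library_type == "sample"`` rows participate when the column exists.
    """
    meta = metadata
    if "library_type" in meta.columns:
        meta = meta[meta["library_type"] == "sample"]
    profiles: dict[str, ParticipantProfile] = {}
    for pid, group in meta.groupby("participant_id"):
        cols, names = [], []
        for comp in COMPARTMENTS:
            match = group.loc[group["compartment"] == comp, "sample_id"]
            if len(match) == 0:
                continue
            sid = match.iloc[0]
            if sid in table.data.columns:
                cols.append(table.data[sid])
                names.append(comp)
        if cols:
            counts = pd.concat(cols, axis=1)
            counts.columns = names
            profiles[pid] = ParticipantProfile(pid, counts, rank=table.rank)
    return profiles


def normalize_counts(
    profile: ParticipantProfile, target_depth: float | None = None
) -> ParticipantProfile:
    """Total-sum scale each compartment to a common depth.

    The default target is the participant's median raw compartment depth.
    Zero-total compartments cannot be scaled and are excluded with a
    warning. Values stay real-valued (no rounding).
    """
    totals = profile.counts.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        logger.warning(
            "participant %s: excluding empty compartments %s",
            profile.participant_id, list(empty.index),
        )
    counts = profile.counts.loc[:, totals > 0]
    totals = totals[totals > 0]
    if target_depth is None:
        target_depth = float(np.median(totals.to_numpy()))
    scaled = counts / totals * target_depth
    return ParticipantProfile(
        profile.participant_id, scaled, rank=profile.rank,
        normalized=True, target_depth=target_depth,
    )


def compartment_differences(profile: ParticipantProfile) -> pd.DataFrame:
    """Per-species lavage-minus-mouth and lavage-minus-nose differences.

    Requires a normalized profile with LAV, mouth and nose present;
    participants missing any of them are excluded from enrichment (the
    incomplete-sampling precedent: their samples still join the community
    summaries).
    """
    if not profile.normalized:
        raise ValidationError("profile must be normalized before differencing")
    missing = [c for c in ENRICHMENT_COMPARTMENTS if c not in profile.counts.columns]
    if missing:
        raise MissingCompartmentError(
            f"participant {profile.participant_id} lacks {missing}; excluded from enrichment"
        )
    return pd.DataFrame(
        {
            "d_mouth": profile.counts["LAV"] - profile.counts["mouth"],
            "d_nose": profile.counts["LAV"] - profile.counts["nose"],
        }
    )


def classify_enriched(
    diffs: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> tuple[set[str], pd.DataFrame]:
    """Call lung-enriched species from paired differences.

    A species is enriched iff d_mouth > threshold AND d_nose > threshold
    (strict, conjunctive — the conservative reading of paired
    subtraction). Returns the enriched set plus a per-species frame with
    the margin min(d_mouth, d_nose) - threshold.
    """
    if not np.isfinite(diffs[["d_mouth", "d_nose"]].to_numpy()).all():
        raise ValidationError("differences must be finite")
    margin = diffs[["d_mouth", "d_nose"]].min(axis=1) - threshold
    enriched = (diffs["d_mouth"] > threshold) & (diffs["d_nose"] > threshold)
    detail = pd.DataFrame({"enriched": enriched, "margin": margin})
    return set(diffs.index[enriched]), detail


def gradient_classify(
    profile: ParticipantProfile, epsilon: float = 0.0
) -> pd.Series:
    """Classify each species' compartment pattern using the throat as pivot.

    ``inside_out``: LAV > throat > outer (strictly, beyond ``epsilon``);
    ``outside_in``: the reverse; ``flat``: all pairwise differences within
    ``epsilon``; anything else is ``discordant``. The outer value is the
    mean of the present mouth/nose compartments.
    """
    if not profile.has("LAV", "throat"):
        raise MissingCompartmentError(
            f"participant {profile.participant_id}: gradient undetermined without LAV and throat"
        )
    outer_cols = [c for c in ("mouth", "nose") if c in profile.counts.columns]
    if not outer_cols:
        raise MissingCompartmentError(
            f"participant {profile.participant_id}: no outer compartment present"
        )
    lav = profile.counts["LAV"]
    throat = profile.counts["throat"]
    outer = profile.counts[outer_cols].mean(axis=1)

    inside = (lav > throat + epsilon) & (throat > outer + epsilon)
    outside = (outer > throat + epsilon) & (throat > lav + epsilon)
    flat = (
        ((lav - throat).abs() <= epsilon)
        & ((throat - outer).abs() <= epsilon)
        & ((lav - outer).abs() <= epsilon)
    )
    out = pd.Series("discordant", index=profile.counts.index, name="gradient_class")
    out[flat] = "flat"
    out[inside] = "inside_out"
    out[outside] = "outside_in"
    return out


def enriched_fraction(n_enriched: int, n_detected: int) -> float:
    """Enriched species as a percentage of detected species."""
    if n_detected <= 0:
        raise ValidationError("detected species count must be positive")
    return 100.0 * n_enriched / n_detected


@dataclass
class EnrichmentResult:
    """Per-participant enrichment and gradient calls at one threshold."""

    participant_id: str
    diffs: pd.DataFrame            # species x (d_mouth, d_nose)
    enriched: set[str]
    detail: pd.DataFrame           # species x (enriched, margin)
    gradient: pd.Series | None     # species -> class (None if throat absent)
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        out = self.diffs.copy()
        out["enriched"] = self.detail["enriched"]
        out["gradient_class"] = (
            self.gradient if self.gradient is not None else "undetermined"
        )
        out.insert(0, "participant_id", self.participant_id)
        out["threshold"] = self.threshold
        return out


def analyze_participant(
    profile: ParticipantProfile,
    threshold: float = DEFAULT_THRESHOLD,
    target_depth: float | None = None,
    epsilon: float = 0.0,
) -> EnrichmentResult:
    """Normalize, difference, threshold and gradient-classify one participant."""
    norm = profile if profile.normalized else normalize_counts(profile, target_depth)
    diffs = compartment_differences(norm)
    enriched, detail = classify_enriched(diffs, threshold)
    gradient = None
    if norm.has("LAV", "throat"):
        gradient = gradient_classify(norm, epsilon)
    else:
        logger.warning("participant %s: throat missing, gradient undetermined",
                       profile.participant_id)
    return EnrichmentResult(profile.participant_id, diffs, enriched, detail,
                            gradient, threshold)


def heatmap_matrix(
    results: dict[str, EnrichmentResult], threshold: float | None = None
) -> pd.DataFrame:
    """Species x (participant, difference-type) matrix of normalized differences.

    Rows are restricted to species exceeding the threshold (both
    differences) in at least one participant, ordered by descending
    maximum difference then name — the layout of a lung-enrichment heat
    map. Returns an empty frame (with a warning) when nothing passes.
    """
    if not results:
        raise ValidationError("need at least one participant result")
    if threshold is None:
        threshold = next(iter(results.values())).threshold
    keep: set[str] = set()
    for res in results.values():
        passing, _ = classify_enriched(res.diffs, threshold)
        keep |= passing
    if not keep:
        logger.warning("no species exceed the threshold in any participant")
        return pd.DataFrame(
            columns=pd.MultiIndex.from_arrays([[], []], names=["participant_id", "difference"])
        )
    blocks = {}
    for pid in sorted(results):
        diffs = results[pid].diffs
        blocks[(pid, "d_mouth")] = diffs["d_mouth"]
        blocks[(pid, "d_nose")] = diffs["d_nose"]
    mat = pd.DataFrame(blocks).loc[sorted(keep)]
    mat.columns.names = ["participant_id", "difference"]
    order = mat.max(axis=1).sort_values(ascending=False, kind="mergesort")
    # descending max difference, ties by name (sorted(keep) made names ascending)
    return mat.loc[order.index]


def plot_heatmap(matrix: pd.DataFrame, path: str | None = None):
    """Render the enrichment heat map with matplotlib (optional output file)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels([f"{p}:{d}" for p, d in matrix.columns], rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized read difference (LAV - outer)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
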