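"""End-to-end orchestration: simulate/ingest -> QC -> profile -> enrich -> ordinate.

``run_pipeline`` executes the stages in order, writes every tabular
output as TSV/JSON under the configured output directory, and returns a
manifest recording the config fingerprint, seed and per-stage record
counts. Identical (config, seed) yields identical manifest counts. Any
stage failure aborts with a stage-labelled error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, enrichment, io, qc, simulate, taxprofile
from .containers import UNCLASSIFIED, ValidationError
from .qc import QCConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    In ``synthetic`` mode a scenario (given or default) generates the
    inputs; in ``files`` mode hit/lineage/metadata paths are read.
    """

    mode: str = "synthetic"
    outdir: str | Path = "respiratome_run"
    seed: int = 0
    threshold: float = enrichment.DEFAULT_THRESHOLD
    target_depth: float | None = None
    ranks: tuple[str, ...] = ("phylum", "genus", "species")
    qc: QCConfig = field(default_factory=QCConfig)
    scenario: simulate.ScenarioConfig | None = None
    hits_path: str | None = None
    lineage_path: str | None = None
    metadata_path: str | None = None
    fastq_path: str | None = None
    kitome_neg_rate: float = 0.0003
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.threshold <= 0:
            raise ValidationError("enrichment threshold must be positive")
        if self.mode == "files":
            for name in ("hits_path", "lineage_path", "metadata_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValidationError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ValidationError(f"{name} does not exist: {p}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "qc" in raw and isinstance(raw["qc"], dict):
            raw["qc"] = QCConfig(**raw["qc"])
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        scenario = raw.pop("scenario", None)
        cfg = cls(**raw)
        if scenario is not None and cfg.mode == "synthetic":
            cfg.scenario = simulate.default_scenario(seed=cfg.seed, **scenario)
        return cfg


def _fingerprint(config: RunConfig) -> str:
    """Stable hash of the run configuration (scenario arrays included)."""
    parts: dict = {
        "mode": config.mode,
        "seed": int(config.seed),
        "threshold": config.threshold,
        "target_depth": config.target_depth,
        "ranks": list(config.ranks),
        "qc": vars(config.qc).copy(),
        "kitome_neg_rate": config.kitome_neg_rate,
        "paths": [config.hits_path, config.lineage_path, config.metadata_path,
                  config.fastq_path],
    }
    sc = config.scenario
    if sc is not None:
        parts["scenario"] = {
            "participants": list(sc.participant_ids),
            "effect_size": sc.effect_size,
            "depth": sc.depth,
            "concentration": sc.concentration,
            "contamination_rate": sc.contamination_rate,
            "off_window_fraction": sc.off_window_fraction,
            "infection": list(sc.infection_participants),
            "base_abundance_sha": hashlib.sha256(
                sc.base_abundance.to_csv().encode()
            ).hexdigest(),
            "gradient_sha": hashlib.sha256(
                sc.gradient_class.to_csv().encode()
            ).hexdigest(),
        }
    return hashlib.sha256(json.dumps(parts, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _fingerprint(config),
        "seed": int(config.seed),
        "mode": config.mode,
        "stages": {},
        "results": {},
    }

    # --- ingestion -------------------------------------------------------
    try:
        if config.mode == "synthetic":
            scenario = config.scenario or simulate.default_scenario(seed=config.seed)
            truth = simulate.build_scenario(scenario)
            hits = simulate.sample_reads(truth, scenario, seed=config.seed, qc=config.qc)
            metadata = simulate.sample_metadata(scenario)
            lineage = scenario.taxonomy
            io.write_hits(hits, outdir / "hits_raw.tsv")
            io.write_lineage(lineage, outdir / "lineage.tsv")
            io.write_metadata(metadata, outdir / "metadata.tsv")
            truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t")
        else:
            hits = io.read_hits(config.hits_path)
            lineage = io.read_lineage(config.lineage_path)
            metadata = io.read_metadata(config.metadata_path)
            if config.fastq_path:
                hits = io.attach_read_lengths(
                    hits, io.read_fastq_lengths(config.fastq_path)
                )
    except ValidationError as err:
        raise StageError("ingest", str(err)) from err
    manifest["stages"]["ingest"] = {"reads_in": int(len(hits)),
                                    "samples": int(metadata["sample_id"].nunique())}

    # --- hit QC ----------------------------------------------------------
    try:
        if len(hits) == 0:
            raise ValidationError("empty hit table")
        after_len = qc.filter_read_lengths(hits, config.qc)
        after_hits = qc.filter_hits(after_len, config.qc)
        top = qc.select_top_hit(after_hits)
        summary = qc.qc_summary(hits, after_len, after_hits)
        io.dump_json(summary, outdir / "qc_summary.json")
        io.write_hits(top, outdir / "hits_filtered.tsv")
    except ValidationError as err:
        raise StageError("hit_qc", str(err)) from err
    manifest["stages"]["hit_qc"] = {
        "reads_in": int(len(hits)),
        "reads_after_length_filter": int(len(after_len)),
        "reads_after_hit_filter": int(len(after_hits)),
        "reads_top_hit": int(len(top)),
    }

    # --- taxonomy profiling ---------------------------------------------
    try:
        tables = {r: taxprofile.aggregate_counts(top, lineage, r) for r in config.ranks}
        for r, table in tables.items():
            io.write_count_table(table, outdir / f"counts_{r}.tsv")
            io.write_count_table(
                taxprofile.relative_abundance(table), outdir / f"relabund_{r}.tsv"
            )
        species_table = tables.get("species") or taxprofile.aggregate_counts(
            top, lineage, "species"
        )
        phylum_table = tables.get("phylum") or taxprofile.aggregate_counts(
            top, lineage, "phylum"
        )
        phyla, coverage = taxprofile.dominant_phyla(phylum_table)
        n_species_detected = int(
            (species_table.pooled() > 0).sum()
            - (UNCLASSIFIED in species_table.taxa)
        )
    except ValidationError as err:
        raise StageError("taxonomy_profile", str(err)) from err
    manifest["stages"]["taxonomy_profile"] = {
        "assignments": int(species_table.total()),
        "species_detected": n_species_detected,
    }
    manifest["results"]["dominant_phyla"] = phyla
    manifest["results"]["dominant_phyla_coverage"] = round(float(coverage), 6)

    # --- enrichment ------------------------------------------------------
    try:
        profiles = enrichment.build_profiles(species_table, metadata)
        results, skipped = {}, []
        for pid, profile in sorted(profiles.items()):
            try:
                results[pid] = enrichment.analyze_participant(
                    profile, threshold=config.threshold, target_depth=config.target_depth
                )
            except enrichment.MissingCompartmentError as err:
                skipped.append(pid)
                logger.warning(str(err))
        if results:
            frames = [res.to_frame() for _, res in sorted(results.items())]
            pd.concat(frames).to_csv(outdir / "enrichment.tsv", sep="\t")
            heat = enrichment.heatmap_matrix(results, config.threshold)
            heat.to_csv(outdir / "heatmap.tsv", sep="\t")
            union_enriched = set().union(*(r.enriched for r in results.values()))
            frac = enrichment.enriched_fraction(len(union_enriched), n_species_detected)
        else:
            union_enriched, frac, heat = set(), float("nan"), pd.DataFrame()
    except ValidationError as err:
        raise StageError("enrichment", str(err)) from err
    manifest["stages"]["enrichment"] = {
        "participants_analyzed": len(results),
        "participants_skipped": skipped,
        "enriched_species_union": len(union_enriched),
        "heatmap_rows": int(len(heat)),
    }
    manifest["results"]["enriched_fraction_pct"] = (
        round(float(frac), 4) if np.isfinite(frac) else None
    )

    # --- diversity / ordination -----------------------------------------
    try:
        normalized_profiles = {
            pid: enrichment.normalize_counts(p, config.target_depth)
            for pid, p in profiles.items()
        }
        dm = diversity.bray_curtis_matrix(species_table)
        dm.to_frame().to_csv(outdir / "braycurtis_species.tsv", sep="\t")
        if len(species_table.samples) >= 3:
            ord_res = diversity.ordinate(dm, "pcoa_braycurtis")
            ord_res.scores.to_csv(outdir / "pcoa_scores.tsv", sep="\t")
            io.dump_json(
                {"explained_pct": [round(float(v), 6) for v in ord_res.explained_pct]},
                outdir / "pcoa_variance.json",
            )
            manifest["results"]["pcoa_pc1_pct"] = round(float(ord_res.explained_pct[0]), 4)
            manifest["results"]["pcoa_pc2_pct"] = (
                round(float(ord_res.explained_pct[1]), 4)
                if len(ord_res.explained_pct) > 1 else None
            )
        try:
            mean, sd, per_part = diversity.compartment_dissimilarity_summary(
                normalized_profiles, ("LAV", "throat")
            )
            per_part.to_csv(outdir / "bc_lav_throat.tsv", sep="\t")
            manifest["results"]["bc_lav_throat_mean"] = round(mean, 4)
            manifest["results"]["bc_lav_throat_sd"] = (
                round(sd, 4) if np.isfinite(sd) else None
            )
        except ValidationError:
            logger.warning("no participant pair for LAV-throat dissimilarity")
    except ValidationError as err:
        raise StageError("diversity_ordination", str(err)) from err
    manifest["stages"]["diversity_ordination"] = {
        "samples": int(len(species_table.samples))
    }

    # --- kitome ----------------------------------------------------------
    try:
        kit = None
        if config.mode == "synthetic":
            scenario = config.scenario or simulate.default_scenario(seed=config.seed)
            neg, pos = simulate.kitome_pair(
                scenario, config.kitome_neg_rate, seed=config.seed, qc=config.qc
            )
            neg_n = len(qc.filter_hits(qc.filter_read_lengths(neg, config.qc), config.qc))
            pos_n = len(qc.filter_hits(qc.filter_read_lengths(pos, config.qc), config.qc))
            if pos_n > 0:
                kit = qc.kitome_contamination(neg_n, pos_n)
        elif "library_type" in metadata.columns:
            neg_ids = metadata.loc[metadata["library_type"] == "pcr_negative", "sample_id"]
            pos_ids = metadata.loc[metadata["library_type"] == "pcr_positive", "sample_id"]
            if len(neg_ids) and len(pos_ids):
                neg_n = int(top["sample_id"].isin(neg_ids).sum())
                pos_n = int(top["sample_id"].isin(pos_ids).sum())
                if pos_n > 0:
                    kit = qc.kitome_contamination(neg_n, pos_n)
        if kit is not None:
            io.dump_json(
                {
                    "neg_count": kit.neg_count,
                    "pos_count": kit.pos_count,
                    "contamination_pct": kit.contamination_pct,
                    "fold_difference": kit.fold_difference,
                },
                outdir / "kitome.json",
            )
            manifest["results"]["kitome_contamination_pct"] = round(
                kit.contamination_pct, 4
            )
    except ValidationError as err:
        raise StageError("kitome", str(err)) from err

    io.dump_json(manifest, outdir / "manifest.json")
    return manifest


def summary_report(manifest: dict) -> str:
    """Human-readable run summary mirroring a profiling study's skeleton."""
    s, r = manifest["stages"], manifest["results"]
    lines = [
        "respiratome run summary",
        "=======================",
        f"mode: {manifest['mode']}   seed: {manifest['seed']}",
        f"config hash: {manifest['config_hash'][:16]}",
        "",
        f"reads in:                  {s['ingest']['reads_in']:>10,}",
        f"after size selection:      {s['hit_qc']['reads_after_length_filter']:>10,}",
        f"after identity/aln QC:     {s['hit_qc']['reads_after_hit_filter']:>10,}",
        f"top hits (assigned reads): {s['hit_qc']['reads_top_hit']:>10,}",
        "",
        f"species detected:          {s['taxonomy_profile']['species_detected']:>10,}",
        f"dominant phyla:            {', '.join(r.get('dominant_phyla', []))}",
        f"dominant-phyla coverage:   {100 * r.get('dominant_phyla_coverage', float('nan')):.2f}%",
        "",
        f"participants analyzed:     {s['enrichment']['participants_analyzed']}"
        + (f" (skipped: {', '.join(s['enrichment']['participants_skipped'])})"
           if s["enrichment"]["participants_skipped"] else ""),
        f"lung-enriched species:     {s['enrichment']['enriched_species_union']}",
    ]
    if r.get("enriched_fraction_pct") is not None:
        lines.append(f"enriched fraction:         {r['enriched_fraction_pct']:.2f}% of detected species")
    if r.get("bc_lav_throat_mean") is not None:
        sd = r.get("bc_lav_throat_sd")
        lines.append(
            f"Bray-Curtis LAV vs throat: {r['bc_lav_throat_mean']:.2f}"
            + (f" +/- {sd:.2f}" if sd is not None else "")
        )
    if r.get("pcoa_pc1_pct") is not None:
        pc2 = r.get("pcoa_pc2_pct")
        lines.append(
            f"PCoA variance explained:   PC1 {r['pcoa_pc1_pct']:.1f}%"
            + (f", PC2 {pc2:.1f}%" if pc2 is not None else "")
        )
    if r.get("kitome_contamination_pct") is not None:
        lines.append(f"kitome contamination:      {r['kitome_contamination_pct']:.2f}%")
    return "\n".join(lines) + "\n"
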