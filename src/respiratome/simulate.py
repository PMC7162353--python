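"""Synthetic multi-compartment respiratory communities with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-compartment species abundance profiles over a taxonomy
dominated by five phyla, monotone abundance gradients along the
nose/mouth -> throat -> lung axis (planted ``inside_out`` and
``outside_in`` species, with the throat at the geometric midpoint),
infection-displacement of the lavage community in selected participants,
nanopore-like percent-identity / read-length / alignment-length
distributions, trace reagent ("kitome") contamination, and a configurable
fraction of reads deliberately generated outside the QA/QC windows.

Read counts are drawn Dirichlet-multinomial around the expected
proportions. The overdispersion knob ``concentration`` is a per-taxon
scale: the Dirichlet parameter is ``concentration * n_species * p``, so
the total concentration grows with community size and the default of 200
gives a coefficient of variation of roughly 12-15% for taxa observed at
~100 reads at a depth of 5e4 — the replicate variability long-read operon
counts show in practice.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning; equal (config, seed) gives
byte-identical output after serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    COMPARTMENTS,
    LineageTable,
    ValidationError,
    participant_sample_id,
)
from .qc import QCConfig

GRADIENT_CLASSES = ("inside_out", "outside_in", "flat")

_DOMINANT_PHYLA = {
    "Firmicutes": {
        "weight": 0.40,
        "genera": {
            "Streptococcus": ("Streptococcaceae", ["infantis", "mitis", "parasanguinis", "oralis"]),
            "Veillonella": ("Veillonellaceae", ["dispar", "atypica", "tobetsuensis", "rogosae"]),
            "Megasphaera": ("Veillonellaceae", ["micronuciformis"]),
            "Staphylococcus": ("Staphylococcaceae", []),
            "Lactobacillus": ("Lactobacillaceae", []),
        },
    },
    "Proteobacteria": {
        "weight": 0.25,
        "genera": {
            "Neisseria": ("Neisseriaceae", []),
            "Campylobacter": ("Campylobacteraceae", []),
            "Haemophilus": ("Pasteurellaceae", []),
            "Pseudomonas": ("Pseudomonadaceae", ["aeruginosa"]),
            "Pantoea": ("Erwiniaceae", []),
            "Tatumella": ("Erwiniaceae", ["ptyseos"]),
            "Citrobacter": ("Enterobacteriaceae", ["youngae"]),
        },
    },
    "Actinobacteria": {
        "weight": 0.15,
        "genera": {
            "Actinomyces": ("Actinomycetaceae", []),
            "Propionibacterium": ("Propionibacteriaceae", []),
            "Rothia": ("Micrococcaceae", []),
            "Corynebacterium": ("Corynebacteriaceae", []),
        },
    },
    "Bacteroidetes": {
        "weight": 0.12,
        "genera": {
            "Prevotella": ("Prevotellaceae", []),
            "Porphyromonas": ("Porphyromonadaceae", []),
            "Capnocytophaga": ("Flavobacteriaceae", []),
        },
    },
    "Fusobacteria": {
        "weight": 0.08,
        "genera": {
            "Fusobacterium": ("Fusobacteriaceae", []),
            "Leptotrichia": ("Leptotrichiaceae", []),
        },
    },
}

_MINOR_PHYLA = {
    "Spirochaetes": {
        "Treponema": ("Spirochaetaceae", []),
        "Brachyspira": ("Brachyspiraceae", []),
    },
    "Tenericutes": {
        "Mycoplasma": ("Mycoplasmataceae", []),
        "Ureaplasma": ("Mycoplasmataceae", []),
    },
}

#: Classic reagent-contaminant lineages (kitome pool); not part of the
#: biological community, drawn only through the contamination channel.
_REAGENT_LINEAGES = (
    ("Ralstonia pickettii", "Ralstonia", "Burkholderiaceae", "Proteobacteria"),
    ("Bradyrhizobium kitense", "Bradyrhizobium", "Bradyrhizobiaceae", "Proteobacteria"),
)


def default_taxonomy(n_species: int = 200) -> tuple[LineageTable, tuple[str, ...]]:
    """Build a deterministic study-like taxonomy with ``n_species`` community species.

    Species are spread over five dominant phyla (plus two minor phyla with
    eight species total) using the approximate phylum weights seen in
    respiratory communities; well-known respiratory species are named
    first, the rest filled with ``Genus sp###`` placeholders. Returns the
    lineage table (community + reagent taxa) and the reagent taxon ids.
    """
    if n_species < 60:
        raise ValidationError("default taxonomy needs at least 60 species")
    n_minor = sum(2 for ph in _MINOR_PHYLA for _ in _MINOR_PHYLA[ph])  # 2 species/genus
    n_dominant = n_species - n_minor

    records: list[dict] = []

    def add_species(genus: str, family: str, phylum: str, epithet: str) -> None:
        records.append(
            {
                "taxon_id": f"EZB{len(records) + 1:05d}",
                "species": f"{genus} {epithet}",
                "genus": genus,
                "family": family,
                "phylum": phylum,
            }
        )

    weights = np.array([info["weight"] for info in _DOMINANT_PHYLA.values()])
    min_alloc = np.array([2 * len(info["genera"]) for info in _DOMINANT_PHYLA.values()])
    raw = weights / weights.sum() * n_dominant
    alloc = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - alloc))[: n_dominant - alloc.sum()]:
        alloc[i] += 1
    alloc = np.maximum(alloc, min_alloc)  # every genus gets >= 2 species
    while alloc.sum() > n_dominant:
        alloc[int(np.argmax(alloc - min_alloc))] -= 1

    for (phylum, info), n_ph in zip(_DOMINANT_PHYLA.items(), alloc):
        genera = list(info["genera"].items())
        targets = {g: 2 for g, _ in genera}
        gi = 0
        while sum(targets.values()) < n_ph:
            targets[genera[gi % len(genera)][0]] += 1
            gi += 1
        for genus, (family, named) in genera:
            epithets = list(named[: targets[genus]])
            k = 0
            while len(epithets) < targets[genus]:
                k += 1
                epithets.append(f"sp{k:03d}")
            for epithet in epithets:
                add_species(genus, family, phylum, epithet)

    for phylum, genera in _MINOR_PHYLA.items():
        for genus, (family, _) in genera.items():
            for k in (1, 2):
                add_species(genus, family, phylum, f"sp{k:03d}")

    reagent_ids = []
    for species, genus, family, phylum in _REAGENT_LINEAGES:
        records.append(
            {
                "taxon_id": f"EZB{len(records) + 1:05d}",
                "species": species,
                "genus": genus,
                "family": family,
                "phylum": phylum,
            }
        )
        reagent_ids.append(records[-1]["taxon_id"])

    return LineageTable.from_records(records), tuple(reagent_ids)


@dataclass
class ScenarioConfig:
    """Full description of one synthetic study.

    ``base_abundance`` is the species relative-abundance vector of the
    "outer" (mouth/nose) pool, on the simplex over community species.
    ``gradient_class`` plants each species' compartment pattern;
    ``effect_size`` is the total outer-to-lung fold-change applied to
    non-flat species. ``concentration`` is the per-taxon
    Dirichlet-multinomial scale (see module docstring).
    """

    taxonomy: LineageTable
    base_abundance: pd.Series
    gradient_class: pd.Series
    reagent_taxa: tuple[str, ...] = ()
    n_participants: int = 5
    participant_ids: tuple[str, ...] | None = None
    effect_size: float = 4.0
    depth: int = 25_000
    concentration: float = 200.0
    infection_participants: tuple[str, ...] = ()
    infection_genera: tuple[str, ...] = ("Pseudomonas", "Pantoea", "Tatumella")
    infection_mass: float = 0.6
    contamination_rate: float = 0.0003
    off_window_fraction: float = 0.04
    identity_model: tuple[float, float] = (85.0, 5.0)
    length_model: tuple[float, float] = (4400.0, 400.0)
    aln_model: tuple[float, float] = (1450.0, 120.0)
    missing_compartments: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participant_ids is None:
            self.participant_ids = tuple(f"P{i + 1:02d}" for i in range(self.n_participants))
        else:
            self.participant_ids = tuple(self.participant_ids)
            self.n_participants = len(self.participant_ids)
        self.validate()

    @property
    def community_species(self) -> pd.Index:
        return self.base_abundance.index

    def validate(self) -> None:
        lin = self.taxonomy.df
        community = lin.loc[~lin.index.isin(self.reagent_taxa)]
        if community["species"].duplicated().any():
            raise ValidationError("community species names must be unique")
        if community["phylum"].nunique() < 5:
            raise ValidationError("taxonomy needs at least 5 phyla")
        per_phylum = community.groupby("phylum")["genus"].nunique()
        if (per_phylum < 2).any():
            raise ValidationError("each phylum needs at least 2 genera")
        per_genus = community.groupby("genus")["species"].nunique()
        if (per_genus < 2).any():
            raise ValidationError("each genus needs at least 2 species")
        if set(self.base_abundance.index) != set(community["species"]):
            raise ValidationError("base_abundance must cover exactly the community species")
        if (self.base_abundance < 0).any():
            raise ValidationError("base_abundance must be non-negative")
        if abs(self.base_abundance.sum() - 1.0) > 1e-9:
            raise ValidationError("base_abundance must sum to 1 within 1e-9")
        if set(self.gradient_class.index) != set(self.base_abundance.index):
            raise ValidationError("gradient_class must cover exactly the community species")
        bad = set(self.gradient_class.unique()) - set(GRADIENT_CLASSES)
        if bad:
            raise ValidationError(f"unknown gradient classes {sorted(bad)}")
        if not self.effect_size > 1:
            raise ValidationError("effect_size must be > 1")
        if not self.depth >= 0:
            raise ValidationError("depth must be non-negative")
        if not self.concentration > 0:
            raise ValidationError("concentration must be positive")
        if not (0 <= self.contamination_rate <= 1):
            raise ValidationError("contamination_rate must lie in [0, 1]")
        if not (0 <= self.off_window_fraction):
            raise ValidationError("off_window_fraction must be non-negative")
        if not self.contamination_rate + self.off_window_fraction < 1:
            raise ValidationError("contamination_rate + off_window_fraction must be < 1")
        if self.contamination_rate > 0 and not self.reagent_taxa:
            raise ValidationError("contamination requires reagent taxa")
        unknown_reagent = [t for t in self.reagent_taxa if t not in self.taxonomy]
        if unknown_reagent:
            raise ValidationError(f"reagent taxa missing from taxonomy: {unknown_reagent}")
        unknown_part = set(self.infection_participants) - set(self.participant_ids)
        if unknown_part:
            raise ValidationError(f"unknown infection participants {sorted(unknown_part)}")
        if not (0 < self.infection_mass < 1):
            raise ValidationError("infection_mass must lie in (0, 1)")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")

    def species_to_taxon(self) -> pd.Series:
        """species name -> taxon id over the whole taxonomy."""
        return pd.Series(self.taxonomy.df.index.values, index=self.taxonomy.df["species"].values)


@dataclass
class TruthTable:
    """Planted ground truth for one scenario.

    ``expected``: (participant, species) x compartment expected proportions.
    ``labels``: (participant, species) -> gradient_class, is_lung_enriched.
    """

    expected: pd.DataFrame
    labels: pd.DataFrame

    def participants(self) -> tuple[str, ...]:
        return tuple(self.expected.index.get_level_values(0).unique())

    def participant_expected(self, participant_id: str) -> pd.DataFrame:
        return self.expected.loc[participant_id]

    def n_enriched_species(self) -> int:
        flagged = self.labels.loc[self.labels["is_lung_enriched"]]
        return flagged.index.get_level_values("species").nunique()

    def to_frame(self) -> pd.DataFrame:
        return self.expected.join(self.labels)


def _compartment_weights(config: ScenarioConfig) -> pd.DataFrame:
    """Unnormalized per-compartment abundance weights for community species."""
    b = config.base_abundance.astype(float)
    e = float(config.effect_size)
    cls = config.gradient_class.reindex(b.index)
    lav_factor = pd.Series(1.0, index=b.index)
    lav_factor[cls == "inside_out"] = e
    lav_factor[cls == "outside_in"] = 1.0 / e
    throat_factor = np.sqrt(lav_factor)  # geometric midpoint between outer and lung
    return pd.DataFrame(
        {
            "LAV": b * lav_factor,
            "throat": b * throat_factor,
            "mouth": b,
            "nose": b,
        }
    )


def _displace_lav(lav: pd.Series, config: ScenarioConfig) -> pd.Series:
    """Reallocate ``infection_mass`` of the lavage vector to the infection genera."""
    species_genus = (
        config.taxonomy.df.drop_duplicates("species").set_index("species")["genus"]
    )
    in_set = species_genus.reindex(lav.index).isin(config.infection_genera)
    if not in_set.any():
        raise ValidationError("infection genera not present in community taxonomy")
    m = config.infection_mass
    out = lav.copy()
    set_mass = lav[in_set].sum()
    if set_mass > 0:
        out[in_set] = lav[in_set] / set_mass * m
    else:
        out[in_set] = m / in_set.sum()
    rest_mass = lav[~in_set].sum()
    out[~in_set] = lav[~in_set] / rest_mass * (1.0 - m)
    return out


def build_scenario(config: ScenarioConfig) -> TruthTable:
    """Turn a scenario config into expected proportions and planted labels.

    Inside-out species rise monotonically from the outer pool through the
    throat (geometric midpoint) to the lavage with a total fold-change of
    ``effect_size``; outside-in species fall in the reverse direction;
    flat species are equal everywhere. Each compartment vector is
    renormalized to the simplex. Infected participants have
    ``infection_mass`` of their lavage vector reallocated to the infection
    genera.
    """
    config.validate()
    weights = _compartment_weights(config)
    base_profile = weights / weights.sum(axis=0)

    frames, label_frames = [], []
    for pid in config.participant_ids:
        prof = base_profile.copy()
        infected = pid in config.infection_participants
        if infected:
            prof["LAV"] = _displace_lav(prof["LAV"], config)
        idx = pd.MultiIndex.from_product(
            [[pid], prof.index], names=["participant_id", "species"]
        )
        frames.append(prof.set_index(idx))
        labels = pd.DataFrame(
            {
                "gradient_class": config.gradient_class.reindex(prof.index).values,
                "is_lung_enriched": (
                    (config.gradient_class.reindex(prof.index) == "inside_out") & ~infected
                ).values,
            },
            index=idx,
        )
        label_frames.append(labels)

    return TruthTable(pd.concat(frames), pd.concat(label_frames))


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd <= 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_one(
    sample_id: str,
    proportions: pd.Series,
    taxon_of: pd.Series,
    config: ScenarioConfig,
    qc: QCConfig,
    rng: np.random.Generator,
    contamination_rate: float | None = None,
) -> pd.DataFrame:
    """Draw one sample's reads: DM counts, per-read metrics, planted off-window reads."""
    depth = int(config.depth)
    cols = ["read_id", "taxon_id", "pct_identity", "aln_length", "bit_score",
            "read_length", "sample_id"]
    if depth == 0:
        return pd.DataFrame(columns=cols)
    rate = config.contamination_rate if contamination_rate is None else contamination_rate
    n_contam = int(round(rate * depth))
    n_body = depth - n_contam

    taxa_parts = []
    if n_body > 0:
        pos = proportions[proportions > 0]
        alpha = config.concentration * len(proportions) * pos.to_numpy()
        q = rng.dirichlet(alpha)
        counts = rng.multinomial(n_body, q)
        taxa_parts.append(np.repeat(taxon_of.reindex(pos.index).to_numpy(), counts))
    if n_contam > 0:
        reagent = np.asarray(config.reagent_taxa)
        counts = rng.multinomial(n_contam, np.full(len(reagent), 1.0 / len(reagent)))
        taxa_parts.append(np.repeat(reagent, counts))
    taxa = np.concatenate(taxa_parts)
    is_contam = np.concatenate(
        [np.zeros(n_body, dtype=bool), np.ones(n_contam, dtype=bool)]
    )
    perm = rng.permutation(depth)
    taxa, is_contam = taxa[perm], is_contam[perm]

    id_mean, id_sd = config.identity_model
    len_mean, len_sd = config.length_model
    aln_mean, aln_sd = config.aln_model
    identity = _truncnorm_draw(rng, id_mean, id_sd, qc.id_min, qc.id_max, depth)
    lengths = _truncnorm_draw(rng, len_mean, len_sd, qc.len_min, qc.len_max, depth)
    aln = _truncnorm_draw(rng, aln_mean, aln_sd, qc.aln_min + 1.0, np.inf, depth)

    n_off = int(round(config.off_window_fraction * depth))
    if n_off > 0:
        body_pos = np.flatnonzero(~is_contam)
        off_idx = rng.choice(body_pos, size=min(n_off, len(body_pos)), replace=False)
        kinds = rng.integers(0, 5, size=len(off_idx))
        for j, kind in zip(off_idx, kinds):
            if kind == 0:  # identity below window
                identity[j] = rng.uniform(max(30.0, qc.id_min - 30.0), qc.id_min - 0.01)
            elif kind == 1:  # identity above window
                identity[j] = rng.uniform(qc.id_max + 0.01, 100.0)
            elif kind == 2:  # alignment too short (<= aln_min fails the strict bound)
                aln[j] = rng.integers(200, int(qc.aln_min) + 1)
            elif kind == 3:  # read shorter than size selection
                lengths[j] = rng.integers(1000, int(qc.len_min))
            else:  # read longer than size selection
                lengths[j] = rng.integers(int(qc.len_max) + 1, int(qc.len_max) + 2001)

    identity = np.round(identity, 3)
    lengths = np.round(lengths).astype(int)
    aln = np.round(aln).astype(int)
    bit = np.round(aln * identity / 100.0 * rng.uniform(1.6, 1.9, depth), 1)

    return pd.DataFrame(
        {
            "read_id": [f"{sample_id}_r{i:06d}" for i in range(depth)],
            "taxon_id": taxa,
            "pct_identity": identity,
            "aln_length": aln,
            "bit_score": bit,
            "read_length": lengths,
            "sample_id": sample_id,
        }
    )


def _sample_plan(config: ScenarioConfig) -> list[tuple[str, str]]:
    plan = []
    for pid in config.participant_ids:
        absent = set(config.missing_compartments.get(pid, ()))
        for comp in COMPARTMENTS:
            if comp not in absent:
                plan.append((pid, comp))
    return plan


def sample_reads(
    truth: TruthTable,
    config: ScenarioConfig,
    seed: int | None = None,
    qc: QCConfig | None = None,
) -> pd.DataFrame:
    """Draw per-read hit records for every sample in the scenario.

    Counts are Dirichlet-multinomial around the truth proportions; each
    read carries identity, alignment length, bit score and read length.
    An ``off_window_fraction`` of reads is forced outside at least one QC
    window; a ``contamination_rate`` fraction is drawn from the reagent
    pool (and kept inside the QC windows, as reagent reads survive QC in
    practice). Same (config, seed) -> bit-identical output.
    """
    if seed is None:
        seed = config.seed
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValidationError("seed must be a non-negative integer")
    qc = qc or QCConfig()
    taxon_of = config.species_to_taxon()
    plan = _sample_plan(config)
    children = np.random.SeedSequence(int(seed)).spawn(len(plan))
    frames = []
    for (pid, comp), child in zip(plan, children):
        rng = np.random.default_rng(child)
        props = truth.participant_expected(pid)[comp]
        sid = participant_sample_id(pid, comp)
        frames.append(_sample_one(sid, props, taxon_of, config, qc, rng))
    if not frames:
        return pd.DataFrame(
            columns=["read_id", "taxon_id", "pct_identity", "aln_length",
                     "bit_score", "read_length", "sample_id"]
        )
    return pd.concat(frames, ignore_index=True)


def sample_metadata(config: ScenarioConfig) -> pd.DataFrame:
    """Sample sheet for the scenario (sample id, participant, compartment)."""
    rows = [
        {
            "sample_id": participant_sample_id(pid, comp),
            "participant_id": pid,
            "compartment": comp,
            "library_type": "sample",
        }
        for pid, comp in _sample_plan(config)
    ]
    return pd.DataFrame(rows)


def kitome_pair(
    config: ScenarioConfig,
    neg_rate: float,
    seed: int | None = None,
    qc: QCConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a PCR-negative / PCR-positive library pair.

    The positive library is an ordinary sample (first participant's
    lavage profile). The negative library holds only reagent-taxon reads,
    Poisson-distributed around ``neg_rate`` times the positive depth.
    Returns ``(negative, positive)`` hit tables.
    """
    if not (0 <= neg_rate < 1):
        raise ValidationError("neg_rate must lie in [0, 1)")
    if seed is None:
        seed = config.seed
    if not (isinstance(seed, (int, np.integer)) and seed >= 0):
        raise ValidationError("seed must be a non-negative integer")
    qc = qc or QCConfig()
    truth = build_scenario(config)
    taxon_of = config.species_to_taxon()
    ss_pos, ss_neg = np.random.SeedSequence(int(seed)).spawn(2)

    rng_pos = np.random.default_rng(ss_pos)
    props = truth.participant_expected(config.participant_ids[0])["LAV"]
    pos = _sample_one("pcr_positive", props, taxon_of, config, qc, rng_pos)

    rng_neg = np.random.default_rng(ss_neg)
    n_neg = int(rng_neg.poisson(neg_rate * len(pos)))
    if n_neg == 0 or not config.reagent_taxa:
        neg = pos.iloc[0:0].copy()
    else:
        reagent = np.asarray(config.reagent_taxa)
        counts = rng_neg.multinomial(n_neg, np.full(len(reagent), 1.0 / len(reagent)))
        id_mean, id_sd = config.identity_model
        len_mean, len_sd = config.length_model
        aln_mean, aln_sd = config.aln_model
        identity = np.round(
            _truncnorm_draw(rng_neg, id_mean, id_sd, qc.id_min, qc.id_max, n_neg), 3
        )
        lengths = np.round(
            _truncnorm_draw(rng_neg, len_mean, len_sd, qc.len_min, qc.len_max, n_neg)
        ).astype(int)
        aln = np.round(
            _truncnorm_draw(rng_neg, aln_mean, aln_sd, qc.aln_min + 1.0, np.inf, n_neg)
        ).astype(int)
        neg = pd.DataFrame(
            {
                "read_id": [f"pcr_negative_r{i:06d}" for i in range(n_neg)],
                "taxon_id": np.repeat(reagent, counts),
                "pct_identity": identity,
                "aln_length": aln,
                "bit_score": np.round(aln * identity / 100.0 * rng_neg.uniform(1.6, 1.9, n_neg), 1),
                "read_length": lengths,
                "sample_id": "pcr_negative",
            }
        )
    return neg, pos


def default_scenario(
    n_species: int = 200,
    n_inside_out: int = 20,
    n_outside_in: int = 60,
    effect_size: float = 4.0,
    depth: int = 25_000,
    n_participants: int = 5,
    concentration: float = 200.0,
    seed: int = 0,
    abundance_sigma: float = 0.5,
    minor_phylum_mass: float = 0.015,
    **overrides,
) -> ScenarioConfig:
    """Construct a study-like scenario with planted gradient classes.

    Base abundances are lognormal weights (``sigma=abundance_sigma``,
    moderate rank-abundance spread) over dominant-phylum species, with a
    fixed small mass on the minor phyla so the five dominant phyla carry
    >98% of reads. Gradient classes are planted uniformly at random.
    """
    taxonomy, reagent = default_taxonomy(n_species)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(1)[0])
    lin = taxonomy.df.loc[~taxonomy.df.index.isin(reagent)]
    species = lin["species"].to_numpy()
    minor = lin["phylum"].isin(_MINOR_PHYLA).to_numpy()

    w = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(species))
    base = np.empty(len(species))
    base[~minor] = w[~minor] / w[~minor].sum() * (1.0 - minor_phylum_mass)
    base[minor] = w[minor] / w[minor].sum() * minor_phylum_mass
    base_abundance = pd.Series(base, index=species)
    base_abundance /= base_abundance.sum()

    if n_inside_out + n_outside_in > len(species):
        raise ValidationError("more planted non-flat species than species available")
    picks = rng.choice(len(species), size=n_inside_out + n_outside_in, replace=False)
    classes = pd.Series("flat", index=species)
    classes.iloc[picks[:n_inside_out]] = "inside_out"
    classes.iloc[picks[n_inside_out:]] = "outside_in"

    return ScenarioConfig(
        taxonomy=taxonomy,
        base_abundance=base_abundance,
        gradient_class=classes,
        reagent_taxa=reagent,
        n_participants=n_participants,
        effect_size=effect_size,
        depth=depth,
        concentration=concentration,
        seed=seed,
        **overrides,
    )


def study_like_scenario(seed: int = 0, depth: int = 25_000, **overrides) -> ScenarioConfig:
    """Scenario mirroring the study design: five complete participants plus
    one lacking a lavage sample, and two participants whose lavage
    community is displaced by an infection genus set (Pseudomonas /
    Pantoea / Tatumella), with Veillonella-type species planted inside-out
    and Streptococcus-type species outside-in."""
    config = default_scenario(
        n_species=200,
        n_inside_out=20,
        n_outside_in=60,
        depth=depth,
        n_participants=6,
        seed=seed,
        participant_ids=("S01", "S06", "S07", "S08", "S12", "S15"),
        infection_participants=("S07", "S08"),
        missing_compartments={"S01": ("LAV",)},
        **overrides,
    )
    # anchor the narrative species to their field-known patterns
    genus = config.taxonomy.df.drop_duplicates("species").set_index("species")["genus"]
    cls = config.gradient_class.copy()
    cls[genus.reindex(cls.index) == "Veillonella"] = "inside_out"
    cls[genus.reindex(cls.index) == "Streptococcus"] = "outside_in"
    cls[genus.reindex(cls.index).isin(config.infection_genera)] = "flat"
    config.gradient_class = cls
    return config


def recovery_scores(
    truth: TruthTable,
    enriched_by_participant: Mapping[str, set],
    gradient_by_participant: Mapping[str, pd.Series] | None = None,
) -> dict:
    """Score enrichment calls (and optionally gradient calls) against truth.

    Precision/recall are over (participant, species) pairs for the
    participants present in ``enriched_by_participant``; gradient accuracy
    is over planted non-flat species.
    """
    tp = fp = fn = 0
    for pid, called in enriched_by_participant.items():
        labels = truth.labels.loc[pid]
        true_set = set(labels.index[labels["is_lung_enriched"]])
        called = set(called)
        tp += len(called & true_set)
        fp += len(called - true_set)
        fn += len(true_set - called)
    out = {
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
    }
    if gradient_by_participant is not None:
        n_ok = n_tot = 0
        for pid, calls in gradient_by_participant.items():
            labels = truth.labels.loc[pid]
            nonflat = labels.index[labels["gradient_class"] != "flat"]
            for sp in nonflat:
                if sp in calls.index:
                    n_tot += 1
                    n_ok += calls[sp] == labels.loc[sp, "gradient_class"]
        out["gradient_accuracy"] = n_ok / n_tot if n_tot else float("nan")
    return out
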