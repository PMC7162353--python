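"""Synthetic community generator: planted structure, sampling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import respiratome as r
from respiratome.containers import ValidationError
from respiratome.simulate import GRADIENT_CLASSES


def tiny_config(classes=None, effect_size=4.0, **overrides):
    """Minimal valid scenario: 5 phyla x 2 genera x 2 species, uniform base."""
    records = []
    for p in range(5):
        for g in range(2):
            for s in range(2):
                genus = f"G{p}{g}"
                records.append(
                    {"taxon_id": f"t{len(records)}", "species": f"{genus} sp{s}",
                     "genus": genus, "family": f"F{p}{g}", "phylum": f"P{p}"}
                )
    taxonomy = r.LineageTable.from_records(records)
    species = taxonomy.df["species"]
    base = pd.Series(1.0 / len(species), index=species.values)
    cls = pd.Series("flat", index=species.values)
    if classes:
        for sp, c in classes.items():
            cls[sp] = c
    kw = dict(depth=1000, n_participants=1, contamination_rate=0.0,
              off_window_fraction=0.0)
    kw.update(overrides)
    return r.ScenarioConfig(
        taxonomy=taxonomy, base_abundance=base, gradient_class=cls,
        effect_size=effect_size, **kw,
    )


class TestBuildScenario:
    def test_geometric_midpoint_fold_changes(self):
        """An inside-out species gains effect_size relative to flat species in
        the lavage and sqrt(effect_size) in the throat."""
        cfg = tiny_config({"G00 sp0": "inside_out"}, effect_size=4.0)
        truth = r.build_scenario(cfg)
        prof = truth.participant_expected("P01")
        rel = prof.loc["G00 sp0"] / prof.loc["G11 sp1"]  # flat reference species
        assert rel["LAV"] / rel["mouth"] == pytest.approx(4.0, abs=1e-12)
        assert rel["throat"] / rel["mouth"] == pytest.approx(2.0, abs=1e-12)

    def test_all_flat_gives_identical_compartments(self):
        cfg = tiny_config()
        prof = r.build_scenario(cfg).participant_expected("P01")
        for comp in ("throat", "mouth", "nose"):
            assert np.allclose(prof["LAV"], prof[comp], atol=1e-12)

    def test_planted_enriched_species_count(self):
        cfg = r.default_scenario(n_species=200, n_inside_out=20, seed=7)
        assert r.build_scenario(cfg).n_enriched_species() == 20

    def test_compartment_vectors_on_simplex(self, small_truth):
        for pid in small_truth.participants():
            prof = small_truth.participant_expected(pid)
            assert np.allclose(prof.sum(axis=0), 1.0, atol=1e-9)

    def test_gradient_monotonicity(self, small_scenario, small_truth):
        prof = small_truth.participant_expected("P01")
        outer = prof[["mouth", "nose"]].mean(axis=1)
        cls = small_scenario.gradient_class
        inside = cls.index[cls == "inside_out"]
        outside = cls.index[cls == "outside_in"]
        assert (prof.loc[inside, "LAV"] > prof.loc[inside, "throat"]).all()
        assert (prof.loc[inside, "throat"] > outer[inside]).all()
        assert (outer[outside] > prof.loc[outside, "throat"]).all()
        assert (prof.loc[outside, "throat"] > prof.loc[outside, "LAV"]).all()

    def test_infection_displacement_mass(self):
        cfg = r.default_scenario(
            n_species=100, seed=3, infection_participants=("P01",)
        )
        truth = r.build_scenario(cfg)
        genus = cfg.taxonomy.df.drop_duplicates("species").set_index("species")["genus"]
        lav = truth.participant_expected("P01")["LAV"]
        in_set = genus.reindex(lav.index).isin(cfg.infection_genera)
        assert lav[in_set].sum() == pytest.approx(cfg.infection_mass, abs=1e-9)
        assert lav.sum() == pytest.approx(1.0, abs=1e-9)
        # displaced participants lose their planted enrichment labels
        assert not truth.labels.loc["P01", "is_lung_enriched"].any()

    def test_inconsistent_taxonomy_rejected(self):
        records = [
            {"taxon_id": "a", "species": "X y", "genus": "G1",
             "family": "F", "phylum": "P"},
            {"taxon_id": "b", "species": "X y", "genus": "G2",
             "family": "F", "phylum": "P"},
        ]
        with pytest.raises(ValidationError):
            r.LineageTable.from_records(records)

    @pytest.mark.parametrize(
        "kw", [
            {"effect_size": 1.0},
            {"contamination_rate": 0.6, "off_window_fraction": 0.5},
            {"infection_participants": ("nobody",)},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            tiny_config(**kw)


class TestSampleReads:
    def test_depth_exact_without_contamination(self):
        cfg = tiny_config(depth=10_000)
        hits = r.sample_reads(r.build_scenario(cfg), cfg)
        assert hits.groupby("sample_id").size().eq(10_000).all()

    def test_seed_determinism_is_bytewise(self, small_scenario, small_truth):
        a = r.sample_reads(small_truth, small_scenario, seed=42)
        b = r.sample_reads(small_truth, small_scenario, seed=42)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seeds_differ(self, small_scenario, small_truth):
        a = r.sample_reads(small_truth, small_scenario, seed=1)
        b = r.sample_reads(small_truth, small_scenario, seed=2)
        assert not a["taxon_id"].equals(b["taxon_id"])

    def test_negative_seed_rejected(self, small_scenario, small_truth):
        with pytest.raises(ValidationError):
            r.sample_reads(small_truth, small_scenario, seed=-1)

    def test_zero_depth_gives_empty_sample(self):
        cfg = tiny_config(depth=0)
        hits = r.sample_reads(r.build_scenario(cfg), cfg)
        assert len(hits) == 0

    def test_empirical_ratio_tracks_truth(self):
        """Monte-Carlo: observed lavage/outer count ratio for an inside-out
        species stays within 10% of the planted ratio at depth 5e4."""
        cfg = r.default_scenario(
            n_species=200, n_inside_out=20, effect_size=4.0,
            depth=50_000, n_participants=1, seed=3,
        )
        truth = r.build_scenario(cfg)
        hits = r.sample_reads(truth, cfg)
        prof = truth.participant_expected("P01")
        inside = cfg.gradient_class.index[cfg.gradient_class == "inside_out"]
        sp = prof.loc[inside, "LAV"].idxmax()  # most abundant planted species
        taxon = cfg.species_to_taxon()[sp]
        counts = hits[hits["taxon_id"] == taxon].groupby("sample_id").size()
        obs = counts["P01_LAV"] / ((counts["P01_mouth"] + counts["P01_nose"]) / 2)
        expect = prof.loc[sp, "LAV"] / prof.loc[sp, "mouth"]
        assert obs == pytest.approx(expect, rel=0.10)

    def test_empirical_proportions_within_three_se(self):
        """At depth 5e4, nearly all per-species sample proportions sit within
        3 Dirichlet-multinomial standard errors of the planted truth."""
        cfg = r.default_scenario(
            n_species=200, depth=50_000, n_participants=1, seed=9,
            contamination_rate=0.0, off_window_fraction=0.0,
        )
        truth = r.build_scenario(cfg)
        hits = r.sample_reads(truth, cfg)
        taxon_of = cfg.species_to_taxon()
        prof = truth.participant_expected("P01")
        n, c_total = cfg.depth, cfg.concentration * len(cfg.base_abundance)
        ok = total = 0
        for comp in r.COMPARTMENTS:
            sample = hits[hits["sample_id"] == f"P01_{comp}"]
            counts = sample["taxon_id"].value_counts()
            for sp, p in prof[comp].items():
                if p <= 0:
                    continue
                se = np.sqrt(p * (1 - p) / n * (n + c_total) / (1 + c_total))
                obs = counts.get(taxon_of[sp], 0) / n
                total += 1
                ok += abs(obs - p) <= 3 * se
        assert ok / total >= 0.99

    def test_off_window_read_count_is_exact(self):
        cfg = r.default_scenario(
            n_species=60, n_inside_out=6, n_outside_in=18,
            depth=1000, n_participants=1, seed=5,
            contamination_rate=0.0, off_window_fraction=0.10,
        )
        hits = r.sample_reads(r.build_scenario(cfg), cfg)
        qc = r.QCConfig()
        in_window = (
            (hits["pct_identity"] >= qc.id_min) & (hits["pct_identity"] <= qc.id_max)
            & (hits["aln_length"] > qc.aln_min)
            & (hits["read_length"] >= qc.len_min) & (hits["read_length"] <= qc.len_max)
        )
        per_sample_off = (~in_window).groupby(hits["sample_id"]).sum()
        assert per_sample_off.eq(100).all()


class TestKitomePair:
    def test_zero_rate_gives_empty_negative(self):
        cfg = r.default_scenario(n_species=60, n_inside_out=6, n_outside_in=18, depth=2000, n_participants=1, seed=2)
        neg, pos = r.kitome_pair(cfg, neg_rate=0.0)
        assert len(neg) == 0
        assert len(pos) == 2000

    def test_negative_depth_in_poisson_interval(self):
        """At the study's positive depth and a 3e-4 rate, the negative library
        lands in the Poisson 99% interval around rate x depth (~12.3 reads)."""
        cfg = r.default_scenario(n_species=60, n_inside_out=6, n_outside_in=18, depth=41_135, n_participants=1, seed=1)
        neg, pos = r.kitome_pair(cfg, neg_rate=0.0003)
        lo, hi = stats.poisson.interval(0.99, 0.0003 * len(pos))
        assert lo <= len(neg) <= hi
        reagents = set(cfg.reagent_taxa)
        assert set(neg["taxon_id"]).issubset(reagents)

    def test_pair_feeds_contamination_estimate(self):
        cfg = r.default_scenario(n_species=60, n_inside_out=6, n_outside_in=18, depth=10_000, n_participants=1, seed=4)
        neg, pos = r.kitome_pair(cfg, neg_rate=0.001)
        est = r.kitome_contamination(len(neg), len(pos))
        assert est.contamination_pct == pytest.approx(100 * len(neg) / len(pos))

    def test_invalid_rate_rejected(self):
        cfg = r.default_scenario(n_species=60, n_inside_out=6, n_outside_in=18, depth=100, n_participants=1, seed=0)
        with pytest.raises(ValidationError):
            r.kitome_pair(cfg, neg_rate=1.0)


def test_gradient_classes_cover_config():
    cfg = r.default_scenario(n_species=100, seed=0)
    assert set(cfg.gradient_class.unique()) <= set(GRADIENT_CLASSES)
    assert (cfg.gradient_class == "inside_out").sum() == 20
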