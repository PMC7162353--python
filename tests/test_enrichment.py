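"""Normalization, compartment differencing, enrichment calls and gradients."""

import itertools

import numpy as np
import pandas as pd
import pytest

import respiratome as r
from respiratome import enrichment, qc, taxprofile
from respiratome.containers import ValidationError
from respiratome.enrichment import MissingCompartmentError


class TestNormalize:
    def test_scaling_to_target(self, profile_from_counts):
        prof = profile_from_counts({"LAV": [500, 500], "mouth": [1000, 1000]})
        norm = enrichment.normalize_counts(prof, target_depth=1000)
        assert np.allclose(norm.counts["LAV"], [500, 500])
        assert np.allclose(norm.counts["mouth"], [500, 500])

    def test_equal_totals_unchanged(self, profile_from_counts):
        prof = profile_from_counts({"LAV": [600, 400], "mouth": [700, 300]})
        norm = enrichment.normalize_counts(prof, target_depth=1000)
        pd.testing.assert_frame_equal(norm.counts, prof.counts)

    def test_default_target_is_median_depth(self, profile_from_counts):
        prof = profile_from_counts(
            {"LAV": [100, 0], "throat": [0, 200], "mouth": [300, 0]}
        )
        norm = enrichment.normalize_counts(prof)
        assert norm.target_depth == 200
        assert np.allclose(norm.counts.sum(axis=0), 200, atol=1e-6)

    def test_all_totals_hit_target(self, profile_from_counts):
        rng = np.random.default_rng(2)
        prof = profile_from_counts(
            {c: rng.integers(1, 100, 20) for c in r.COMPARTMENTS}
        )
        norm = enrichment.normalize_counts(prof, target_depth=5000)
        assert np.allclose(norm.counts.sum(axis=0), 5000, atol=1e-6)

    def test_empty_compartment_excluded(self, profile_from_counts, caplog):
        prof = profile_from_counts({"LAV": [1, 2], "mouth": [0, 0]})
        with caplog.at_level("WARNING"):
            norm = enrichment.normalize_counts(prof)
        assert "mouth" not in norm.counts.columns


class TestDifferences:
    def test_simple_subtraction(self, profile_from_counts):
        prof = profile_from_counts(
            {"LAV": [400.0], "mouth": [100.0], "nose": [50.0]}, normalized=True
        )
        d = enrichment.compartment_differences(prof)
        assert d["d_mouth"].iloc[0] == 300.0
        assert d["d_nose"].iloc[0] == 350.0

    def test_identical_compartments_give_zero(self, profile_from_counts):
        prof = profile_from_counts(
            {"LAV": [5.0, 7.0], "mouth": [5.0, 7.0], "nose": [5.0, 7.0]},
            normalized=True,
        )
        assert (enrichment.compartment_differences(prof) == 0).all().all()

    def test_elementwise_oracle_and_antisymmetry(self, profile_from_counts):
        rng = np.random.default_rng(4)
        vals = {c: rng.uniform(0, 500, 30) for c in ("LAV", "mouth", "nose")}
        prof = profile_from_counts(vals, normalized=True)
        d = enrichment.compartment_differences(prof)
        for i in range(30):
            assert d["d_mouth"].iloc[i] == vals["LAV"][i] - vals["mouth"][i]
        swapped = profile_from_counts(
            {"LAV": vals["mouth"], "mouth": vals["LAV"], "nose": vals["nose"]},
            normalized=True,
        )
        d2 = enrichment.compartment_differences(swapped)
        assert np.allclose(d2["d_mouth"], -d["d_mouth"])

    def test_missing_compartment_excludes_participant(self, profile_from_counts):
        prof = profile_from_counts({"LAV": [1.0], "mouth": [1.0]}, normalized=True)
        with pytest.raises(MissingCompartmentError):
            enrichment.compartment_differences(prof)

    def test_unnormalized_profile_rejected(self, profile_from_counts):
        prof = profile_from_counts({"LAV": [1], "mouth": [1], "nose": [1]})
        with pytest.raises(ValidationError):
            enrichment.compartment_differences(prof)


class TestClassifyEnriched:
    def diffs(self, rows):
        return pd.DataFrame(rows, columns=["d_mouth", "d_nose"],
                            index=[f"sp{i}" for i in range(len(rows))])

    def test_both_differences_must_exceed_threshold(self):
        enriched, _ = enrichment.classify_enriched(
            self.diffs([(300, 200), (100, 400), (151, 151), (150, 300)])
        )
        assert enriched == {"sp0", "sp2"}

    def test_margin_reported(self):
        _, detail = enrichment.classify_enriched(self.diffs([(300, 200)]))
        assert detail["margin"].iloc[0] == 50.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        d = self.diffs(rng.normal(100, 200, size=(200, 2)))
        sets = [enrichment.classify_enriched(d, t)[0] for t in (50, 150, 300)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_matches_brute_force_enumeration(self):
        """On a <=10-species profile the enriched set equals direct enumeration
        of the definition over every species."""
        rng = np.random.default_rng(11)
        d = self.diffs(rng.normal(150, 120, size=(10, 2)))
        enriched, _ = enrichment.classify_enriched(d, 150)
        by_hand = {
            sp for sp in d.index
            if d.loc[sp, "d_mouth"] > 150 and d.loc[sp, "d_nose"] > 150
        }
        assert enriched == by_hand

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            enrichment.classify_enriched(self.diffs([(np.inf, 1)]))


class TestGradient:
    def build(self, lav, throat, outer, profile_from_counts):
        return profile_from_counts(
            {"LAV": [lav], "throat": [throat], "mouth": [outer], "nose": [outer]},
            normalized=True,
        )

    @pytest.mark.parametrize(
        "lav,throat,outer,expected",
        [
            (500, 300, 90, "inside_out"),
            (50, 200, 350, "outside_in"),
            (100, 100, 100, "flat"),
            (100, 300, 100, "discordant"),
        ],
    )
    def test_patterns(self, lav, throat, outer, expected, profile_from_counts):
        prof = self.build(lav, throat, outer, profile_from_counts)
        assert enrichment.gradient_classify(prof).iloc[0] == expected

    def test_epsilon_tolerance_flattens_noise(self, profile_from_counts):
        prof = self.build(105, 100, 98, profile_from_counts)
        assert enrichment.gradient_classify(prof, epsilon=0).iloc[0] == "inside_out"
        assert enrichment.gradient_classify(prof, epsilon=10).iloc[0] == "flat"

    def test_missing_throat_is_undetermined(self, profile_from_counts):
        prof = profile_from_counts(
            {"LAV": [1.0], "mouth": [1.0], "nose": [1.0]}, normalized=True
        )
        with pytest.raises(MissingCompartmentError):
            enrichment.gradient_classify(prof)


class TestEnrichedFraction:
    def test_arithmetic(self):
        assert enrichment.enriched_fraction(5, 100) == 5.0
        assert enrichment.enriched_fraction(0, 50) == 0.0

    def test_zero_detected_rejected(self):
        with pytest.raises(ValidationError):
            enrichment.enriched_fraction(1, 0)


class TestHeatmap:
    def result(self, pid, rows, threshold=150.0):
        diffs = pd.DataFrame(rows, columns=["d_mouth", "d_nose"],
                             index=[f"sp{i}" for i in range(len(rows))])
        enriched, detail = enrichment.classify_enriched(diffs, threshold)
        return enrichment.EnrichmentResult(pid, diffs, enriched, detail, None, threshold)

    def test_single_participant_single_species(self):
        mat = enrichment.heatmap_matrix({"P01": self.result("P01", [(300, 200)])})
        assert mat.shape == (1, 2)
        assert mat.loc["sp0", ("P01", "d_mouth")] == 300

    def test_all_below_threshold_gives_empty(self, caplog):
        with caplog.at_level("WARNING"):
            mat = enrichment.heatmap_matrix({"P01": self.result("P01", [(10, 10)])})
        assert mat.empty

    def test_cells_equal_recomputation_and_order(self):
        rng = np.random.default_rng(5)
        results = {
            pid: self.result(pid, rng.normal(120, 150, size=(8, 2)))
            for pid in ("P01", "P02")
        }
        mat = enrichment.heatmap_matrix(results)
        for sp in mat.index:
            for pid in ("P01", "P02"):
                assert mat.loc[sp, (pid, "d_mouth")] == results[pid].diffs.loc[sp, "d_mouth"]
                assert mat.loc[sp, (pid, "d_nose")] == results[pid].diffs.loc[sp, "d_nose"]
        row_max = mat.max(axis=1)
        assert (row_max.diff().dropna() <= 1e-12).all()  # descending order
        # rows restricted to species enriched somewhere
        union = set().union(*(res.enriched for res in results.values()))
        assert set(mat.index) == union


class TestNormalizationInvariance:
    def test_per_compartment_rescaling_is_removed(self, profile_from_counts):
        """Multiplying one compartment's raw counts by any positive constant
        leaves every post-normalization result unchanged."""
        rng = np.random.default_rng(9)
        raw = {c: rng.integers(0, 400, 40).astype(float) for c in r.COMPARTMENTS}
        prof = profile_from_counts(raw)
        scaled = profile_from_counts(
            {c: (v * 3.7 if c == "mouth" else v) for c, v in raw.items()}
        )
        res_a = enrichment.analyze_participant(prof, target_depth=10_000)
        res_b = enrichment.analyze_participant(scaled, target_depth=10_000)
        pd.testing.assert_frame_equal(res_a.diffs, res_b.diffs)
        assert res_a.enriched == res_b.enriched
        assert res_a.gradient.equals(res_b.gradient)


class TestRecovery:
    def test_planted_signals_recovered(self):
        """Smaller-scale recovery: planted inside-out species at effect 5 are
        called with high precision/recall and correct gradients."""
        cfg = r.default_scenario(
            n_species=100, n_inside_out=10, n_outside_in=30, effect_size=5.0,
            depth=20_000, n_participants=2, seed=13,
        )
        truth = r.build_scenario(cfg)
        hits = r.sample_reads(truth, cfg)
        w = qc.QCConfig()
        top = qc.select_top_hit(qc.filter_hits(qc.filter_read_lengths(hits, w), w))
        table = taxprofile.aggregate_counts(top, cfg.taxonomy, "species")
        profiles = enrichment.build_profiles(table, r.sample_metadata(cfg))
        eb, gb = {}, {}
        for pid, prof in profiles.items():
            res = enrichment.analyze_participant(prof)
            eb[pid], gb[pid] = res.enriched, res.gradient
        scores = r.recovery_scores(truth, eb, gb)
        assert scores["precision"] >= 0.9
        assert scores["recall"] >= 0.9
        assert scores["gradient_accuracy"] >= 0.9
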