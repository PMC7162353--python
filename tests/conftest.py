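import numpy as np
import pandas as pd
import pytest

import respiratome as r


@pytest.fixture(scope="session")
def small_scenario():
    """Moderate scenario reused across read-level tests."""
    return r.default_scenario(
        n_species=100, n_inside_out=10, n_outside_in=30,
        depth=5000, n_participants=3, seed=5,
    )


@pytest.fixture(scope="session")
def small_truth(small_scenario):
    return r.build_scenario(small_scenario)


@pytest.fixture(scope="session")
def small_hits(small_scenario, small_truth):
    return r.sample_reads(small_truth, small_scenario)


@pytest.fixture(scope="session")
def tiny_lineage():
    """Hand-written 6-species lineage over 2 phyla (no scenario constraints)."""
    return r.LineageTable.from_records(
        [
            {"taxon_id": "t1", "species": "Streptococcus mitis", "genus": "Streptococcus",
             "family": "Streptococcaceae", "phylum": "Firmicutes"},
            {"taxon_id": "t2", "species": "Streptococcus oralis", "genus": "Streptococcus",
             "family": "Streptococcaceae", "phylum": "Firmicutes"},
            {"taxon_id": "t3", "species": "Veillonella dispar", "genus": "Veillonella",
             "family": "Veillonellaceae", "phylum": "Firmicutes"},
            {"taxon_id": "t4", "species": "Veillonella atypica", "genus": "Veillonella",
             "family": "Veillonellaceae", "phylum": "Firmicutes"},
            {"taxon_id": "t5", "species": "Prevotella melaninogenica", "genus": "Prevotella",
             "family": "Prevotellaceae", "phylum": "Bacteroidetes"},
            {"taxon_id": "t6", "species": "Prevotella oris", "genus": "Prevotella",
             "family": "Prevotellaceae", "phylum": "Bacteroidetes"},
        ]
    )


def hits_frame(rows):
    """Build a hit DataFrame from (read_id, taxon_id, ident, aln, bit[, length]) tuples."""
    cols = ["read_id", "taxon_id", "pct_identity", "aln_length", "bit_score"]
    if rows and len(rows[0]) == 6:
        cols = cols + ["read_length"]
    df = pd.DataFrame(rows, columns=cols)
    df["sample_id"] = "s1"
    return df


def multi_hit_fixture(n_reads=2000, seed=0):
    """Random multi-hit table (1-3 hits per read) with frequent score ties."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_reads):
        for j in range(rng.integers(1, 4)):
            rows.append(
                {
                    "read_id": f"read{i:05d}",
                    "taxon_id": f"tax{rng.integers(0, 50):03d}",
                    "pct_identity": float(np.round(rng.uniform(70, 95), 1)),
                    "aln_length": int(rng.integers(1300, 2000)),
                    "bit_score": float(rng.choice([700.0, 750.0, 800.0, 850.0])),
                    "sample_id": "s1",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def profile_from_counts():
    """Factory: build a ParticipantProfile from a compartment -> counts dict."""

    def _build(counts: dict, participant_id="P01", normalized=False, **kw):
        df = pd.DataFrame(counts, dtype=float)
        df.index = [f"sp{i}" for i in range(len(df))]
        return r.ParticipantProfile(participant_id, df, normalized=normalized, **kw)

    return _build
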