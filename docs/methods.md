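# Methods

This note records the models, parameter choices and numerical conventions
behind `respiratome`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The analysis model

The pipeline consumes one best database hit per long read (a ~4.4 kb
rRNA operon amplicon screened against a 16S reference), not raw
sequence. Everything upstream — basecalling, demultiplexing, the
database search itself — is out of scope; the artifact begins at the
tabular hit level.

**QC windows.** A read enters the analysis when its length lies in
[3,700, 5,700] bp (size selection for the near-full-length operon), its
percent identity lies in [70, 95], and its alignment spans more than
1,200 bp of the 16S gene. The identity *ceiling* is deliberate: on
error-prone long reads, near-perfect identities indicate short conserved
stretches or database self-matches rather than trustworthy species
assignments. Length and identity bounds are inclusive; the alignment
bound is strictly exclusive, following the stated ">1,200 bp" form. Ties
in top-hit selection resolve by bit score, then identity, then alignment
length, then lexicographically smallest taxon id — a total order, so the
operation is deterministic. Records lacking the optional read length
pass the length filter with a logged warning (hit tables derived from
pre-size-selected reads carry no lengths); a strict mode raises instead.

**Normalization.** Enrichment compares read *counts*, so compartments
are put on a common scale by total-sum scaling to the participant's
median raw compartment depth. Using a read-count-like target (rather
than proportions) keeps the 150-read threshold meaningful. Values stay
real; nothing is rounded before thresholding. Because total-sum scaling
removes any per-compartment multiplicative factor, all downstream
results are invariant to per-compartment rescaling of the raw counts
(tested as a property).

**Enrichment definition.** A species is lung-enriched for a participant
iff *both* normalized differences LAV−mouth and LAV−nose strictly exceed
the threshold (default 150). The conjunctive form is the conservative
reading of paired subtraction against two outer compartments; a
disjunctive form would admit species abundant in the nose but absent in
the mouth. The threshold sits where replicate long-read counts become
reliably distinguishable (replicate CV ≈ 12% above ~100 reads).
Participants missing LAV, mouth or nose are excluded from enrichment but
retained in community summaries. The throat is deliberately *not* part
of the enrichment definition; it serves as the independent gradient
check.

**Gradient classification.** With outer = mean of the present
mouth/nose columns, a species is inside-out iff LAV > throat + ε and
throat > outer + ε; outside-in with the inequalities reversed; flat when
all pairwise differences are within ε; discordant otherwise. ε defaults
to 0 (strict ordering) and is configurable; any positive ε absorbs
sampling noise at the cost of sensitivity.

**Diversity.** Bray-Curtis is computed on per-sample proportions by
default (depth-invariant); raw-count mode exists and is documented as
depth-sensitive. Two ordination pathways are implemented and labelled
distinctly, because "PCA on a Bray-Curtis index" conflates two methods:
`pca_logcounts` is an SVD of column-centred log(count+1) data, and
`pcoa_braycurtis` is classical metric MDS (eigendecomposition of the
double-centred squared dissimilarity matrix, negative eigenvalues
dropped). Axes with explained variance below 1e-10 of the total are
dropped; the sign of each axis is fixed by making its largest-magnitude
loading (score, for PCoA) positive, so repeated runs are bit-identical.
Both are written in-package to guarantee that sign convention and the
variance bookkeeping; tests cross-check PCoA against scikit-bio and
Bray-Curtis against scipy. The ± in compartment dissimilarity summaries
is the sample standard deviation (n−1) across participants, one value
per participant, not across all sample pairs.

**Kitome.** Contamination is the PCR-negative library's QA/QC read count
as a percentage of the paired PCR-positive library's, with the
fold-difference reported alongside (undefined when the negative library
is empty). It is an upper bound on the reagent contribution to any one
sample, not a per-taxon decontamination procedure.

## The synthetic community generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen once to mirror the study design:

| parameter | default | meaning |
|---|---|---|
| participants | 5 | complete four-compartment participants |
| depth | 25,000 reads/sample | a study-scale per-sample budget (~600k reads over 23 samples) |
| taxonomy | 200 species | 5 dominant phyla (~98.5% of mass) + 2 minor phyla + 2 reagent taxa |
| base abundance | lognormal, σ = 0.5 | moderate rank-abundance spread over the outer pool |
| effect size | 4 (tests use 5) | total outer→lavage fold-change for non-flat species |
| concentration | 200 per taxon | Dirichlet-multinomial overdispersion (below) |
| contamination | 3 × 10⁻⁴ | trace reagent reads (classic water-kit genera) |
| off-window reads | 4% | forced outside ≥1 QC window |
| identity / length / alignment | 85 ± 5 % / 4,400 ± 400 bp / 1,450 ± 120 bp | truncated normals inside the QC windows |

**Gradients.** Expected proportions put the throat at the *geometric*
midpoint between the outer pool and the lavage: an inside-out species at
effect size *e* has unnormalized weights (outer, throat, LAV) =
(b, b√e, be); outside-in reverses the direction. Geometric spacing makes
the two steps equal in fold-change, the natural reading of "intermediate
relative abundance" on compositional data. Each compartment vector is
then renormalized to the simplex. Mouth and nose share one expected
outer pool and differ only by sampling noise, treating both as exchangeable
end members.

**Count noise.** Counts are Dirichlet-multinomial with Dirichlet
parameter α = c·K·p, where p is the expected proportion vector, K the
number of community species and c the `concentration` knob — i.e. c is a
*per-taxon* concentration scale and the total concentration grows with
community size. At the defaults (c = 200, K = 200, depth 5 × 10⁴) a
taxon observed at ~100 reads has a replicate CV of roughly 12–15%,
matching the replicate variability long-read operon counts show in
practice. A fixed total concentration of 200 would instead give CVs
above 100% at that count scale, which no replicate data supports.

**Infection displacement.** For designated participants, a configurable
mass (default 0.6) of the lavage vector is reallocated to an infection
genus set (Pseudomonas/Pantoea/Tatumella by default), the remainder
rescaled. Displaced participants' planted `is_lung_enriched` labels are
cleared: after displacement the residual inside-out species need not
exceed the read-difference threshold in expectation, so keeping the
labels would make the ground truth self-inconsistent.

**Determinism.** All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, one child stream per sample in a
fixed order; equal (config, seed) yields byte-identical serialized
output. Off-window and contaminant read counts are deterministic
(rounded fractions of depth) so fixtures have exactly known composition;
only the kitome negative library is Poisson by design.

**What the generator does not emulate.** Nucleotide-level sequences and
error profiles, chimeras, barcode cross-talk, database incompleteness or
mis-annotation, participant-to-participant differences in the *identity*
of the colonizing flora, and compositional coupling between species
beyond the simplex constraint. Passing recovery tests therefore shows
the *inference machinery* is correct under the stated noise model — not
that the thresholds would achieve the same precision/recall on real
airway data, where effect sizes, depths and taxonomic misassignment
rates are less favourable.

## Problem sizes in the test and acceptance runs

The reference recovery scenario is 200 species × 5 participants × 4
compartments at 5 × 10⁴ reads per sample (10⁶ reads end to end); unit
tests use 60–150 species at 10³–2.5 × 10⁴ reads. These sizes make the
planted effects (fold-change 5 against DM noise) detectable with wide
margins while keeping the full suite fast; they were chosen as the
package's reference conditions, and the acceptance script regenerates
them from scratch at every run.

## Known limitations

- Enrichment is a fixed read-difference threshold, not a statistical
  test; no multiplicity control is attempted (by design — the method is
  a conservative screen, not an inference procedure).
- The 150-read threshold is only meaningful on the normalization scale
  used here; changing the target depth rescales differences and shifts
  the threshold's effective stringency.
- Bray-Curtis summaries are per-participant; pooling all sample pairs
  would give a different (typically larger-variance) estimate.
- With ε = 0, gradient classes for near-flat species are effectively
  random among {inside_out, outside_in, discordant}; only planted
  non-flat species are scored in recovery tests.
- The kitome estimate assumes the negative library saw the same reagent
  batch and cycling as the positive; it cannot attribute contamination
  to individual taxa in real samples.
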