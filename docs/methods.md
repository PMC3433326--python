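# Methods

This note documents the models, parameter choices and numerical decisions
behind hybriscope, in the order the pipeline runs them.

## Marker model and fragment statistics

Dominant markers are strictly binary: a locus is a sized fragment, a sample
either shows the band or does not.  Missing data are not modelled; the
uncertainty of band scoring is instead represented by replicate re-runs that
differ from their originals through independent per-band errors.  This is
why all difference-based statistics (repeatability, clone thresholds)
operate on flip counts rather than on genotype likelihoods.

A *group carries a band if at least one non-excluded member does*.  This
"any-member" convention is what makes directional shared-fragment
percentages (`100 · |F_a ∩ F_b| / |F_a|`, denominator = first group) and
private-fragment counts reproduce the arithmetic of published
shared-fragment tables for dominant data; a frequency-threshold variant can
be obtained by pre-filtering the matrix, but is deliberately not the
default.  Samples flagged as excluded (typically field misidentifications
revealed by clustering) are dropped before any group set is built.
Percentages are rounded half-up to 2 decimals, diversity indices to 3,
matching how such tables are printed.

## Clones and genotype diversity

Two samples are clonemates when their band difference is at most a
threshold.  Clusters are single-linkage connected components of the
"difference ≤ t" graph — the only clustering under which a tolerance
threshold behaves transitively (if a~b and b~c are within scoring error,
a and c belong together even at distance 2t).  Threshold suggestions come
from (i) the largest observed replicate-pair difference, and (ii) the edge
of the first empty bin in the pairwise-difference histogram; when the two
disagree the larger (more conservative, clone-lumping) value is the
recommended pick.

Genotype diversity is the bias-corrected Nei index
`D_g = n/(n−1) (1 − Σ (s_i/n)²)`.  The `n/(n−1)` correction is forced by
the boundary case: a population of n singleton genotypes must score exactly
1.000 (the uncorrected index would give 1 − 1/n).

## Plastid haplotypes and the parsimony network

Alignment columns inside user-declared excluded regions (poly-A stretches
and similar unalignable motifs) are removed first.  Each maximal gap run
with identical boundaries across the sequences that show it is coded as one
binary presence/absence character and its columns removed; overlapping
distinct runs cannot be coded automatically and raise an error demanding
manual coding.  Coded indels count one mutational step each, exactly like
substitutions; positions containing N are ignored in step counts.

The network joins haplotypes in increasing step order; a k-step connection
inserts k−1 inferred intermediates.  A connection is skipped when the pair
is already linked by a path no longer than its step count — so alternative
equal-step connections are all retained (the graph may contain cycles,
matching statistical-parsimony semantics), while redundant longer ones are
not.  Connections above the limit are never made, and connected components
are the haplotype groups.

The connection limit defaults to an explicit 3 steps: single-step links
always join, and groups separated by 4 or more steps (the regime the
pipeline is designed to resolve; deep inter-group separations in real
plastid data are typically 4–12 steps) never merge.  A pluggable
`parsimony_connection_limit(L, confidence)` routine is provided for the
classical 95%-probability convention.  It uses a Poisson approximation:
with j observed differences over L characters the per-site substitution
load is θ = −ln(1 − j/L), the chance that no character was hit twice is
`[e^−θ(1+θ)]^L`, and the limit is the largest j keeping that probability
above the confidence.  This is an approximation to the classical recursion,
deliberately simple and monotone in L; users wanting the exact published
limits should pass an explicit integer.

## Jaccard distances and Neighbor-Net

Between-genotype distances are Jaccard, `1 − a/(a+b+c)`: shared absences
carry no signal for dominant markers.  A pair of all-absent profiles has no
defined distance and is rejected rather than silently zeroed.

Neighbor-Net follows the canonical agglomerative scheme: clusters hold one
or two linked nodes; selection is neighbor-joining-like, first between
clusters on averaged distances, then between their member nodes (other
clusters counting as single averaged units); a merged chain of three nodes
x–y–z is reduced to two fresh nodes via

    d(u,s) = 2/3 d(x,s) + 1/3 d(y,s)
    d(v,s) = 1/3 d(y,s) + 2/3 d(z,s)
    d(u,v) = (d(x,y) + d(y,z) + d(x,z)) / 3

and unwinding the reduction stack yields the circular ordering.  Ties in
both selection steps break toward the lowest node index, making the
ordering deterministic under row permutation (up to rotation/reflection,
which is all a circular ordering defines).  Split weights are estimated by
nonnegative least squares of the pairwise distances on all n(n−1)/2 splits
compatible with the ordering; weights at or below a floor of 1e−6 are
dropped as numerical dust from the active-set solver.  On distances from an
additive tree this estimator returns exactly the tree's splits with their
branch lengths (verified to 1e−6 in the tests), because every tree split is
an arc of some circular ordering the agglomeration recovers.

The NNLS system is square in the number of splits, so its cost grows
quickly with taxa; the pipeline stride-subsamples to at most
`splits_max_samples` (default 60) taxa before fitting.  At that size the
fit takes under a second.

## Ordination

Hybrid/parent relations are not tree-like, so the 2D view anchors
predefined reference groups first: their centroid–centroid Euclidean
distance matrix is embedded by classical (Torgerson) scaling, which places
the groups at maximal planar separation in the least-squares sense.  Every
sample is then positioned by minimising the squared deviation between its
2D distances to the fixed centroids and its original-space distances to
those centroids.  The placement solver is a deterministic multi-start
Levenberg–Marquardt (starts: centroid mean, each centroid, and a 3×3 grid
over the padded centroid bounding box; first-best wins), so results are
reproducible bit-for-bit.  This two-stage scheme is an interpretation of
the group-separating ordinations used in the hybrid literature, chosen
because it provably puts an additive F1 between its parents' anchors; a
plain metric-MDS mode (`mode="mds"`) is provided for comparison, and no
attempt is made to reproduce any historical program's exact coordinates.

The mapping error is `Σ_{i<j} |d2D − d| / Σ_{i<j} d` — the relative
absolute distortion of pairwise distances, 0 for perfectly planar data and
invariant under rigid motions.  The sum-ratio normalisation is a design
choice; the quantity is defined only verbally in the literature this
mirrors.

## Ploidy from flow cytometry

Per species, fluorescence ratio = β · ploidy is fit through the origin on
chromosome-counted reference individuals (least squares, so
β̂ = Σ r k / Σ k²).  Samples are assigned the integer ploidy minimising
|ratio − βk|.  Records with a sample-peak CV of 5% or more are excluded
with a reason; species without a usable reference yield an explicit
"cannot attribute" rather than a guess.  A best assignment whose relative
residual exceeds 3% is flagged as a possible aneuploid: at a measurement
noise of ~1% this keeps euploid calls unflagged (3σ) while a 6.3×-slope
individual sits at a 5% residual from 6x and is caught.

## Gamete model and the single-event test

Each parental taxon/cytotype declares male gamete ploidies (meiotic pollen)
and female gamete ploidies (meiotic eggs, plus unreduced apomeiotic eggs in
facultatively apomictic cytotypes — encoded simply as extra female
ploidies, with no attempt to model the reproductive pathway itself), and
the plastid haplotype group it transmits maternally.  The default model is
the study system's: 1x/1x for diploid *P. argentea*, 3x/6x for hexaploid
*P. argentea*, 2x,3x / 2x,3x,5x,6x,7x for *P. pusilla*.  Same-taxon crosses
are treated as selfing and excluded by default.

For a lineage of ploidy p and haplotype group h, all crosses with
egg + pollen = p and a mother transmitting h are enumerated.  The lineage
is *single-event* iff at least one enumerated cross also passes the
composition clause: with expected maternal genome fraction
f = egg/(egg+pollen), f > 0.5 requires the lineage's shared-fragment
percentage toward the mother to exceed that toward the father, f < 0.5 the
reverse, with a dead band of ±0.05 around 0.5 inside which either ranking
is accepted.  The dead band exists because shared-percentage differences of
a few points are within band-scoring noise and must not flip verdicts.  The
rank-plus-dead-band rule is a deliberate, documented operationalisation of
"composition reflects the contributed parental genomes"; it uses only
quantities the rest of the pipeline already computes.

Lineages are maximal sample sets homogeneous in (cluster, cytotype,
haplotype).  The pipeline derives clusters by single-linkage at a coarser
`cluster_threshold` (default 20 band differences) than the clone threshold:
within-lineage clonemates differ by scoring error (~6 bands on 241 loci,
upper tail well below 20) while independently formed lineages differ by
tens of bands, so 20 sits in the empty middle of the two scales.

## The synthetic scenario

`simulate_dataset` plants, over 241 loci: three parental panels (8 samples
each) drawn from blocked band-frequency profiles — widespread bands (25
loci at 0.90 in all taxa), an argentea-wide block (20 at 0.80), cytotype-
and taxon-diagnostic blocks (30 at 0.60 for 2x *P. argentea*; 70+6 at 0.90
for 6x *P. argentea*; 70 at 0.60 plus 6 at 0.90 for *P. pusilla*) and rare
noise bands (14 at 0.05) — four replicate re-scorings, and four hybrid
lineages:

* **a** — pentaploid F1, *P. pusilla* egg 2x (haplotype W) × 6x
  *P. argentea* pollen 3x: the one single-event-explainable lineage;
* **b**, **c** — hexaploids carrying argentea-type haplotypes (G, F),
  generated through reduced 3x eggs of the hexaploid — a gamete mode the
  inference model deliberately lacks, so no single cross can explain them;
* **d** — a five-generation backcross chain into *P. pusilla* (haplotype W,
  pentaploid): haplotype-compatible with the F1 hypothesis but
  composition-inconsistent with it.

Scoring error ε = 0.0124 per band (98.76% mean repeatability), hybrid band
loss 0.17 and de-novo gain 0.024, FCM noise 1% multiplicative with
per-species slopes (0.50 argentea, 0.55 pusilla, 0.52 for the hybrids) so
that each species genuinely needs its own regression.  Plastid sequences
are 550 bp with two excluded poly-A stretches and three coded indels; the
two haplotype groups lie 12 steps apart (9 substitutions + 3 indels) with a
star of 1-step haplotypes inside each group, so any connection limit in
1..3 resolves exactly two groups.

The block sizes and frequencies were chosen once so that every planted
contrast is separated from its decision boundary by at least ~3–4 standard
deviations of the binomial sampling noise: the F1's fragment sharing leans
to the 6x argentea side (its diagnostic block is both larger and
higher-frequency than pusilla's), while five backcross generations decay
the argentea bands by 0.83 per generation, pushing lineage d decisively to
the pusilla side.  What the generator does *not* emulate: fragment-size
homoplasy, co-migration of non-homologous bands, linkage between loci,
within-taxon population structure, segregation within hybrid progenies, or
any explicit sequence-evolution model beyond unit steps.  Passing tests
therefore demonstrate correct inference under the stated statistical model,
not robustness to those real-data complications.

## Numerical and interface conventions

Alignment coordinates are 1-based inclusive in files and reports, 0-based
half-open internally.  Delimiters are auto-detected among tab, comma and
semicolon; writes are tab-delimited.  Split systems are exported as a
SplitsTree-dialect NEXUS Splits block (1-based indices, CYCLE line, weights
to 10 decimals) and round-trip through the bundled reader.  All simulation
randomness flows through one `numpy` generator seeded from the config, and
the pipeline report contains no timing data, so a rerun with the same seed
and config is byte-identical.

## Known limitations

* The statistical-parsimony probability routine is an approximation (see
  above); the default is an explicit step limit.
* Composition consistency uses a rank test with a fixed dead band, not a
  quantitative genome-dosage model; it cannot distinguish hypotheses whose
  predicted maternal fractions fall on the same side of 0.5.
* The ordination's group-anchored objective is an interpretation, not a
  re-implementation of any specific historical program.
* Clone assignment assumes scoring errors are independent across bands;
  systematic electrophoresis artefacts violating this would bias the
  suggested thresholds.
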