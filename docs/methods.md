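# Methods

## The phenotype model

The package models an EMT-reversal screen as movement along a single
*severity* axis: severity 1 is the TGF-β-driven mesenchymal background
(scattered nuclei, bright fibronectin with multiscale texture), severity 0
a fully reverted epithelial culture (compact islets, low smooth
fibronectin). A compound's effect is a reduction in severity. This
one-dimensional family is deliberately simple: graded control ladders are
observed in such assays but no functional form is identified, so the
18-parameter profile means interpolate *linearly* between an epithelial and
a mesenchymal anchor vector (`parameters.py`); linearity is the simplest
monotone choice and the anchors are configurable.

Toxicity (high-dose staurosporine) is modelled as a separate anchor with
very few surviving nuclei, not as a severity value — toxic and reverted
wells must be distinguishable, which is exactly what the nuclei-count
validity floor and the clustering step are for.

### The 18 parameters

Only four parameters of the original assay are identified by name
(fibronectin texture entropy, contrast-below-threshold colony fraction,
minimum neighbour distance, convex-hull-perimeter ratio); the remainder are
reconstructed from the five described blocks — fibronectin
(4 parameters), colony morphology (4), nuclear distribution (3), nuclear
intensity/shape (5), assay performance (2). The mapping is declared in
`parameters.PARAMETER_NAMES`, not claimed identical to the original
supplementary list.

### Noise model

Well-to-well noise is a one-factor Gaussian model: each profile draw is

    x = mean(severity) + sd ⊙ (ℓ·u + sqrt(1 − ℓ²) ⊙ ε),   u, ε ~ N(0, 1)

where `ℓ` is a signed per-parameter loading on a latent well factor (local
cell density / staining efficiency: denser wells have more nuclei and
colonies, shorter neighbour distances, more matrix signal). Marginal SDs
are unchanged by the factor. Correlated multiparametric noise is a basic
property of real well data; with independent noise the inactive population
is an isotropic blob, which is both unrealistic and a known pathology for
k-means at fixed k.

Three calibration rules fix the anchor/SD tables:

* the full epithelial↔mesenchymal swing of an informative parameter spans
  ~6–7 SDs, so the whole profile separates by a Euclidean distance of ~24
  reference-SD units — the regime of an assay whose multivariate Z′ sits
  clearly above the 0.5 "excellent" bar (measured: ~0.7–0.8), and in which
  a compound with severity reduction 0.8 scores strength ~19, safely above
  the hit threshold of 15;
* each parameter's epithelial:mesenchymal *ratio* stays within ~3×, because
  percent-of-control normalisation divides by the plate's negative-control
  median and amplifies that median's sampling noise by exactly this ratio
  (a 9× parameter produced ±2–4σ per-plate jitter in reverted wells before
  this constraint was imposed);
* plate effects are additive per parameter with a per-parameter
  susceptibility: intensity/texture/morphology/distance readouts receive
  offsets of 0.5 SD (default scale), while object counts, the validity flag
  and the contrast fraction (which is calibrated against the same plate's
  control colonies) receive none — batch shifts in staining and
  illumination do not move object counts.

The Gaussian family itself is an assumption, not a claim about real
screens; real per-well distributions are heteroscedastic (e.g. the colony
contrast fraction is binomial in the colony count) and heavier-tailed.

### Control ladder

Positive controls are two receptor-kinase inhibitors with IC50s of 1.9 µM
and 0.2 µM on a five-point ladder (10, 3, 1, 0.3, 0.1 µM). Residual
severity follows a logistic in log-concentration with an effective Hill
slope of 3.5: EMT maintenance responds ultrasensitively to receptor
inhibition, so the top two ladder concentrations act as near-complete
("strong") reversal standards while mid-ladder points give graded partial
phenotypes. Because parameter responses are linear in severity, fitting
the 4PL to any normalised parameter along the ladder recovers these IC50s.

### Default screen

The desk-scale default is 4 × 384-well plates: 16 + 8 negative (DMSO +
TGF-β) wells, two positive-control ladder columns (extra replicates at the
strongest concentrations), 8 staurosporine toxicity wells, 320 library
wells per plate; 1% of library compounds are planted actives with severity
reductions uniform on [0.8, 1], six compounds are planted toxic, and a
quarter of the actives are flagged receptor-like for the counter-screen.
These sizes keep a full pipeline run under ~10 s on one CPU and are the
problem sizes used throughout the test suite and the acceptance script.

## Image synthesis and analysis

Nuclei occupy sites of a jittered hexagonal lattice (pitch 8.5 px, ±1 px
jitter) inside islet discs whose count and radius interpolate geometrically
with severity — compact islets at severity 0, sparse random lattice
occupancy (≈ uniform with a hard core) at severity 1. Nuclei render as 2-D
Gaussians (σ 2.2 px, 16-bit counts); fibronectin is a severity-scaled base
level modulated by smoothed cell density plus band-passed noise texture
whose amplitude grows with severity.

Segmentation follows the classic recipe: Otsu threshold → fill holes →
watershed → area filter, with one refinement: watershed markers come from
smoothed-*intensity* maxima rather than distance-transform maxima, because
the distance transform plateaus inside confluent epithelial sheets and
under-seeds by ~40%; the flood itself still runs on the distance relief.
Colonies are connected components of the nuclei mask dilated by
`link_radius` (default 4 px at this rendering scale — at real-image scale
this corresponds to a few cell radii), each component smoothed by a
per-component morphological closing (6 px) so the colony outline is the
drawn boundary of a confluent group.

GLCM texture quantises intensities to 32 levels over the image's robust
(1st–99th percentile) range — hence invariance to adding a constant — and
averages symmetric normalised co-occurrence matrices over the offsets
(0,1), (1,0), (1,1), (1,−1), restricted to pixel pairs inside the colony
mask. Entropy is −Σ P ln P (nats); contrast Σ P(i,j)(i−j)². Perimeters are
measured on the half-level marching-squares boundary polygon; the hull
perimeter is the convex hull of its vertices. Distances aggregate per well
by median (robust to stray nuclei), intensities and textures by mean.

**Known limitation.** On rendered fields, texture entropy, neighbour
distance and colony count respond monotonically to severity (noise-free),
but the hull-perimeter ratio does not: with isotropic nucleus-dilation
colony masks, small dispersed colonies are nearly circular (ratio ~0.95)
while large islets score ~0.92 from boundary waviness. The raggedness of
real dispersed mesenchymal colonies comes from spindle-shaped cell bodies
that this renderer does not model. The decreasing hull-ratio anchors
(0.95 → 0.70) therefore live in the profile-level family, which is what
the statistical pipeline consumes; the image route demonstrates the
feature's correctness (oracle equivalence, shape tests), not this
monotonicity. Passing image-route tests show the named features behave
correctly on idealised fields; they do not certify performance on real
micrographs with debris, illumination gradients or focus failure, none of
which are modelled.

## Normalisation

Robust POC uses the *median* of the plate's valid negative controls
(resistant to dead control wells); plates need ≥ 8 valid negatives.
Z-scoring uses median / 1.4826·MAD over the whole run's valid library +
vehicle wells — library wells are overwhelmingly inactive, so hits stay
outliers while the reference standardises to median 0, scaled-MAD 1
(verified to 1e-9). Classical moments and per-plate z are config switches.
A parameter whose reference MAD is zero carries no information on the run
and is dropped with consistent bookkeeping — the constant validity flag
exercises this path on every default run, so downstream profiles have 17
effective dimensions. Toxicity controls never enter reference statistics.

## QC statistics

Multivariate Z′ scalarises every profile as its Euclidean distance to the
negative-control centroid (coordinate-wise median when robust) and applies
the univariate formula to the two distance samples; distance-to-own-centroid
is available by flag. Per plate it is computed per positive-control
compound at its *top* ladder concentration — pooling the whole ladder mixes
phenotype grades into σ₊ and answers a different question. A plate passes
when its best positive-control Z′ and its toxicity Z′ both reach 0.5.
Replicate correlation is computed on z-values (plate effects cannot inflate
it); the pipeline measures it between two independent noise realisations of
the same screen. Note the robust multivariate Z′ is exactly rotation
invariant only with classical moments (the coordinate-wise median is not
rotation-equivariant); permutation invariance holds for both.

## Hit calling

Toxic/invalid wells (< 10 nuclei or validity 0) are excluded before
clustering and can never be hits. k-means (k = 5, k-means++, 25 restarts,
fixed seed) clusters the z-profiles; the EMT cluster is the one holding the
largest fraction of strong positive-control wells (top two ladder
concentrations), ties broken by higher median control strength, with a
manual-review flag below a 40% plurality. A well is a hit iff it is in the
EMT cluster **and** its strength strictly exceeds 15 (the boundary is
strict by specification: D = 15.0 is not a hit). Compounds condense by the
any-well rule with the maximum strength as the compound score — controls
are hits at several ladder points, so any-well is the consistent reading;
an all-well rule is the obvious alternative and would only change
multi-well library entries. TPR is counted over strong positive-control
wells, FPR over vehicle wells, hit rate over library compounds, all to one
decimal.

## Dose-response

4PL fits run on log10 concentration with the Hill slope boxed to
[0.2, 5] — geometric 5–8-point ladders cannot support slopes outside that
box — and top/bottom free, so curve direction is absorbed by the
asymptotes and the IC50 is invariant to relabelling them. Initialisation
takes the asymptotes from the data extremes and the IC50 from the
half-response crossing; three seeded jittered restarts guard against local
minima; convergence to 1e-10 relative RSS. Flat data (dynamic range under
twice the noise estimate) is reported as "no fit", never as a number; an
IC50 outside the tested range carries a flag. The compound summary is the
median IC50 over successfully fitted parameters — all parameters enter,
since no subset is distinguished.

## Counter-screen

With no cytoplasm stain, the cytoplasm is approximated by a ring (nucleus
dilated by 4 px, minus all nuclei); per-image background (5th percentile)
is subtracted from both compartments. Degenerate cases are defined rather
than propagated: a uniform image scores ratio 1 (no differential signal), a
nuclear-only signal floors the cytoplasmic estimate at 1% of the nuclear
mean (ratio ≤ 100), crowded cells with empty rings are skipped, and wells
with < 10 measurable cells are invalid. Translocation inhibition is the
linear position of a compound's well ratio between same-run stimulated and
saturating-inhibitor anchors, clipped to [0, 1]; a run whose anchors are
indistinguishable is invalid. Hits with strength ≥ 15 split at inhibition
0.5 (config) into receptor-like versus plasticity modulators; weaker
compounds are indeterminate. The generator's ratio anchors (3.0 stimulated,
1.2 unstimulated) render as exact disk/annulus intensities, so noise-free
round-trips recover inhibition to numerical precision.

## Determinism and problem sizes

Every generator takes an explicit seed (single `numpy` Generator per
operation, no global state); the pipeline derives per-stage seeds from the
config seed by hashing, and reruns are byte-identical. The test suite and
`scripts/acceptance.py` use the default desk-scale screen (4 × 384 wells;
5 independent screens in the acceptance script), 256² px fields, and
≤ 64×64 fixtures for the brute-force oracle comparisons.
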