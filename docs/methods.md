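# Methods

`enhancerscreen` implements the computational side of a genome-wide,
chromatin-integrated enhancer reporter screen: a library of ATAC-derived
fragments is integrated single-copy upstream of a minimal-promoter YFP
reporter, cells are differentiated through five stages (ES, HB, HE1, HE2,
HP) and FACS-sorted into four YFP intensity bins, and each recovered
fragment's coordinates plus its sort bin constitute one measurement of
enhancer activity. The package covers fragment reconstruction and
filtering, enhancer-positive site calling, motif co-localization and
enrichment statistics, differential chromatin accessibility, and
enhancer-to-gene linking — together with a synthetic-data generator that
produces the whole input universe with known ground truth.

## Coordinate and interval conventions

All coordinates are 0-based half-open (BED convention); 1-based dialects
must be converted at the reader boundary. Interval sets iterate sorted by
(chromosome, start, end, name) with stable tie-breaking, so every table and
file the pipeline emits is reproducible byte-for-byte. Overlap length is
`max(0, min(ends) − max(starts))`; an overlap requires at least 1 shared
base unless a larger `min_bp` is requested.

## Fragment reconstruction and filtering

Read pairs (BEDPE) become fragments spanning `min(start1, start2)` to
`max(end1, end2)`, which handles reversed mate order symmetrically; pairs on
different chromosomes or spanning more than 600 bp (the aligner's insert
cap; configurable) are dropped into a discard ledger, never silently. When
MAPQ is present, pairs are kept only with MAPQ strictly greater than 40;
records without MAPQ are treated as pre-filtered upstream.

The per-sample filtering chain is:

1. **Deduplication** — one record per distinct (chrom, start, end). When
   coordinate-identical records carry different YFP bins, the
   highest-intensity bin wins, so a genuine sorting event is never masked by
   a coincidentally identical fragment.
2. **Background removal** — a background library amplified from
   untransfected DNA defines PCR artifacts; any fragment with a *perfect*
   coordinate match in it is removed. Partial overlaps are retained.
3. **Open-chromatin restriction** — fragments must overlap (≥ 1 bp) an
   open-chromatin site of their own differentiation stage.
4. **Promoter/distal classification** — an element is promoter-proximal iff
   its center lies within 1.5 kb (inclusive) of the nearest TSS; the
   inclusive boundary is a determinism choice.

Every step records input = retained + removed per stage × replicate in a
`FilterLedger`; reconciliation is asserted, not assumed.

## Site calling and the activity matrix

A site is called enhancer-positive in a replicate iff at least one
overlapping fragment was sorted into the low, medium or high YFP bin;
negative-bin-only sites are "negative/unknown", because a non-scoring
fragment may simply have missed the relevant binding sites. Intensity
gradation is carried as metadata but does not enter the call. Replicate
consensus is a strict site-level intersection (positive in both replicates);
fragment-level consensus is available but makes no equivalence claim.

For the cross-stage view, per-stage site sets are merged by single-linkage
overlap into union elements (the merged element takes the union span), each
element gets a 5-character binary pattern code over the stages (e.g.
`00111`), and rows are sorted by pattern then coordinate. A site is
stage-specific iff active in exactly one stage.

## Motif co-localization z-score

For a set of "specific" regions (typically stage-specific positive
enhancers), every unordered pair of motif hit instances whose centers lie
within 50 bp is counted, including homotypic pairs (k mutually close
instances of one motif contribute C(k, 2) to the diagonal). Pairs of
coordinate-identical hit intervals are excluded — they arise from
overlapping motif definitions, not biology. Center-to-center distance is
the default anchor because it is symmetric in motif width; an edge-to-edge
gap mode exists behind a flag.

The null distribution for a pair is built by drawing, repeatedly (default
1000 reps), the same number of regions uniformly without replacement from
the universe of all distal open-chromatin sites of the stage, and
recounting. With observed count x, resample mean μ and sample standard
deviation σ (ddof = 1),

    z = (x − μ) / σ.

When σ = 0, z is 0 if x = μ and ±cap (default 10) otherwise, with a flag.
One seeded generator drives the whole resampling run, so results are
reproducible. Draws are count-matched to the specific set; length-matched
sampling is not implemented.

Calibration: when the specific set is itself a uniform draw from the
universe, x and the null draws are identically distributed, so E[z] ≈ 0 per
pair. Because all pairs of one draw share the draw's aggregate hit density,
z values are strongly correlated within a draw; the calibration check
therefore pools z over several independent uniform draws per null so that
the Monte-Carlo error of the pooled mean (~0.03 here) is small relative to
the acceptance band, and the check measures calibration rather than
single-draw luck.

## Relative motif enrichment

For motif i in peak set j, with n_ij motif instances and m_j sites in set j,

    S_ij = (n_ij / m_j) / (Σ_j n_ij / Σ_j m_j),

the per-set rate over the pooled rate. The m_j-weighted mean of every
defined row is identically 1 (asserted to 1e-9); rows with no instances
anywhere are flagged undefined rather than forced to a value. For heatmap
display the package provides row/column z-scaling (constant vectors flagged
and zeroed) and complete-linkage hierarchical clustering of Euclidean
distances via scipy, returning the leaf order and merge tree; rendering
itself is out of scope.

## Differential accessibility

Peak sets of two conditions are merged into a union (overlapping peaks take
the union span; the summit of the taller peak wins, ties to the leftmost).
Tags are counted in a 400 bp half-open window centred on each summit
(windows leaving chromosome bounds are clipped and flagged). Counts are
normalized to counts-per-million per sample, transformed as log2(CPM + 1),
and replicates are averaged after the transform. A site is gained (lost)
when the condition means differ by at least log2(2) on that scale. The
alternative reading — a two-fold ratio of raw CPM — is available via a
flag; the log-difference form is the default because the transform precedes
all comparisons and the pseudo-count guards zeros.

Caveat worth knowing: CPM normalization is compositional. If a large
fraction of sites is genuinely amplified in one condition, the library-size
rescaling shrinks every fold change (e.g. 30% of sites at 4× drags the
effective CPM fold to ~2.1, at the calling threshold). The generator's
default plants 10% of sites, where the effective fold (~3×) is comfortably
detectable; analyses of globally shifted libraries need an external
normalization, which is out of scope here.

## Enhancer–gene linking

An enhancer is linked to a gene when it overlaps (≥ 1 bp) one anchor of a
chromatin-interaction pair whose other anchor overlaps the gene's promoter
window, in either anchor orientation. Promoter windows are TSS ± 1500 bp,
reusing the pipeline's promoter definition. Optional co-regulation link
tables merge in unchanged. Enhancers untouched by any interaction fall back
to the nearest TSS by center distance, ties broken by smaller coordinate
then lexicographic gene id, so every enhancer ends with at least one link
and a recorded method. Multi-linked enhancers keep all links; fraction-type
summaries count an enhancer once (any-link semantics).

The responsive-linkage fraction is |responsive enhancers with ≥ 1 link to a
responsive gene| / |responsive enhancers with ≥ 1 link|, with contingency
counts reported and an explicitly undefined result for an empty
denominator.

## The synthetic screen generator

The generator emulates the screen's data universe under one seeded
configuration; two runs with the same `SimConfig` are byte-identical.

* **Geometry.** Candidate loci (200–1000 bp, summit inside) are placed on a
  slot grid with ≥ 700 bp gaps and, for distal loci, edges ≥ 2.2 kb from
  every TSS; a configurable fraction sits within 1.4 kb of a TSS to
  populate the promoter class. Because reporter fragments are at most
  650 bp, no fragment can bridge two loci and promoter-locus fragments
  cannot reach distal loci — under noiseless settings the calling pipeline
  must recover truth exactly, and any deviation is a bug, not noise.
* **Stage structure.** A `site_sharing` fraction of each stage's sites is
  constitutive (shared by all five stages); the rest are stage-exclusive.
  Among the open sites of a stage, a `true_positive_fraction` (default 0.3)
  is truly active.
* **Fragments.** Truly active loci emit at least one positive-bin fragment
  per replicate plus Poisson extras; all open loci emit negative-bin
  fragments. Lengths are uniform in 350–650 bp (the library's size
  selection) and every fragment overlaps its source locus. Exact duplicates
  are injected at `duplicate_rate`; background artifacts are written both
  to a standalone background library and spiked verbatim into samples at
  `background_artifact_rate` (default 1%, a free parameter), so
  perfect-overlap removal is genuinely exercised.
* **Motif hits.** Baseline hits are Poisson per locus per motif (default
  rate 1), placed uniformly. Planted co-localizations *reposition* existing
  hits of the pair's second motif next to hits of the first (within
  `max_dist`, default 40 bp) rather than inserting new ones: insertion
  would inflate the planted motifs' marginal hit counts and contaminate
  every pair involving them, whereas repositioning changes only the
  targeted pair's co-location rate. The price is saturation — the achieved
  rate multiplier is capped by the number of available partner hits (a
  requested 5× yields ~3.3× at baseline rate 1), which is ample for z ≫ 3.
* **Counts.** Per-site counts are negative binomial with variance
  μ + φμ² (φ → 0 recovers Poisson); a planted subset is multiplied by a
  configured fold in condition B, with truth recorded.
* **Interactions and expression.** A coverage fraction of true
  enhancer→gene links (gene drawn among the 3 nearest TSS) is emitted as
  anchor pairs (locus interval ↔ promoter window); the rest are left to the
  nearest-TSS fallback. Gene expression per stage is two-level — high when
  ≥ 1 truth-linked enhancer is active, low otherwise — plus Gaussian noise.

What the generator does **not** emulate: sequence (no FASTA/PWM sampling or
read-level errors), realistic fragment-length mixtures, chromatin-domain
structure, distance-dependent interaction frequencies, or a full
transcriptomic model. Passing tests therefore demonstrate the correctness
and calibration of the pipeline's logic and statistics under controlled
conditions, not performance on the noise structure of real libraries.

## Numerical and tie-breaking choices

* Sorting ties broken by (chrom lexicographic, start, end, name);
  mergesort (stable) throughout.
* Resampling σ uses ddof = 1; z capping at ±10 with flags.
* z-scaling uses population sd; constant vectors flag and zero.
* Clustering delegates to scipy's complete linkage, which resolves distance
  ties deterministically by merge order.
* Degenerate inputs raise early: empty TSS sets, zero column totals,
  fold ≤ 1, n_draw exceeding the universe, summits outside peaks.

## Problem sizes used in validation

The shipped test-suite and acceptance runs use: 5000-site universes with
500-site draws and 500 resampling reps (×10 null seeds, 10 uniform draws
each) for calibration; 1000 sites/stage with ~500 stage-specific positives
and 200 reps for planted-pair recovery; 2000 sites/stage across 5 stages
(34,000 site calls) with 30% duplicates and 5% background spike-ins for
end-to-end recovery; 1700-site count tables for differential calls; and
3500 enhancers for linking. These sizes give every statistical check a
comfortable margin while a full validation run completes in about a minute.

## Known limitations

* The calling model is binary; bin intensities are carried but unused, and
  quantitative enhancer strength is out of scope.
* Pair counting counts instance pairs, so a clique of 3 mutually close
  hits yields 3 pairs; event-level (clique) counting is not offered.
* CPM compositional bias (above) is documented, not corrected.
* Nearest-gene fallback is intra-chromosomal; an enhancer on a chromosome
  with no annotated TSS is an error rather than a cross-chromosome guess.
* The interaction linker treats anchors as given; no significance modelling
  of interaction calls is performed.
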