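# Methods

This note documents the models, conventions, and design choices behind
nucblur, and what the synthetic-data generator does and does not emulate.

## Occupancy tracks

A nucleosome tag is an inferred 146-bp nuclease-protected fragment
defined by its sequenced 5′ end; the occupancy of a basepair is the
number of tags spanning it. `coverage_from_tags` treats every tag start
as the leftmost basepair of a 146-bp interval (any strand column in the
input is ignored, since the 3′ end is defined by construction) and
truncates tags at chromosome ends, so total occupancy is exactly
`146 × n_tags − truncated basepairs`. All coordinates, in memory and on
disk (bedGraph, sites TSV), are 0-based half-open.

Normalization to genome-wide mean 1 divides by the pooled mean over all
chromosomes; scaling a library to a reference either matches genome-wide
totals (the default for difference maps — totals and means differ only by
a constant, and totals are the simpler reading) or matches the mean over
flank basepairs 100–600 bp from a set of site centers, which is the right
choice when the site-proximal signal itself is the quantity under study.

## Windowing and blurring

Lower-resolution data is emulated by averaging over centered windows of
15, 40, 75, 150, 300 and 600 bp. The window for a motif starts at
`center − size//2`; even-length motifs have no central basepair, so the
left of the two middle basepairs is the center and the window is extended
one basepair rightward. `blur` applies the same window per basepair as a
sliding mean. At chromosome ends windows shrink to the available
basepairs rather than producing missing values, so downstream statistics
never see NaNs; consequently the genome-wide mean of a blurred random
track matches the input only to order `window/chromosome length`, which
is negligible for the intended window sizes. Blurring is linear and
agrees exactly with `window_average` at interior loci.

Site-centered profiles (`extract_profile`) average occupancy at offsets
−H..+H around site centers; minus-strand sites are reversed first, so
positive offsets always mean "downstream of the motif" (the convention is
invisible for palindromic displays, which are symmetrized anyway). Sites
whose window would be clipped are dropped and counted.

## Association statistics

The occupancy/binding association is the ROC area with bound motifs as
positives and random promoter basepairs as negatives. With
`low_predicts_positive`, `AUC = P(s_pos < s_neg) + ½ P(tie)`, computed by
midranks (the normalized Mann–Whitney U), which handles the heavy ties of
integer tag counts exactly. Random-promoter backgrounds are drawn
uniformly from the union of promoter intervals with replacement; they may
include bound promoters, which makes absolute AUCs conservative — the
same convention makes AUCs *comparable* across window sizes because one
control set is reused for all sizes. Bootstrap CIs are percentile
intervals from 1000 resamples of both classes.

The blurring delta is `ΔAUC = AUC(600) − AUC(15)` per TF; across TFs,
|Δ| is classified against the mean and sample SD (ddof = 1) of the |Δ|
distribution into `<1σ`, `1–2σ`, `≥2σ`, with the sign reported
separately.

qPCR enrichment uses ΔΔCt arithmetic: per replicate,
`ΔCt = Ct_IP − Ct_input` and the reference is the mean ΔCt of exactly two
control sites; per site, `fold = 2^(−mean over replicates of ΔΔCt)`.
Before correlating log2 fold with tag counts, folds below 1 are clamped
to 1 and tag counts above 600 to 600; the fit is ordinary least squares
of log2 enrichment on tag count (the log base affects only the reported
slope, not r), with a one-sided p-value available for the anti-correlation
alternative r < 0.

## Profile clustering

Each TF's feature is the catenation of the central 600 bp of its
symmetrized, mean-normalized in vivo profile and the same for the in
vitro profile (1200 values). `ProfileKMeans` z-scores each row and runs
Euclidean k-means (best inertia of 20 restarts, explicit seed). For
z-scored rows `‖z_i − z_j‖² = 2p(1 − r_ij)`, so the clustering is exactly
the Pearson-similarity clustering and is invariant to any per-profile
affine rescaling — which also makes the choice between "normalize to mean
1" and "normalize to mean 0" immaterial for the clustering itself
(display defaults to mean 1). Rows with zero variance map to the zero
vector rather than erroring, so structureless profiles cluster together.
`k = 5` by default, exposed as a parameter. Within clusters TFs are
ranked by the in vitro 600-vs-15-bp ΔAUC, descending, ties broken by
name.

## Thermodynamic binding model

For a PWM with probabilities `p_j(b)` (pseudocount 0.01, renormalized),
every motif-length window on both strands gets a relative association
constant `Ka_rel = Π_j p_j(base_j)/0.25` — the standard likelihood-ratio
correspondence between PWM score and relative affinity. Windows
containing N are skipped. Given a concentration `c`, a window is occupied
with probability `c·Ka/(1 + c·Ka)` and a promoter is bound if at least
one window is, treating windows as independent:
`P = 1 − exp(Σ log(1 − p_i))`. The default `c = 1/max_genome(Ka_rel)`
half-occupies the best site in the genome; all weighting variants share
one `c` so their rankings are comparable.

Occupancy weights: the genome is tiled into non-overlapping 15-bp
segments; a segment's occupancy is its local mean tag count (or the mean
of a centered regional window, 600 bp by default, 300 bp available via
`regional_window`), expressed as `Q` = occupancy divided by the
genome-wide SD of per-segment local means — measured from zero with no
mean subtraction, so segments with no mapped tags (e.g. unmappable
sequence) get weight exactly 1. The weight is `W^(−Q)` with `W = 4`,
fixed rather than fitted; higher occupancy thus lowers affinity
exponentially. A window's Ka is multiplied by the weight of the segment
containing the window's center (both strands alike) — the simplest
deterministic rule on the 15-bp grid. The SD is always that of the
*local* segment means, so local and regional Q share one scale.

## The synthetic generator

The generator emulates the statistical structure the analyses exploit,
at a scale where the whole pipeline runs in seconds: one 300-kb
chromosome with 300 evenly spaced genes (600-bp promoters covering ~60%
of the genome, yeast-like; bound promoters are a minority of the
random-promoter background), uniform-ACGT sequence, a near-deterministic
8-bp PWM whose consensus is written into 50 bound and 60 unbound
promoters, and per-bp Poisson tag counts around a mean depth of 10.

Key modeling choices, each reflecting a feature of real data:

* **Bound-site heterogeneity.** ChIP-based "bound" calls (p < 0.001) are
  liberal; half the bound sites get no planted NDR at all and the rest
  get dip depths uniform on (0, 0.8]. This is what keeps
  depletion-vs-binding AUCs in the realistic 0.6–0.8 range instead of
  saturating near 1, and it is essential for any faithful comparison of
  statistics across maps.
* **Mass-conserving in vivo NDRs.** The displaced nucleosome mass is
  piled into compensating bumps at the first phased flanking positions
  (repeat 165 bp, decaying cosine over ~3 repeats), so a 600-bp average
  sees roughly the genomic mean — which is exactly why blurring destroys
  the in vivo association.
* **Intrinsic (in vitro) regimes.** A genome-wide random-phase cosine
  positioning signal (amplitude 0.6, a few-fold peak-to-trough ratio)
  underlies all regimes. `local_ndr` mirrors the in vivo structure;
  `broad_poor`/`regional_depletion` plant a promoter-scale smooth
  depression whose center is displaced randomly (±250 bp) from the site,
  so the site-local value carries no information beyond the regional
  level — the defining property of the class; `occluded_site` puts a
  well-bound nucleosome on the site inside a poor region;
  `flank_enriched` over-compensates the flanks.
* **Labile nucleosomes.** The crosslinked track equals the in vivo track
  plus a constant tag excess (+5/bp) over a 146-bp span at labile bound
  sites. Lability is assigned preferentially to NDR-bearing sites, since
  TF–nucleosome competition produces both; with half the bound sites
  labile, the difference map predicts binding about as well as depletion
  itself — the qualitative behavior of real crosslink/uncrosslink pairs.
* **qPCR.** Planted log2 enrichment is
  `baseline − slope × occupancy_SD + noise` with baseline 3 (assayed
  consensus sites are genuinely bound, ~8-fold on average, so the clamp
  at fold 1 rarely censors), slope 1, and 0.5-cycle noise; controls are
  noise-free at enrichment 1, making the noise-free pipeline round trip
  exact.
* **Profile archetypes.** For clustering recovery, five feature shapes
  (broad-poor, narrow NDR, occluded site, flank-enriched, flat) with
  pairwise z-scored correlations ≤ 0.44 are jittered with 8% Gaussian
  noise, the scatter expected of a profile averaged over a few dozen
  sites at ~10× depth.

All randomness flows from explicit seeds through spawned generator
streams; identical configuration and seed give bit-identical output, and
the emitted truth tables suffice to recompute every planted quantity.

What the generator does **not** emulate: sequence-dependent nucleosome
energetics (dinucleotide periodicity, poly(dA:dT) exclusion), MNase
sequence bias, mappability structure, replicate-level variation, or
TF–TF cooperativity. Tests passing on synthetic data therefore validate
the *statistical machinery* — estimators, conventions, directions of
effects — not biological discovery on real chromatin.

## Problem sizes and determinism

Default analyses use 50 bound sites, 200–1000 random promoter controls,
1000 bootstrap replicates, and 20-replicate direction checks; these sizes
give standard errors of a few hundredths of an AUC while keeping any
single analysis under a few seconds. Stochastic direction claims
(blurring helps broad regimes, hurts narrow ones) are stated as
majorities over seeded replicates rather than certainties: real TF sets
behave the same way, with a minority of factors going against each trend.

## Known limitations

* The independent-window approximation in the binding model ignores
  overlap between windows; for sharply peaked PWMs the error is
  negligible, for information-poor PWMs promoter probabilities are
  slightly inflated.
* Difference maps inherit the Poisson noise of both libraries; at low
  depth the per-bp difference is dominated by noise and only windowed
  scores are meaningful.
* Edge-shrunk blurring slightly biases statistics within one window of a
  chromosome end; sites that close to an end are dropped from profiles
  anyway.
* The probe-assignment rule (probe containing the site center) and the
  with-replacement promoter sampling are conventions chosen for
  determinism; alternatives (any-overlap assignment, without-replacement
  sampling) would change results only marginally and are not exposed.
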