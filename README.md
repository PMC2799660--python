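# nucblur

Analysis pipeline for relating **nucleosome occupancy maps** to
**transcription-factor (TF) binding** in a compact genome, built around a
deliberately simple question: does TF binding care about the *precise*
position of nucleosomes, or only about the *regional* nucleosome density?

The package is aimed at regulatory genomicists working with
MNase-protection sequence tags (in vivo crosslinked / uncrosslinked
chromatin, or chromatin reconstituted in vitro), motif-site calls with
ChIP enrichment p-values, and PWMs.

## What it computes

* **Occupancy tracks.** A nucleosome "tag" is an inferred 146-bp
  nuclease-protected fragment; the number of tags spanning a basepair is
  the occupancy there. `coverage_from_tags` builds per-bp tracks from tag
  5′ starts; tracks can be normalized to mean 1 and scaled to a reference
  library.
* **Blurring.** `blur` and `window_average` replace per-bp occupancy with
  its mean over centered windows of 15–600 bp, emulating lower-resolution
  data.
* **Difference maps.** `difference_map` forms crosslinked − (scaled)
  uncrosslinked occupancy; positive peaks mark "labile" nucleosomes
  trapped by the crosslinker, which concentrate at TF binding sites.
* **Association statistics.** The occupancy/binding association is the ROC
  area: with positives the bound motifs and negatives random promoter
  basepairs, `AUC = P(score_pos < score_neg) + ½P(tie)` (the normalized
  Mann–Whitney U; low occupancy predicts binding). Bootstrap CIs, the
  blurring delta `ΔAUC = AUC(600 bp) − AUC(15 bp)` and its σ-classification
  across TFs, and ChIP-qPCR ΔΔCt fold enrichments
  (`fold = 2^(−ΔΔCt)` against the mean of two control sites) complete the
  statistics layer.
* **Profile clustering.** Per-TF 1200-value features (central 600 bp of
  the symmetrized, mean-normalized in vivo profile catenated with the in
  vitro one) are grouped by `ProfileKMeans`, a scikit-learn estimator that
  z-scores rows so Euclidean k-means orders points exactly like
  1 − Pearson correlation.
* **Thermodynamic binding model.** `GomerModel` scores every motif window
  on both strands with a PWM likelihood ratio
  `Ka_rel = Π p_j(base)/0.25`, occupies each window with probability
  `c·Ka/(1 + c·Ka)`, and reports
  `P(bound) = 1 − Π(1 − p_i)` per promoter. Nucleosome occupancy enters as
  weights on non-overlapping 15-bp segments: `weight = W^(−Q)` with
  `W = 4` and `Q` the tag count in SD-above-zero units, taken either from
  the segment itself (local) or from a 600-bp window around it (regional,
  i.e. blurred).
* **Synthetic studies.** `simulate_study` generates a genome, a PWM,
  planted bound/unbound motifs, the three tag maps (in vivo, in vitro,
  crosslinked) under several occupancy regimes, explicit tag starts, and a
  matching qPCR Ct table — with full ground truth, so every stage of the
  pipeline can be verified end to end.

## Worked example

```python
import nucblur as nb

bundle = nb.simulate_study(nb.SimConfig(regime="local_ndr"), seed=7)
bound = bundle.sites[bundle.sites["bound"]]
promoters = nb.promoters_from_gene_starts(bundle.genome, bundle.gene_starts)
controls = nb.random_promoter_sites(promoters, 200, seed=8)

res = nb.delta_auc(bundle.maps["invivo"], bound, controls)
for size, rr in res["aucs"].items():
    print(f"window {size:>3} bp: AUC = {rr.auc:.3f}")
print(f"delta AUC (600 vs 15 bp) = {res['delta']:+.3f}")

dm = nb.difference_map(bundle.maps["xlink"], bundle.maps["invivo"])
pos = [nb.window_average(dm, r.chrom, nb.site_center(r.start, r.end), 15,
                         motif_even=(r.end - r.start) % 2 == 0)
       for r in bound.itertuples(index=False)]
neg = [nb.window_average(dm, r.chrom, int(r.pos), 15)
       for r in controls.itertuples(index=False)]
print(f"difference-map AUC = "
      f"{nb.roc_auc(pos, neg, low_predicts_positive=False).auc:.3f}")
```

prints

```
window  15 bp: AUC = 0.729
window  40 bp: AUC = 0.756
window  75 bp: AUC = 0.764
window 150 bp: AUC = 0.780
window 300 bp: AUC = 0.732
window 600 bp: AUC = 0.509
delta AUC (600 vs 15 bp) = -0.220
difference-map AUC = 0.758
```

Reading the output: at 15 bp resolution, low in vivo occupancy identifies
bound motifs well above chance (AUC 0.73); windows of 40–150 bp do
slightly better because the planted nucleosome-depleted regions are
50–150 bp wide; by 600 bp the window swallows the compensating phased
flanking nucleosomes and the association collapses to chance (0.51) —
ΔAUC is −0.22. Excess tags in the crosslinked library (the difference
map) predict binding about as well as depletion itself does (0.76 vs
0.73). Running the same analysis on a `broad_poor` in vitro regime flips
the sign of ΔAUC: when low occupancy is regional rather than precisely
positioned, blurring *helps*.

A `nucblur` command-line tool mirrors the library
(`simulate`, `coverage`, `blur`, `diffmap`, `roc`, `cluster`, `predict`);
every stochastic subcommand takes an explicit `--seed`.

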