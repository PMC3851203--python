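# epienrich

Enrichment profiling of genomic region-set families against a
pooled-universe sampled null.

`epienrich` answers a question that comes up whenever a genome carries many
*families* of elements (non-coding RNA classes such as tRNAs, miRNAs,
piRNAs, snoRNAs) and many *annotation tracks* (chromatin states, histone
modification peaks, transcription factor binding sites): which annotations
distinguish one family from the rest, and which families look alike by
their annotation profile?  It is aimed at regulatory-genomics analysts who
have one BED file per family and one BED file per track and want a
reproducible, statistically calibrated association matrix rather than a
one-off overlap count.

## The statistic

For a family (query class) of size $n$ and one annotation track, the
observed count $O$ is the number of members sharing at least 1 nt with at
least one track interval — a member touching three intervals still counts
once.  The null is *pooled*: draw $n$ members without replacement from the
union of all families, recount, and repeat (1000 samplings by default),
giving the null mean $E$ (and variance, kept as a diagnostic).  Using the
pool rather than the whole genome asks specifically what distinguishes a
family from elements of its own kind.  The test is a df-1 chi-square of
$O$ against $E$,

$$\chi^2 = \frac{(O - E)^2}{n\,p_0(1 - p_0)}, \qquad p_0 = E/n,$$

with direction *enriched* ($O > E$) or *depleted* ($O < E$).  P-values are
Benjamini–Hochberg corrected (per class across tracks by default) and
transformed to signed scores $s = \pm(-\log_{10} p_{\mathrm{adj}})$,
negative for depletion.  The class × track score matrix is then:

- **filtered** — tracks significant in no class ($\min p_{\mathrm{adj}}
  \ge \alpha$, default $\alpha = 0.01$) or flat across classes (score SD
  < 2) are dropped;
- **clustered** — Ward agglomeration on Chebyshev (maximum) distances,
  for classes and tracks, exported as Newick and a blue–yellow heatmap;
- **correlated** — Pearson correlation between class score profiles, with
  a per-class table of the best-correlated and best-anticorrelated partner
  class.

A synthetic-study generator produces pooled universes with *planted*
per-(class, track) overlap-rate multipliers and a truth manifest, so the
whole pipeline is testable without any downloads.

## Worked example

```python
from epienrich import RegionEnrichment, generate_study, ncrna_study_spec

study = generate_study(ncrna_study_spec(n_tracks=40, seed=11))
model = RegionEnrichment.from_study(study)     # or .from_bed_dirs(qdir, adir)
results = model.fit(n_samplings=200, seed=11)
print(results.summary(top=5))
```

```
Region-set enrichment profile
================================================================
classes:    15    tracks:    40    pairs tested: 600
samplings per pair: 200    seed: 11    statistic: gof
BH scope: per_class    alpha: 0.01    SD filter: 2.0
pairs with p_adj < alpha: 26

top associations by |score| (signed -log10 adjusted p):
 class    track  observed  expected     p_adj direction  score
snoRNA track_25       562     283.2 1.342e-83  enriched  82.87
 miRNA track_10       621     313.2 7.122e-77  enriched  76.15
  tRNA track_05       216     67.67 8.562e-77  enriched  76.07
 piRNA track_15        78     298.9 1.579e-41  depleted  -40.8
CD_box track_05       113      37.3 2.524e-36  enriched   35.6
```

The study planted, among others, a 4.0× overlap-rate multiplier for tRNA
and 2.2× for snoRNA on their tracks and a 0.25× (depleting) multiplier for
piRNA: each shows up with the right sign, an observed count far from the
pooled expectation, and a huge signed score.  Classes planted on the same
track end up with near-identical profiles:

```python
print(results.best_partners().head(4).to_string(index=False))
```

```
   class best_partner   best_r worst_partner   worst_r
     7SK       scaRNA 0.481533  spliceosomal -0.978802
  CD_box         tRNA 0.999958        scaRNA -0.448301
HACA_box       snoRNA 0.994756     pri_miRNA -0.592537
  lncRNA          7SK 0.285903         miRNA -0.658785
```

CD-box and tRNA (both enriched on `track_05`) correlate at r ≈ 1.00;
HACA-box pairs with snoRNA (shared `track_25` enrichment).
`results.save("out/")` writes the enrichment table, full/filtered
matrices, dendrograms, correlation and partner tables, heatmap, and a
manifest with checksums.  The same pipeline runs from the shell:

```
epienrich generate --out-dir study --seed 11
epienrich run --query-dir study/queries --annotation-dir study/annotations \
              --output-dir out --n-samplings 1000 --seed 11
epienrich validate --query-dir study/queries --annotation-dir study/annotations
```

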