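# Methods

## Model and assumptions

`epienrich` tests families of genomic intervals (query classes) for
enrichment or depletion in annotation tracks, using the union of all
classes as the sampling universe.  The model assumes:

- **Half-open BED coordinates.**  Overlap means sharing at least one
  nucleotide: `max(starts) < min(ends)`.  Strand is carried through I/O but
  never consulted by overlap tests — annotations of the kind targeted here
  (chromatin states, ChIP-seq peaks) are unstranded.
- **Member-centric counting.**  The unit of evidence is the class member,
  not the base pair or the annotation interval.  A member touching many
  track intervals contributes one count; duplicate coordinates remain
  countable members.  The amount of overlap is deliberately ignored.
- **Pooled null.**  A pseudo-class is a uniform without-replacement draw of
  the same size from the pooled universe, including the class under test
  (no exclusion — the pool is simply "all elements of this kind").
  Conditional on the data, each pool member's overlap status against a
  track is a fixed Boolean, so the null count is exactly hypergeometric;
  the package nevertheless *samples* the null (default 1000 samplings),
  which keeps the estimator agnostic to that reduction and retains the
  per-sampling counts for diagnostics.  The closed form is used as an
  independent oracle in the tests, never as the implementation.
- **Exact chromosome names.**  `chr1` and `1` are different strings; the
  input validator reports query chromosomes absent from all annotations
  rather than aliasing them.

## The test statistic

For observed count `O`, class size `n` and sampled null mean `E`, the
default statistic is the one-sample (goodness-of-fit) chi-square with
df = 1 and no continuity correction:

    chi2 = (O - E)^2 / (n * p0 * (1 - p0)),   p0 = E / n

Direction is the sign of `O - E`; an exact tie yields `chi2 = 0, p = 1,
direction = none`.

An alternative construction — the Pearson chi-square on the 2×2 table
`[[O, n-O], [E, n-E]]` — is available as `statistic="contingency"` (with an
optional Yates correction flag).  It is not the default because it treats
the null expectation as a second observed sample of size `n`, doubling the
assumed variance; under the sampling null it rejects at roughly 0.5%
when nominal 5% is intended.  The goodness-of-fit form treats `E/n` as a
known null probability and is nearly calibrated: in the package's own
calibration run (500 null classes of size 200 from a pool of 5,000 at
overlap fraction 0.3) it rejects at ≈ 0.04 at α = 0.05.  It remains
slightly conservative because sampling without replacement shrinks the
true variance by the finite-population factor `(N - k)/(N - 1)`; the
sampled variance is retained in `NullDistribution` for diagnostics but is
not plugged into the statistic.

`p_adj = 0` cannot occur (chi-square survival values underflow to 0 only
below ~1e-308); adjusted p-values are floored at `1e-300` before the
signed `-log10` transform so scores stay finite (|score| ≤ 300).

## Multiple testing and scores

Benjamini–Hochberg correction runs *per class across tracks* by default
(`bh_scope="per_class"`), mirroring per-family reporting of adjusted
series; `bh_scope="global"` corrects across the whole class × track
matrix instead.  Scores are `-log10(p_adj)`, negated for depletion, 0 for
ties — so the matrix entry is symmetric under swapping
enrichment/depletion at fixed p.

## Matrix filtering and variability

Two column rules (classes are never removed):

- **presence**: keep a track only if some class reaches `p_adj < alpha`
  (default 0.01);
- **flatness**: keep a track only if the sample SD (n−1 denominator) of
  its signed scores across classes is ≥ `sd_min` (default 2.0) — a track
  that associates equally with every class says nothing about what
  distinguishes them.

`alpha = 1` or `sd_min = 0` disables the respective rule (making the
filter the identity), and the flatness rule is skipped with fewer than two
classes, where a sample SD is undefined.  The filter is idempotent.

Per-class variability (score SD across **all** tracks, unfiltered) is
reported together with its Pearson correlation against class size, both
for all classes and after excluding a configurable label set — large or
strongly associated families can dominate the spread, and the excluded
rerun shows how much they do.  With fewer than 3 classes the correlation
is reported as NaN.

## Similarity and clustering

Profile correlations are Pearson coefficients between class score vectors
over the presence-passing tracks (flatness rule *not* applied there, so
consistent-but-significant tracks still inform similarity); an explicit
track list can override the rule.  Constant profiles get NaN rows flagged
by label — zero-filling would fabricate similarity.  Partner tables take
the off-diagonal argmax/argmin per class, ties resolved toward the earlier
label, NaNs excluded.

Clustering is agglomerative Ward on Chebyshev (maximum-coordinate)
distances.  The Ward step applies the Lance–Williams recurrence to the
supplied distances **as given** (the classical behaviour predating the
squared-distance disambiguation); `ward_squared=True` applies it to
squared distances and reports square roots of merge criteria, which on
Euclidean inputs reproduces `scipy.cluster.hierarchy.linkage(...,
"ward")`.  Class clustering defaults to Chebyshev distances between rows
of the correlation matrix (`on="correlation"`); `on="scores"` clusters the
filtered score profiles directly.  Track clustering uses the filtered
matrix columns.  Dendrograms export as Newick with branch length =
parent merge height − child merge height, so root-to-leaf path length
equals the root height.

Heatmaps use a symmetric blue–black–yellow palette about zero (blue =
depleted, yellow = enriched); a display cap clips only the exported table
and image, never the analysis matrix.

## Synthetic studies

The generator emulates the statistical shape of a multi-family ncRNA ×
epigenomic-track study: 15 classes of 52–3,024 members (16,701 total) with
right-skewed lengths spanning 15–8,302 nt, and tracks of non-overlapping
intervals covering 2–40% of a 100 Mb two-chromosome genome.  Lengths are
log-normal, parameterised from each family's (min, mean, max) range with
`sigma = ln(max/min)/4` clipped to [0.2, 1.2] and the mean matched, then
clipped to the range.

Planted effects: each member of a class with multiplier `m` on a track
overlaps it with probability `clip(m × coverage, 0, 1)` — designated
members start uniformly inside a length-weighted random track interval
(guaranteeing ≥ 1 nt), the rest are placed wholly inside the complement —
so the planted rate is exact by construction.  One planted track per class
(placement conditions on a single track).  Classes without effects are
placed uniformly over the genome.  Every generated study is self-audited:
realized rates of planted pairs must fall within 4 binomial SDs of target.
The default effect map plants twelve effects (multipliers 0.25–4.0) on six
moderate-coverage tracks, two deviating classes per track, so the default
study shows the differential, clusterable structure the analysis exists to
find.  A "shared-state" mode instead derives two correlated track groups
from one latent genomic partition and places two class groups to prefer
opposite states, for testing cluster recovery.

What the generator does **not** emulate: real sequence content, the strong
and heterogeneous correlation structure of real chromatin panels,
cell-type structure, mappability or assembly gaps, and class-specific
chromosomal clustering (e.g. tandem families).  Passing tests therefore
demonstrate statistical correctness and calibration of the machinery, not
biological conclusions about any real family.

## Reproducibility

One master seed drives everything.  Per-(class, track) substreams are
derived from `SeedSequence([seed, crc32(class), crc32(track)])`, so
results are independent of evaluation order and worker count; the fitted
pool is put in canonical coordinate order, making results independent of
input file enumeration order too.  Null sampling draws uniform k-subsets
by arg-partitioning rows of uniform variates (chunked to bound memory) and
sums precomputed per-member overlap Booleans — identical in distribution
and in contract to re-counting the sampled intervals, and fast enough for
hundreds of tracks × 1000 samplings on one CPU.  `save()` writes only
deterministic text tables plus a manifest of SHA-256 checksums; two runs
with the same configuration and seed are byte-identical.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen to
make every statistical property measurable in minutes on one CPU: the
null-moment check at pool 1,000 / 1,000 samplings; calibration with 500
replicate null classes (size 200, pool 5,000); planted-effect recovery
with 100 replicates per direction (class 500, pool 10,000, 1,000
samplings); the full default study at 15 × 40 with 200 samplings; and 20
shared-state seeds for cluster recovery.  Oracle-equivalence checks
(overlap counts, BH, Pearson, Chebyshev, Ward) run on hundreds of small
random fixtures at 1e-9 tolerance.

## Known limitations

- The chi-square remains an approximation; for very small expected counts
  (`E` near 0 or `n`) an exact hypergeometric test would be preferable.
- The pooled null conditions on observed overlap statuses; it does not
  model uncertainty in the annotation tracks themselves.
- Only one planted track per class in the generator; multi-track joint
  effects arise only indirectly (via the shared-state mode).
- Ward on Chebyshev distances has no variance interpretation; it is used
  as a reproducible convention, matching common practice for signed
  significance matrices, not as an optimality claim.
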