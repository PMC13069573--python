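# Methods

This note documents the models, conventions and numerical choices
behind `exprvar`, and what the synthetic-data tests do and do not
establish about real data.

## Normalized expression variability (NEV)

Per gene and timepoint, the mean and unbiased (n−1) variance are taken
across non-missing individuals (at least 2 required, configurable);
CV² = var/mean².  The mean–variance trend is fitted in
(log2 mean, log2 CV²) space with locally weighted regression
(statsmodels lowess), **span 0.3, one robustness iteration**, per
timepoint.  NEV = log2 CV² − fitted log2 CV² at that gene's mean, and
a gene's summarized NEV is the median over timepoints with defined
NEV, reported only when at least ⌈T/2⌉ timepoints are defined.

Choices and their reasons:

* *Smoother family and span.*  The underlying mean–CV² law of
  overdispersed counts (CV² ≈ 1/μ + φ₀) is curved in log–log space, so
  a local fit is used rather than a line.  Span 0.3 is wide enough to
  be stable at a few thousand genes and narrow enough to follow the
  curvature; the single robustness iteration downweights genes far
  above the trend so that a minority of genuinely hyper-variable genes
  does not inflate the reference level.
* *Per-timepoint fitting.*  The trend can differ between timepoints
  (library depth, circadian state), so each timepoint gets its own
  fit; pooling is available (`pool_timepoints=True`).
* *Filters.*  Points with mean < 1 expression unit or CV² = 0 are
  excluded from the fit (log space); CV² = 0 yields a missing NEV,
  never −∞.  Evaluation outside the fitted mean range clamps to the
  boundary value to avoid wild extrapolation for extreme-mean genes.
* *Units.*  Panels are taken as already-normalized expression; no
  library-size normalization is applied.
* *Known residual.*  Normalization removes most but not all of the
  mean dependence; the residual NEV–mean correlation is reported by a
  test, not forced to zero.

An important consequence of normalizing against the *observed*
mixture: when a large fraction of genes carries inflated variance, the
fitted trend rises toward them, shifting all NEVs down by a common
offset.  Group *differences* are preserved (this is what the group
contrasts use); absolute NEV recovery of a planted multiplier m (median
NEV ≈ log2 m) holds when the inflated group is a minority (the
recovery tests use 5–15% planted fractions).

## Synthetic-data generator

The generator emulates a per-seedling expression study with planted,
recorded ground truth:

* **Counts.** Negative binomial per (gene, individual, timepoint) with
  gene mean drawn log-uniformly on [5, 5000] and variance
  trend(m)·μ·m², trend(m) = 1/m + φ₀ with φ₀ = 0.05 — a ~22% CV floor
  at high expression, a realistic inter-individual level for bulk
  RNA-seq of clonal seedlings.  The planted multiplier μ acts on the
  variance above the trend, so expected NEV = log2 μ by construction.
* **Design defaults.** 14 individuals and 6 timepoints (a diurnal
  series); 800 singletons + 400 SSD pairs + 400 WGD pairs, i.e. ~67%
  duplicated genes, matching the ~65% duplicate fraction typical of
  plant genomes.  Group multipliers: singleton 1, SSD 2, WGD 2, plus
  an extra 2× on SSD derived copies (the planted derived/ancestral
  asymmetry).  A per-gene log2-normal spread (sd 0.5) makes NEV
  distributions broad and continuous, as in real data; it is symmetric,
  so group medians still recover log2 μ.
* **Gene ages.** Ancestral clade uniform on 1..10; derived clade =
  ancestral + uniform{1..5} capped at 15 (strictly younger except a
  configurable 5% tie fraction).  WGD copies draw clades independently
  and share the same variance distribution — a true null for the
  asymmetry analysis.  Singletons are uniform on 1..15.
* **Atlas.** One control plus 10 treatment samples (seedling, Col-0)
  and 11 tissue columns.  Treatment expression = baseline · 2^effect,
  effect ~ N(0, s_g) with s_g = 0.5 + 0.5·log2(multiplier) + noise,
  clipped at 0 — a positive noise–plasticity coupling whose strength
  is a free parameter; only its sign is asserted by tests.  Tissue
  values interpolate linearly between uniform (specificity 0) and
  single-tissue-at-floor (specificity 1).
* **TF flags** are assigned per pair (10% singleton, 5% SSD, 20% WGD —
  TF depletion among SSDs) with a rare (2%) mixed-pair fraction.
* **Ontology.** A random rooted tree (40 terms, depth ≤ 4); trees make
  the MICA unique and tests crisp.  Annotation: 3 leaves per gene;
  WGD copies share one term set, SSD copies draw from two *different*
  root-level subtrees — planting the functional divergence the
  similarity contrast detects.
* **Determinism.** All draws use numpy PCG64 streams seeded from
  (design seed, stage index); the RNG is recorded in the run log.

What passing these tests shows: the estimators recover effects of the
planted form at realistic sizes.  What they do not show: robustness to
library-size artifacts, batch structure, read-level noise,
non-NB dispersion, annotation bias, or real GO topology — none of
which the generator emulates.

## Statistical conventions

* *Rank tests.* Two-sided Mann–Whitney for group contrasts;
  Benjamini–Hochberg adjustment across the tested label pairs (Holm
  available).  Paired Wilcoxon signed-rank for derived-vs-ancestral
  NEV (two-sided) and for the synteny daughter-vs-parent clade check
  (one-sided, matching the directional claim; configurable).
* *Cliff's delta.* δ = (#{x>y} − #{x<y})/(nm), computed by sorted
  binary search (O((n+m)log)) and verified against the O(nm) oracle.
  The 95% CI uses Cliff's consistent variance estimator with the
  asymmetric (Fisher-z-style) interval; |δ| = 1 or zero variance gives
  a point interval.
* *Responsiveness.* The summed log2 ratio is signed in its literal
  form, but opposing responses cancel; the default sums |log2 ratio|
  (the quantity is a magnitude of plasticity) with `signed=True` for
  the literal convention.  Pseudocount 1 in numerator and denominator;
  contrasts with both values below the detection floor (1 unit) are
  skipped and counted.
* *τ.* Values below 1 are floored at 1 before log2, which keeps every
  term in [0, 1] (and hence τ ≤ 1) and makes a single-tissue gene give
  τ = 1 exactly.  Note the log form is *not* invariant to rescaling
  all tissues by a constant — τ should be computed on a fixed
  expression unit.
* *Top-divergence selection.* Within each duplication class, the
  floor(5%·n) pairs with largest |ΔNEV| (ties broken by pair id for
  determinism), then greedy deduplication in descending |ΔNEV| so no
  gene appears twice.
* *Age asymmetry.* Pairs with missing or zero ΔClade are excluded
  (equal strata carry no derived/ancestral signal).  Reported as (i)
  the paired test above and (ii) a Spearman correlation of ΔClade vs
  ΔNEV over both orientations of every pair, which is exactly
  invariant to the arbitrary A/B labelling; fewer than 10 usable pairs
  flags the result low-power rather than suppressing it.
* *Semantic similarity.* IC(t) = −log of the propagated annotation
  frequency, normalized by the maximum IC over annotated terms (so the
  rarest annotation has IC 1 and the root 0).  Jiang similarity
  1 − min(1, IC₁ + IC₂ − 2·IC(MICA)) on normalized IC; the 1/(1+d)
  form and a normalized Resnik measure (IC(MICA)) are available behind
  the same interface.  Terms with no annotations have undefined IC and
  are excluded.  MICA ties are broken by term id.
* *Enrichment.* One-sided hypergeometric upper tail per term with ≥ 10
  background genes, BH FDR across tested terms, results filtered at
  FDR 0.05 and sorted by fold enrichment (k/n)/(K/N).

## Problem sizes

The default study (2400 genes × 14 × 6) runs the full pipeline in
about a second; recovery tests use 2000–3500 genes, effect-size
coverage uses 100 replicates at n = 1000 per group, and enrichment
nulls use 100 replicate study sets.  These sizes put Monte-Carlo error
well below the tested tolerances while keeping the suite fast.

## Known limitations

* The NEV reference trend is estimated from the analyzed mixture
  itself; strong, asymmetric variance inflation in a majority of genes
  biases absolute (not relative) NEV.
* The Jiang similarity's exact algebraic form varies between
  implementations; both common normalized forms are exposed, and
  numeric values are comparable only within one convention.
* Parent/daughter orientation labels and clade assignments are taken
  as inputs; the package validates their consistency but does not
  infer them.
* The CI for Cliff's delta is asymptotic; at very small samples it is
  reported but approximate.
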