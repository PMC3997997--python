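# Methods

This note records the statistical model behind `mirnod`, the conventions and
numerical choices that were genuinely open, and what the synthetic-data
generator does and does not emulate.

## The NOD statistic

In the bipartite miRNA→gene network, a gene with exactly one regulator is an
*exclusive target*; NOD(m) is the number of exclusive targets of miRNA m.
Two structural facts are used as assertions throughout: exclusive-target
sets are pairwise disjoint across miRNAs, and Σ_m NOD(m) equals the number
of single-regulator genes in the database. NOD is always computed on the
full union database, never on the differential-expression subgraph: the
statistic is a property of the regulatory network, not of one experiment.

### Significance of an individual NOD

"Is this miRNA's NOD significantly above the population level?" is not a
well-posed signed-rank problem for a single observation, so the package
adopts an explicit interpretation: a one-sided Wilcoxon signed-rank test on
the paired differences d_j = NOD(focal) − NOD(j) over all other miRNAs j.
Under a ties-free population this reduces to a percentile-style location
test, it is deterministic, and it reproduces the qualitative pattern
expected of the statistic (large NOD against a low-NOD population → very
small P). Users should treat the resulting P as a calibrated ranking score
rather than a literal two-sample probability; it is the filter threshold
(default 0.05) that matters operationally.

Numerics: zero differences are dropped (Wilcoxon's convention; if all
differences are zero the test returns P = 0.5, no evidence either way).
With n ≤ 25 nonzero differences, the null distribution of W⁺ is computed
exactly by dynamic programming over doubled midranks (midranks are
half-integers, so doubling makes them exact integers; the DP is a
subset-sum convolution over 2ⁿ sign assignments without enumerating them).
Beyond n = 25 a normal approximation is used with the standard tie
correction Σ(t³−t)/48 subtracted from the variance and a 0.5 continuity
correction. The exact branch was verified against brute-force enumeration
of all sign assignments at n ≤ 12, and against `scipy.stats.wilcoxon`'s
exact method on tie-free data.

The reference population defaults to *all* miRNAs in the database;
`reference="candidates"` restricts it to the differentially expressed
candidates themselves (both are meaningful readings of "the median level";
the database-wide reading is the default because it does not change as the
candidate list changes).

## Differential expression

Classic pooled-variance (equal-variance) two-sample Student t-test,
two-sided, no multiple-testing correction by default — the selection rule
is deliberately a raw P < 0.05 plus a fold-change magnitude ≥ 2, mirroring
small-sample microarray practice; a Benjamini–Hochberg column is available
(`bh=True`) for users who want FDR control.

The t-test runs on **log2 intensities** by default. Microarray intensity
noise is multiplicative, so the log scale is where the additive-Gaussian
assumptions of the t-test actually hold; on the linear scale the test is
measurably conservative at n = 8 + 8. Matrices containing nonpositive
values automatically fall back to the linear scale with a warning
(`test_scale="linear"` forces it). Degenerate rows are reported, never
dropped: zero pooled variance with equal means gives (t = 0, P = 1), with
unequal means (t = ±∞, P = 0).

Fold change is computed on **linear-scale group means** with the signed
convention: up-regulation c/k (≥ 1), down-regulation −(k/c), so a halving
is −2 and the filter is |FC| ≥ 2 on both sides. log2 FC is log2(c/k); both
are flagged NaN when a group mean is nonpositive.

## ROC / AUC

AUC is the Mann–Whitney probability that a random case outscores a random
control, ties half-credited, computed by the rank-sum identity; the curve
itself is traced over every threshold and its trapezoidal area equals the
rank AUC to 1e-12 (asserted in tests). Because a down-regulated biomarker
discriminates with *low* intensities, each miRNA is oriented by its
fold-change sign before scoring (scores negated, `orientation="flipped"`),
so every reported AUC is a discriminatory accuracy ≥ chance in expectation.
Confidence intervals: Hanley–McNeil standard error by default (the classical
choice for single-marker microarray reports), truncated to [0, 1]; DeLong's
placement-value variance is available as `method="delong"`.

## Enrichment

Upper-tail hypergeometric P(X ≥ overlap) per gene set, with population =
universe, successes = set size, draws = |query ∩ universe|. The universe
defaults to the union of the collection's genes (annotated-universe
convention, the usual choice when the annotation source defines coverage)
and can be switched to the interaction database's gene space
(`universe="db"`). Query genes outside the universe are dropped from the
draw count and tallied in a warning. Raw P < 0.05 flags significance, and a
BH-adjusted column is always emitted. The query for candidate
characterization is the union of the candidates' exclusive targets — these
are disjoint by construction, so the query size is exactly the sum of the
candidates' NODs.

## Protein-interaction subnetworks

N0 = exclusive targets present in the PPI graph (isolated nodes count as
present); N1 = direct neighbors of N0, minus N0; N2 = N0 + N1. The exported
subnetwork contains only PPI edges with ≥ 1 endpoint in N0 (pure one-hop
star expansion) — edges internal to N1 are excluded by default because N1
membership is defined solely by adjacency to N0; `include_n1_edges=True`
relaxes this for visualization. Identifiers are matched verbatim between
the interaction database and the PPI; there is no mapping service, and a
symbol mismatch simply leaves a target outside N0.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a serum-miRNA biomarker study:

* **Network** — 641 miRNAs × 7706 genes at a mean of 51 targets per miRNA
  (≈ 32.7k pairs), background exclusivity 2% (population median NOD ≈ 1),
  with ten planted hub biomarkers whose exclusive-target counts are fixed
  at 53, 35, 33, 20, 15, 11, 11, 11, 10, 8 — 207 exclusively regulated
  genes in total. Every intended edge is routed through ≥ 1 validated
  source or ≥ 2 distinct predicted sources, so rebuilding the union under
  the consensus rule recovers the intended network *exactly*; decoy pairs
  carried by a single predictor (5% of edges) must be filtered out.
* **Expression** — 556 miRNAs × (8 case + 8 control). Row baselines are
  2^N(7, 2) (a plausible normalized-intensity scale), cell noise is
  multiplicative 2^N(0, 0.5) — i.e. ~1.4× typical within-group spread —
  and planted biomarkers have case means multiplied or divided by 4
  (two of the ten are down-regulated).
* **PPI** — Erdős–Rényi (or Barabási–Albert) over 75% of the gene
  namespace at mean degree 10, so some exclusive targets fall outside the
  PPI and N0 < NOD, as in real interactome coverage.
* **Gene sets** — random sets over the gene universe, one of which
  oversamples the planted biomarkers' exclusive targets at odds ratio 8
  (weighted sampling without replacement via exponential keys).

One root seed drives per-artifact child RNG streams, so a bundle is a
bit-reproducible function of its seed.

What it does **not** emulate: probe effects, batch effects, between-sample
normalization artifacts, correlated noise across miRNAs, realistic
scale-free regulatory topology, or sequence-based targeting. Consequently a
passing end-to-end recovery says the *pipeline logic* is sound under its
own assumptions — clean multiplicative noise and honestly planted effects —
not that the thresholds would achieve the same sensitivity on real arrays.
With a 4-fold planted effect against 0.5 log2-units of noise, single-miRNA
AUCs come out near 1.0, higher than typical published panels; the recovery
criterion (≥ 9 of 10 planted markers) is about ranking and filtering
correctness, not about emulating marginal detectability.

## Problem sizes used in validation

The automated checks run the oracle comparisons at small sizes chosen for
exhaustiveness rather than realism: exact signed-rank enumeration at
n ≤ 12, hypergeometric draw enumeration at universe ≤ 12, AUC pair
enumeration at 8 + 8, NOD recount on 50×300 random bipartite graphs, and
type-I calibration pooled over 200 null 556×16 matrices; the end-to-end
recovery runs at the full 641×7706 study scale (a few seconds).

## Known limitations

* The per-miRNA NOD significance is an interpretation (see above); other
  formalizations (e.g. a permutation percentile) would order candidates
  identically but print different P magnitudes.
* Hanley–McNeil CIs are known to be slightly anti-conservative for AUC near
  1 with n = 8 + 8; DeLong is offered but both degenerate at AUC = 1.
* The enrichment universe choice materially changes P values; neither
  option is "correct" without knowing the annotation provenance.
* No identifier normalization beyond case-folding: cross-source naming
  drift (aliases, star/arm renames) must be resolved upstream.
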