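# Methods

`gravitome` implements the analysis chain used for short-arm altered-gravity
transcriptome experiments on human immune cell lines: parabolic flights
(~20 s of 1.8 g hypergravity followed by ~20 s of microgravity per parabola)
and suborbital ballistic rockets (~75 s of up to 13.5 g, then ~300 s of
microgravity).  Each campaign lyses dedicated sample groups at the end of each
gravity phase, alongside hardware ground controls and, where available,
in-flight 1 g centrifuge controls and standard cell-culture controls.  The
pipeline consumes already-normalized (RMA-style) expression matrices; array
preprocessing is out of scope.

## Differential expression

For an ordered group pair (numerator, denominator) and each probe set:

* **Group means** are arithmetic means of the *linear* intensities
  (log2-recorded input is back-transformed as 2^x on ingest).
* **Fold change** is the ratio of the means if the ratio exceeds 1, the
  negative reciprocal of the ratio if below 1, and +1 exactly at equality.
  Fold changes therefore live on (−∞, −1] ∪ [+1, +∞); a halving reads −2.0.
  The convention is anti-symmetric: FC(a,b) = −FC(b,a) for a ≠ b.
* **Significance** is a per-probe-set two-group test on the *log2* values.
  The convention of testing on the log scale while reporting linear-mean fold
  changes is standard for RMA-processed arrays, where log2 intensities are
  approximately Gaussian and homoskedastic.  The default is the
  equal-variance (Student) t-test; `method="anova"` runs a one-way ANOVA,
  which for two groups is algebraically identical (F(1, ν) = t²) — the suite
  asserts agreement to 1e-10.  Both conventions appear in this experimental
  literature (t-test for one platform, ANOVA for the other); the identity
  makes the choice immaterial for pairwise contrasts.  Where an omnibus
  multi-group ANOVA might have been intended, we deliberately implement
  per-pair tests: every published quantity the pipeline reproduces is a
  pairwise contrast.  `method="welch"` relaxes the equal-variance assumption.
* A probe set is **called** differentially expressed when p < α (default
  0.05, raw) *and* the ratio is not exactly 1 (direction `up`/`down`, never
  `none`).  No multiple-testing correction is applied by default, matching
  the replication-oriented raw-p convention of the source experiments; a
  Benjamini–Hochberg flag (`adjust=True`) is available for exploratory use.
* Degenerate inputs: zero within-group variance in both groups yields p = 1
  when the group means are equal and p = 0 when they differ (the t statistic
  diverges); `scipy` returns NaN there and the pipeline post-processes it.

## Gravisensitivity sets

Per campaign, two contrasts drive the set logic (both are campaign *data*,
declared in the design, not hard-coded): the hypergravity control comparison
(baseline-hypergravity vs hardware ground control) and the microgravity
comparison (µg vs baseline-hypergravity).

* **Hypergravity-sensitive** = significant in the control comparison.
* **Microgravity-responsive** = significant in the µg comparison.
* Because the µg phase always follows a hypergravity phase, a probe set
  significant in *both* contrasts **in the same direction** may be carrying a
  delayed hypergravity effect; such probe sets are excluded to give the
  **controlled** microgravity-sensitive set.
* The significant intersection is partitioned into **double-same** and
  **double-opposite** by direction agreement.  A direction of `none` never
  matches any direction.

The additive identity |µg-responsive| = |controlled| + |double-same| and the
disjointness of the double partition hold by construction and are
property-tested on randomized fixtures.  Set operations are pure functions of
the direction/significance calls and invariant to probe-set order.

## Temporal classification

Pairing the same contrast at a short and a long exposure (hypergravity:
20 s vs 75 s; microgravity: 20 s vs 300 s), each probe set falls into exactly
one of four categories:

| short call | long call | category |
|---|---|---|
| not significant | not significant | `no_response` |
| significant | significant, same direction | `continuous` |
| significant | not significant, or opposite direction | `adaptation` |
| not significant | significant | `late_response` |

Shares are percentages of the paired universe, rounded **half-up to one
decimal** (`Decimal` arithmetic; this reproduces every published share
exactly).  An integer-rounded display field covers the one published value
printed as a whole percent (165/184 → 89.7% → "90%"); the rounding rule
itself is never changed.  Units can be probe sets (shared array family) or
genes (cross-platform, via the panel's gene→probe-set mapping); unmatched
units are reported, never silently dropped.

**Gene-level aggregation** is by unanimity: a gene is responsive in a dataset
only if at least one of its panel probe sets is significant and all
significant probe sets agree in sign.  The source experiments are silent on
multi-probe-set aggregation; unanimity is the conservative reading of a
"stably regulated" gene and cannot manufacture consensus from conflicting
probe sets.  Cross-platform consensus (`stable_up`/`stable_down`) requires
that unanimous response, with the same sign, in *every* contributing dataset.

## Panel probe-set selection

The gene panel (the published one holds 176 genes: the KEGG HIF-1 signaling
pathway plus literature-curated interactors; supplied as a TSV, not
reconstructed) is matched against platform annotation by **current** gene
symbol AND Entrez id, conjunctively: an Entrez disagreement vetoes a symbol
match.  Symbols compare case-insensitively after trimming; multi-gene
annotations ("NOS3; ATG9B") split on ";" and match on any component.  The
array vendor's original (array-era) annotation never influences inclusion —
probe sets whose array annotation moved are included iff the current
annotation validates them.  Panel genes with zero selected probe sets are
reported as missing (the published platforms cover 175 of 176 genes with
184 transcript clusters, and 176 genes with 375 probe sets, respectively).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, so
every stage is testable offline:

* **Noise model**: intensities are 2^(baseline + group effect + ε) with
  baselines uniform on [4, 12] log2 units and ε ~ N(0, σ), σ = 0.1 log2
  units by default.  Gaussian log2 noise is the standard assumption for
  RMA-processed arrays.  The σ default was fixed so that the weakest
  headline effect the pipeline must resolve (|FC| = 1.25 at n = 6) is
  detected with power > 0.9 — verified by simulation in the test suite, not
  asserted a priori.
* **Replicate counts** come from the built-in campaign designs (parabolic
  flights: 6/8/6/8 and 6/6/6/6; rockets: 6/5/7 and 7/7/9/7/9).
* **Planted truth** assigns each probe set a response archetype — null,
  continuous (up/down), adaptation, late — realized as log2 shifts on the
  relevant group of the short and/or long campaign.  For hypergravity
  planting the µg group inherits the baseline-hypergravity shift so the µg
  contrast stays null; for microgravity planting the shift sits on the µg
  group relative to baseline.  The default class mix is equal quarters
  (continuous split evenly up/down), chosen to exercise every classifier
  branch; with |log2 effect| = 1 and σ = 0.1 the expected recovery rate is
  ≈0.96 (null probe sets are recovered only when both null contrasts stay
  non-significant, ≈0.95² each), clearing the ≥95% recovery criterion
  without tuning.  The default simulation bundle plants the hypergravity
  condition; its microgravity time course is then dominated by
  `no_response`, mirroring the real campaigns' finding.
* **Panel annotation generator**: probe sets per gene follow a truncated
  geometric distribution (minimum 1), reproducing the observed
  multi-probe-set coverage (~2.1 probe sets/gene gives ≈375 rows for 176
  genes); a configurable fraction of rows receives an obsolete array-era
  annotation while the current annotation stays valid, so ground-truth
  selection is known exactly.
* **Densitometry generator**: per-lane total-protein OD uniform on
  [0.8, 1.2], band OD set so the normalized ratio is Normal(mean, σ),
  truncated at zero by redraw.
* All generators are pure functions of (configuration, seed).

**What a green synthetic test does not establish**: the generator has no
probe-level effects, batch/hybridization artifacts, correlated genes, or
heavy-tailed noise, and planted effects are homogeneous within a class.
Green tests establish that the *procedure* is implemented correctly and is
calibrated under its stated assumptions, not that the published biological
set cardinalities (which derive from the real deposited data, GEO GSE94256 /
GSE101309) are reproduced.

## Western-blot densitometry

Band optical density is divided by the lane's total-protein (Coomassie)
optical density — a ratio, not a subtraction, making the result invariant
under common rescaling.  Groups are compared by a two-tailed t-test on the
normalized ODs, Welch by default here (nothing constrains blot-group
variances; an equal-variance flag exists), with the contrast reported as
percent change of the group means.

## Validation targets

The published full-campaign set cardinalities derive from the real deposited
data and cannot be regenerated synthetically, so the recomputable targets are
worked examples whose *inputs* are printed: per-category counts fed through
the share computation (Jurkat hypergravity 43/21/49/71 of 184 →
23.4/11.4/26.6/38.6%; Jurkat microgravity adaptation/late 5.4/4.9%; U937
microgravity 319/1/20/35 of 375 → 85.1/0.3/5.3/9.3%) and the continuous-
response fold-change tables run through the classifier (21 Jurkat probe
sets).  One published count table (U937 hypergravity) is internally
inconsistent in print (its adaptation row reads "38 (36.8%)" where only 138
completes the partition and matches the percentage); it is packaged with the
reconstructed count, flagged, and excluded from validation.

## Known limitations

* The pipeline consumes normalized matrices only; RMA/quantile
  normalization, background correction and CEL/PAIR parsing are out of scope.
* Raw-p thresholding at α = 0.05 is a faithful reimplementation of the
  source convention, not a recommendation; expect ~5% false positives per
  contrast among null probe sets.
* The temporal classifier is categorical; it does not model adaptation
  kinetics.
* Gene-level unanimity aggregation is conservative: one discordant
  significant probe set silences a gene.
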