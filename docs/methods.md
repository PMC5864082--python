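# Methods

This note records the models, parameter choices and numerical decisions
behind `barfit`, in the order data flows through the package.

## Competitive growth model

A pooled competition of *n* barcoded deletion strains is described by
relative abundances *f_i* that evolve per generation as

    f_i ← f_i · 2^(1 + s_i) / Σ_j f_j · 2^(1 + s_j),

where *s_i* is the strain's fitness effect: the log2 offset of its growth
rate per generation (s = 0 neutral, s < 0 haplo-insufficient, s > 0
haplo-proficient). After *g* generations the log-ratio of two strains
changes by exactly g·(s_i − s_j), which is the closed form the simulator
uses and the tests check against.

Sampling stages mirror the chemostat design: pool (P), batch (B) after
g_B generations, then early/mid/late steady state. Defaults: g_B = 6
(≈24 h of batch growth at ~4 h doublings), B→ESS = 4 (the ~42 h settling
into steady state), MSS = ESS + 20 and LSS = ESS + 30 generations (steady
state held for 30 generations with samples at 20 and 30). Only P→B and
ESS→LSS are contrasted by default; MSS is emitted but unused.

Biological repeats (default 2) are made non-identical by a per-repeat
jitter s′ = s + N(0, 0.02) applied to the whole trajectory of that repeat.
The jitter magnitude sets the overdispersion the count model must absorb:
over g_B = 6 generations it contributes a log2-abundance spread of
6·0.02 ≈ 0.12 per repeat, i.e. an NB dispersion of roughly
(ln 2 · 0.12)² ≈ 0.007 at the batch stage.

Sequencing is two independent multinomial draws (UPTAG and DOWNTAG
libraries) of `depth` reads each over the *f_i*, with independent per-base
substitution errors at rate e < 0.1 (no indels — the identification rule is
Hamming-based — and constant quality strings, which the rule ignores).
Reads are `flank5 + TAG + flank3`, the flanks being the 3′ tails of the
amplification primers for each library; the 6-mer sample index travels in
the read header, mimicking demultiplex-ready data. The per-sample depth is
not dictated by the experiment being emulated (it was never reported);
defaults here are sized for statistical power at test scale, and the
calibration studies state their depths explicitly (10⁶–2×10⁶).

What the generator does *not* emulate: PCR amplification bias, index
hopping, indels, quality degradation along the read, strain-specific lag
phases, and chemostat dilution dynamics between samplings. Passing tests
therefore demonstrate correctness of the analysis under multinomial
sampling with substitution noise, not robustness to every artifact of real
Bar-Seq libraries.

## Barcode identification

A read is assigned to its sample by exact 6-mer index match only; a
one-mismatch rescue would risk cross-sample bleed and is deliberately
absent. The TAG is extracted as the fixed-length window after the unique
occurrence of the library flank (absent, duplicated, or truncated flanks →
`no_tag`), and compared against every catalog TAG of the same length: a
distance-0 match, or a unique distance-1 match, identifies the TAG; two or
more TAGs at the minimal distance ≤1 make the read ambiguous and it is
discarded with a tally. Counts for a strain are UPTAG hits + DOWNTAG hits.
The implementation (exact-hash fast path plus a vectorized per-length
Hamming scan) is contractually equal to a brute-force scan, which the
tests enforce with an independent enumeration of the full radius-1
Hamming ball. Per sample, `hits + ambiguous + unmatched + no_tag = reads`
always holds.

TAG length is not fixed: any length ≥15 nt is accepted and each TAG is
matched at its own length. Catalogs enforce global TAG uniqueness, so a
read cannot match both an UPTAG and a DOWNTAG of different strains at
distance 0.

## Fitness contrasts

Counts follow the standard NB mean–variance model Var(K) = μ + αμ².
Normalization uses median-of-ratios size factors: sf_j is the median over
strains (positive in every sample) of K_ij divided by the strain's
geometric mean. Dispersion is estimated per strain by method of moments on
normalized counts, pooling the within-group means and variances of the two
contrasted stages; a trend α(μ) = a0 + a1/μ is fit by least squares and
the final dispersion is max(clipped raw estimate, trend).

Two numerical choices matter here. First, the trend is fit on the
*unclipped* moment estimates: with two replicates per group roughly 40% of
raw estimates are negative and clip to zero, and fitting only the positive
ones inflates the trend by ~1.4×, which measurably depresses the type-I
rate of the downstream test (to ~0.025 at nominal 0.05); the unclipped fit
is approximately unbiased and restores nominal behaviour (measured
0.023–0.049 over eight seeds at the null-calibration conditions). Second,
the final max() deliberately trades a little conservatism for protection
against per-strain underestimation, exactly as count-model practice
recommends with few replicates.

The test statistic is a Wald z on
log2fc = log2((mean_B + c)/(mean_A + c)) with pseudocount c = 0.5 and a
delta-method SE from Var(q_ij) = μ/sf_j + αμ²; p is the two-sided normal
tail and BH-adjusted p is reported alongside. Strains with zero counts
everywhere in both groups are reported NS with p = 1. Calls use the raw p
(p < 0.05) plus a 1.5-fold filter: HP at log2fc ≥ log2 1.5, HI at ≤
−log2 1.5. The UpSet-style intersection tables optionally use the stricter
θ = 1.5 on the log2 scale; both thresholds are config options because the
two conventions coexist in practice. Replication enters at the biological
level only: the two TAGs of a strain are summed before testing, so each
group has the two biological repeats as replicates, and repeats are pooled
(not paired) across the contrast.

## Co-fitness analysis

Profiles are the log2 fold changes over the eight comparisons {B>P, L>E} ×
{C-lim, N-lim} × {30°, 36°}, in that canonical column order; the LiCl
conditions are excluded by default (a flag extends to 12 columns). Strains
missing any comparison are dropped with a count.

Selection fits, per strain, ordinary least squares of the profile on coded
covariates phase/nutrient/temperature ∈ {0,1} with intercept, and two-sided
p-values from the t distribution on the residual degrees of freedom (4 for
the 8-column design). The t reference — rather than a plain normal on the
4-df variance estimate — keeps the per-coefficient rate nominal, so the
per-strain family type-I is ≈ 1 − 0.95³ ≈ 0.14, matching the measured
retention of pure-noise strains (≤15%). A strain is retained when any
non-intercept coefficient has p ≤ 0.05.

Clustering is partitioning around medoids on Euclidean distances: greedy
BUILD, then exhaustive best-improvement SWAP until no cost-reducing swap
exists, with all ties broken toward the lowest strain index, so the result
is deterministic. The cluster count is chosen over k ∈ 2..10 by maximum
mean silhouette (ties to the smaller k), or pinned by the caller. SWAP is
a local search: on unstructured point sets a few percent of tiny instances
converge above the global best-medoid cost (the reference R implementation
behaves the same), so optimality is asserted on fixtures with actual
cluster structure — the geometry retained fitness profiles have.
Sub-clusters split by direction of fitness change: the sign of the
strain's mean profile value.

Enrichment tests each cluster for SUT and CUT content against the class's
background proportion among all clustered strains, with the exact binomial
two-sided tail-doubling p (capped at 1) and BH FDR across all
cluster×class rows.

## Colony screen

Each plate is divided by its median colony size, then one round of
multiplicative row/column median polish removes positional effects;
replicate colonies are averaged per strain (missing colonies ignored).
The distribution of normalized sizes is modelled as a two-component normal
mixture fit by EM: initialization splits at the 10th percentile (lower
tail = presumptive reduced class), convergence at a log-likelihood gain
below 1e-8 (capped at 1000 iterations, non-convergence flagged rather than
raised), σ clamped at 1e-3 to keep the likelihood bounded; the
log-likelihood trace is asserted non-decreasing. Strains are scored
against the component whose mean is closer to the wild-type reference
(designated control positions when present, else the global median):
p = 2(1 − Φ(|v − μ_wt|/σ_wt)), significant at p < 0.05, two-sided because
both unusually large and unusually small colonies are of interest; a
one-sided option exists. The score is calibrated — the fitted σ matches
the empirical spread of the normal class — so the false-positive rate among
truly normal strains sits at the nominal 5% rather than below it.

Growth curves are summarized by the trapezoidal area under the OD–time
curve. This replaces spline-based fitting deliberately: at plate-reader
sampling density (readings every 5 min) the trapezoid is within 0.5% of a
10⁴-point quadrature of the underlying logistic, and it has no smoothing
parameters to document.

## Pipeline and reproducibility

One YAML config drives the whole run. All randomness derives from a single
master seed through named substreams (stage × condition × repeat), so any
stage can be re-run in isolation and two runs with the same config produce
byte-identical artifact trees; every TSV artifact carries the config hash
in a header comment and the JSON report echoes the config and per-stage
counts, which reconcile with the artifacts by construction (and by test).

Problem sizes in the test suite and the acceptance script (hundreds to a
thousand strains, depths 10³–2×10⁶, four plates) are chosen so each
statistical check has the power its tolerance needs; they are package
defaults, not constraints of the method.

## Known limitations

* The NB test is a delta-method Wald test, not an exact conditional test;
  with two replicates its dispersion estimates are noisy and the max(raw,
  trend) rule leaves it mildly conservative in the tails.
* PAM optimality is a local-search guarantee only (see above).
* The simulator's read model omits amplification and indel artifacts, so
  matcher robustness is demonstrated for substitution noise only.
* The colony screen assumes a two-class size distribution; more than two
  fitness classes would need a larger mixture.
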