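# Methods

`smileig` analyses per-eye outcomes of small-incision lenticule extraction
(SMILE) across several surgical centers. Its core is an entropy-based
feature-weighting procedure: the 3-month postoperative spherical equivalent
(SE) is discretized into three accuracy classes, each of 20 candidate
features is scored by information gain against that class label, the gains
are normalized to sum-to-one weights per center, and features are kept only
if their weight clears a threshold in *every* center — first 0.05 over the
full candidate set, then 0.10 after re-ranking the surviving subset. A
synthetic cohort generator reproduces the marginal structure that multicenter
papers publish (median and quartiles per center, sex proportions, eye
counts, surgical parameter ranges) so the whole pipeline can be exercised
and validated without patient data.

## Outcome discretization

The 3-month SE residual `v` (diopters) maps to

| class | interval |
|---|---|
| 0 | −0.25 ≤ v ≤ 0.25 |
| 1 | −0.50 ≤ v < −0.25 or 0.25 < v ≤ 0.50 |
| 2 | v < −0.50 or v > 0.50 |

Class-0 boundaries are closed; the class-1 intervals are half-open on the
inner side. (Clinical write-ups sometimes print the outer class as
"<0.50 or >0.50"; taken literally that overlaps class 1, so the lower
branch is read as v < −0.50.)

Continuous features are binned equal-frequency with k = 4 by default;
quantile boundaries use linear interpolation and ties go to the lower bin,
so binning is deterministic and invariant to strictly monotone transforms.
Equal-frequency was chosen for robustness to the heavy skew of diopter
scales; k is configurable because no standard exists for this choice, and
reported weights do depend on it. Features with at most k distinct values
(e.g. corrected acuity recorded as 1.0/1.2) keep their own levels;
categorical features pass through as level codes.

## Information gain and weights

For outcome classes S and binned feature a, `IG(S,a) = H(S) − H(S|a)` with
Shannon entropy in bits (the base cancels after normalization; bits are
convention). `H(S|a)` is the group-size-weighted entropy of S within each
feature level. Gains are computed per feature on that feature's complete
cases (pairwise deletion, counts reported). Within a ranking, weights are
`w_i = IG_i / Σ_j IG_j`, so they sum to one and ordering by weight equals
ordering by raw gain; ties break alphabetically for reproducibility. If
every gain is zero (e.g. a constant outcome) the weights are reported as
zero with a warning rather than dividing by zero.

The two-stage multicenter selection intersects, across centers, the sets of
features with weight strictly above 0.05; the surviving subset is re-ranked
per center (the smaller denominator grows each weight) and the final set
keeps features above 0.10 in every center. Thresholds apply to normalized
weights because the per-center tables they are quoted against sum to ≈1.

`InformationGainRanker` wraps the same computation as a scikit-learn
transformer (`fit(X, y)`, `weights_`, `transform` keeps columns above the
threshold) so the ranking composes with sklearn pipelines; the module
functions remain the primary interface for the multicenter procedure.

## Synthetic cohort generator

Each center is a `CenterProfile`: eye count, male fraction, quantile
triples (median, P25, P75) for age, sphere (SD), cylinder (CD), SE, central
corneal thickness (CCT) and mean keratometry (Km), uniform ranges for
optical zone (6.2–7.0 mm), cap thickness (110–140 μm) and laser energy
(125–145 nJ), a keratometric spread, and an effect model for the outcome.
The shipped profiles transcribe a three-center design (818/702/830 eyes;
male fractions 0.510/0.634/0.683). One profile's age P25 is 9 years as
printed in its source table despite an adult-only design; it is transcribed
verbatim because fidelity is measured against the profile's own targets.

**Quantile matching.** Published summaries give only (median, P25, P75).
Draws come from a *median-glued two-piece normal*: each half is a
half-normal centred on the median with scale (median−P25)/0.6745 below and
(P75−median)/0.6745 above (0.6745 = Φ⁻¹(0.75)), glued at the median with
probability 1/2 per side. Its median and quartiles equal the targets
*exactly* for any monotone triple. The more familiar density-continuous
two-piece normal (pieces weighted σ_lo/(σ_lo+σ_up)) cannot do this: its
quartile-spread ratio is bounded near 1.34, far below the ratio of 3 seen
in a skewed age row, and its median drifts off target whenever the triple
is asymmetric. The price is a density jump at the median, irrelevant for
rank- and quantile-based downstream statistics.

**The refraction triple.** SE ≡ SD + CD/2 is enforced by construction: SD
and CD are sampled and SE derived. Independent draws would miss the SE
quartile targets by ~0.15 D, so the SD and CD draws are coupled: eyes fall
into six SD-quantile bands, band k adds a location shift a_k to a latent
standard normal, and the latent value is mapped back to a uniform through
the exact mixture CDF F(z) = Σ_k π_k Φ(z−a_k) before inverting the CD
quantile function. The CD marginal therefore stays exactly
quantile-matched, while the six shifts reshape the SE distribution; they
are calibrated once per profile by deterministic fixed-sample least squares
to the SE median and quartiles. Cylinder is clamped to ≤ 0
(negative-cylinder convention).

**Remaining construction** (per eye): K1 = Km − u, K2 = Km + u with
u ~ U(0, k_spread) (default 1.5 D); nomogram ~ U(0, 0.13·|SE| + 0.2) D;
attempted correction = |SE| + nomogram; maximum lenticule thickness
= round(attempted · OZ²/3) μm (a Munnerlyn-style heuristic used only in
generation, never in analysis); RST = CCT − cap − Max, with negative-RST
eyes resampled; uncorrected acuity is a logistic decline in |SE|
(1.05/(1+e^{0.8(|SE|−2.2)})) with lognormal noise, floored at 0.01 decimal
so the floor carries no appreciable point mass; corrected acuity is 1.0 or
1.2 decimal. Intraocular pressure and cylinder axis are plausible defaults
(N(15.5, 2.5²) mmHg clipped to [8, 30]; U(0°, 180°)) — no published
quantiles exist for them, so they are documented choices, not targets.
Feature correlations arise only through this construction chain; there is
no additional copula across blocks.

**Outcome model.** Postoperative SE = intercept + Σ β_f · z(f) + N(0, σ)
over z-standardized features. Defaults: σ = 0.18 D, intercept 0, and signed
coefficients (+0.06 SD, +0.06 SE, +0.02 UDVA, +0.04 RST, −0.02 K1,
−0.04 Km, −0.08 Max, −0.06 CCT, −0.03 nomogram) whose signs follow the
correlation directions reported for these nine features in multicenter
SMILE outcomes. The generator reproduces those *signs* robustly at
n = 5000; it makes no attempt to match reported correlation magnitudes or
information-gain values, which depend on unpublished patient-level data.
Postoperative corrected acuity changes by {−1, 0, +1, +2} lines with
probabilities {0.05, 0.45, 0.35, 0.15} — no eye ever loses two or more
lines — and uncorrected acuity degrades from it with the residual |SE|.

**Planted-effect validation designs.** Two stress tests plant known
signal: a single feature with a coefficient 3× the base, which must rank
first; and four such features, which must be exactly the final
0.10-in-all-centers selection. Two design choices make these experiments
well-posed:

* Base coefficients are restricted to a reference set of mutually
  weakly-dependent features (age, IOP, axis, UDVA, CCT, OZ, cap thickness,
  laser energy). Spreading base effects over near-duplicate groups instead
  (K1/K2/Km correlate at ≈0.95; SD/SE/UDVA/Max/nomogram form one chain;
  RST/CCT another) stacks their contributions until a duplicate group
  reaches ~2.9× base — indistinguishable from a 3× plant by any marginal
  statistic, for any method.
* The planted spec uses intercept −0.30 D (a mild systematic
  undercorrection). With the outcome centred exactly on target, the
  symmetric accuracy classes fold a linear predictor — bins at +x and −x
  produce identical class distributions — and the planted gain collapses
  into the finite-sample bias floor. This is a genuine property of
  class-based statistics around a symmetric target, worth knowing when
  interpreting real cohorts centred on plano.

## Refractive outcome metrics

Safety index = mean ± sample SD of per-eye postoperative/preoperative
corrected decimal acuity; efficacy index uses postoperative uncorrected
over preoperative corrected. Mean-of-ratios (not ratio-of-means) is used
because a "mean ± SD" form implies a per-eye quantity. Line changes are
(logMAR_pre − logMAR_post)/0.1, rounded, positive = gained. Accuracy within
±t D counts eyes with |SE residual| ≤ t against a plano target unless a
per-eye `target` column is supplied. The five standard panels are emitted
as tabulations (cumulative UDVA over Snellen bins ≥20/12.5 … ≥20/40, line
changes, attempted-vs-achieved pairs, SE accuracy histogram, cylinder
magnitude histogram); no figures are rendered. The per-eye schema carries
no postoperative cylinder, so the astigmatism panel tabulates preoperative
cylinder magnitude unless a `post_cd` column is present — a documented
limitation.

## Supporting statistics

Spearman rho is the Pearson correlation of mid-ranks (average ranks on
ties) with a two-sided t-approximation p-value (n − 2 df), standard at
cohort sizes in the thousands; an exact permutation p is available for
n ≤ 8. Kolmogorov–Smirnov normality screening tests against a normal with
the sample mean/SD and only decides median-vs-mean reporting. Quantiles use
linear interpolation (type-7); the convention behind published tables is
unknown, so it is simply fixed and documented.

## Determinism and problem sizes

All randomness flows from one seed through named substreams per center, so
a center's cohort does not depend on how many other centers are simulated.
Reports contain no wall-clock fields; identical config + seed gives
byte-identical CSVs and JSON. CSV writing rounds diopters to 2 decimals and
thicknesses to 0.1 μm, and recomputes SE and RST from the rounded
components so the written file satisfies the SE identity (0.01 D) and RST
identity (1 μm) at file precision.

The validation suite uses the sizes its checks are designed for: quantile
fidelity at 10,000 eyes/center against a 4·IQR/√n band, sign recovery at
5,000 eyes, planted-effect recovery at 2,000 eyes/center × 100 replicates,
and the exhaustive information-gain oracle sweep over all 4¹² small 3×4
contingency tables. End-to-end CLI checks run at a few hundred eyes per
center; the shipped profiles default to the full 818/702/830.

## What passing tests do and do not show

The generator emulates published *marginals*, plausible construction-chain
correlations, and an additive outcome model. Real refractive cohorts have
measurement rounding to 0.25 D steps, device-specific biases,
surgeon/nomogram feedback loops, bilateral correlation between a patient's
two eyes, and non-additive effects — none of which are modelled (bilateral
correlation is deliberately ignored; eyes are treated as independent).
Passing validation therefore shows the *pipeline* is correct and that the
selection procedure recovers known planted structure under realistic
marginals; it does not certify the clinical conclusions of any particular
cohort.
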