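# smileig

Entropy-based feature weighting for multicenter SMILE refractive-surgery
cohorts, with a quantile-matched synthetic cohort generator and the standard
refractive outcome analyses.

## The problem

After small-incision lenticule extraction (SMILE), the clinically relevant
outcome is the residual refraction — the spherical equivalent (SE) at three
months. Which of the many preoperative and surgical-design parameters
actually drive that residual is hard to settle with linear models, because
the candidate features (sphere, cylinder, keratometry, pachymetry, lenticule
geometry, nomogram adjustments) are strongly collinear. An alternative is to
discretize the outcome into accuracy classes and score each candidate
feature `a` by its information gain against the class label `S`:

    IG(S, a) = H(S) − H(S | a),      H(S) = −Σ_k p_k log2 p_k

where `H(S|a)` is the group-weighted entropy of `S` within the levels of a
binned `a`. Within one ranking the gains are normalized to weights summing
to one; a feature is retained only if its weight clears a threshold in
**every** center of a multicenter design (0.05 over the full 20-feature set,
then 0.10 after re-ranking the surviving subset). The package implements
this procedure end to end, together with:

* a per-eye data model and CSV cohort I/O with invariant checking
  (SE = SD + CD/2, K-ordering, residual-stromal-thickness identity);
* a synthetic multicenter generator whose marginals match published
  median (P25, P75) summaries exactly and whose outcome model has
  configurable signed effects — so the pipeline is testable without
  patient data;
* the standard refractive outcome metrics (safety and efficacy indices,
  CDVA line changes, accuracy within ±0.50/±1.00 D, and the five standard
  graph panels as tabulated data);
* supporting statistics (Spearman with tie handling, KS normality
  screening, median/IQR summaries);
* a CLI (`smile-ig simulate | analyze | report`) emitting deterministic
  CSV + JSON reports.

The ranking is also exposed as a scikit-learn compatible transformer,
`InformationGainRanker` (`fit(X, y)` → `weights_`, `transform` keeps
above-threshold columns), so it drops into sklearn pipelines.

## Worked example

Simulate the three shipped center profiles (818/702/830 eyes) and run the
full analysis:

```bash
printf 'seed: 7\n' > config.yaml
smile-ig simulate --config config.yaml --out cohorts
smile-ig analyze --config config.yaml \
    --cohort cohorts/cohort_A.csv --cohort cohorts/cohort_B.csv \
    --cohort cohorts/cohort_C.csv --out report
```

which prints:

```
Centers: A (n=818), B (n=702), C (n=830)
Primary common features (> 0.05 in all centers): max_lenticule, pre_sd, pre_se, pre_udva
Secondary selection (> 0.1 in all centers): max_lenticule, pre_sd, pre_se, pre_udva
Center A top weights: Pre-SE=0.2171, Pre-SD=0.2058, Max=0.1961, Pre-UDVA=0.1939, RST=0.0353
Center B top weights: Pre-SE=0.2422, Pre-UDVA=0.2160, Pre-SD=0.2137, Max=0.1944, RST=0.0235
Center C top weights: Pre-SD=0.2463, Max=0.2205, Pre-SE=0.2076, Pre-UDVA=0.1758, Nomogram=0.0323
Spearman Max: rho=-0.751 (Negative), p=0, n=2350
Spearman Pre-SD: rho=+0.743 (Positive), p=0, n=2350
Spearman Pre-SE: rho=+0.744 (Positive), p=0, n=2350
Spearman Pre-UDVA: rho=+0.727 (Positive), p=0, n=2350
Center A: safety 1.18+/-0.22, efficacy 1.10+/-0.24, within 0.50 D 88.1%, within 1.00 D 99.9%, UDVA 20/20+ 78.6%
Center B: safety 1.17+/-0.22, efficacy 1.09+/-0.24, within 0.50 D 88.7%, within 1.00 D 99.6%, UDVA 20/20+ 76.2%
Center C: safety 1.19+/-0.22, efficacy 1.11+/-0.24, within 0.50 D 88.2%, within 1.00 D 99.9%, UDVA 20/20+ 80.2%
```

Reading this: in every simulated center, each feature's weight is its share
of the summed information gain (each center's 20 weights sum to 1.000). The
refraction cluster (Pre-SE, Pre-SD, maximum lenticule thickness, Pre-UDVA)
carries essentially all of the class information under the default effect
model, clears the 0.05 cut in all three centers, and survives the secondary
0.10 cut after renormalization. The Spearman rows give the pooled rank
correlation of each selected feature with the 3-month SE (sign and
magnitude), and the per-center lines summarize safety (post/pre CDVA ratio),
efficacy (post UDVA / pre CDVA), and the share of eyes within ±0.50 D and
±1.00 D of target. `report/report.json` holds the same content
machine-readably, plus the five standard-graph panel tabulations;
`feature_weights.csv` and `correlations.csv` are flat tables. Reruns with
the same seed reproduce every output byte-for-byte.

The same ranking from Python:

```python
import numpy as np
from smileig import default_profiles, generate_center, rank_features

cohort = generate_center(default_profiles()[0], np.random.default_rng(7))
for fw in rank_features(cohort)[:5]:
    print(f"{fw.feature:14s} raw {fw.raw_ig:.4f} bits  weight {fw.weight:.4f}")
```

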