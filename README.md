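# wmdecode

Directed-connectivity graph features and decoding for trial-epoched
multichannel recordings, with a fully synthetic, ground-truthed cohort
generator so the entire pipeline is testable offline.

Pipeline stages:

1. **`wmdecode.cohort`** — synthetic multi-subject cohorts simulated from
   stable multivariate autoregressive (VAR) models. Each channel carries a
   damped-oscillator AR(2) core at its region's node frequency
   (MTL / PFC / OFC); known directed couplings are planted as off-diagonal
   VAR coefficients active only in chosen trial conditions, and reaction
   times are tied to the planted couplings. Cohorts are written as HDF5
   (+ JSON sidecar) or per-trial CSV.
2. **`wmdecode.connectivity`** — per-trial VAR fit (OLS, order selected by
   Schwarz's Bayesian criterion), spectral transfer matrix H(f),
   row-normalized squared transfer magnitudes (DTF²), and band-averaged
   connectivity matrices (theta 4–8, alpha 8–12, beta 12–30, low-gamma
   30–80, high-gamma 80–200 Hz; half-open band edges).
3. **`wmdecode.graph_metrics` / `wmdecode.features`** — proportional
   thresholding to a fixed edge density, nine node metrics (degree,
   in/out-degree, strength, in/out-strength, clustering coefficient,
   betweenness centrality, eigenvector centrality), averaged within each
   region into a fixed-order 27-value feature vector per trial.
4. **`wmdecode.decoding`** — repeated stratified 80/20 subsampling with
   train-fitted z-scoring, ReliefF feature selection, linear SVM,
   threshold scans, per-feature selection frequencies, label-permutation
   nulls, and fast/slow reaction-time labeling by pooled quartile split.
5. **`wmdecode.stats`** — binomial inversion for selection-frequency
   significance (exact-tail and a stricter compat convention),
   Kruskal–Wallis, Dunn–Šidák pairwise comparisons, Wilcoxon rank-sum and
   signed-rank tests.
6. **`wmdecode.pipeline` / CLI** — end-to-end orchestration with hashed
   manifests and selection-count heatmap reports.

## CLI

```sh
wmdecode simulate --seed 1 --out cohort.h5
wmdecode connect  --cohort cohort.h5 --bands theta,alpha --out conn.csv
wmdecode features --cohort cohort.h5 --bands theta --pth-scan 0.06:0.20:0.01 --out features.csv
wmdecode decode   --features features.csv --contrast spatial-vs-identity \
                  --band theta --pth-scan 0.06:0.20:0.01 --repeats 100 \
                  --n-selected 9 --permutations 1000 --seed 7 --out results/
wmdecode stats bands    --accuracies accs.csv
wmdecode stats features --counts counts.csv --n 100 --p 0.3333 --alpha 0.05
wmdecode run-all --seed 1 --out results/
wmdecode report  --results results/
```

`run-all` accepts a YAML config (`--config`) mirroring
`wmdecode.pipeline.PipelineConfig`: cohort spec, bands, threshold range,
contrasts, decoding settings, permutation counts, output directory, seed.

## Notes

- The permutation test reports two p-values: `p_value` is the empirical
  permutation p (calibrated; exact under label exchangeability) and
  `p_ranksum` is the rank-sum comparison of true-run accuracies against
  the null accuracies, kept for comparability with common practice but
  anti-conservative under the null (the true-run repeats share a single
  labeling).
- Two binomial-threshold conventions are exposed: `exact_tail` (literal
  inversion; 42 at n=100, p=1/3, α=0.05) and `paper_compat` (one count
  stricter; 43 at the same parameters).
- Bands above the data's Nyquist frequency are refused (or skipped with a
  warning in pipeline runs) rather than silently truncated; the default
  250 Hz synthetic sampling rate supports bands up to low-gamma, and the
  high-gamma band requires `sampling_rate >= 500`.
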