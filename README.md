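# waveconn

Wavelet-based functional brain-network construction, and a framework for
quantifying how the wavelet **method** (DWT vs MODWT), **filter family**
(Daubechies Extremal Phase `D`, Least Asymmetric `LA`, Coiflet `C`) and
**filter length** (2–24) change the resulting graph metrics, their
sensitivity to group differences, and classification accuracy.

Resting-state fMRI time series have slowly decaying positive
autocorrelation (long memory, Hurst exponent H > 0.5), which makes
broadband correlation a poor connectivity estimate.  The standard remedy
is the *wavelet correlation*: decompose each regional series with a
discrete wavelet transform, and correlate the coefficients scale by
scale.  At a repetition time TR the scale-j coefficients cover the
frequency band

    ( fs / 2^(j+1),  fs / 2^j ],    fs = 1/TR,

so at TR = 2 s scale 1 is 0.125–0.25 Hz and scale 2 — the band most
resting-state studies analyse — is 0.0625–0.125 Hz.  Each subject's
scale-j correlation matrix is thresholded to a fixed edge density
(30% by default, keeping the strongest edges) and summarised by eight
statistics: mean and variance of the correlations, clustering
coefficient, characteristic path length, global and local efficiency,
Louvain modularity Q (mean over 20 seeded restarts) and the number of
communities in a consensus partition.

Every choice in that chain is swept: DWT or MODWT pyramid, D/LA/C
filters at all admissible lengths (D 2–20, LA 8–20, C 6–24), scales
1–4.  The comparison battery then quantifies

- *method stability*: the per-subject sum of absolute changes of a
  metric across consecutive filter lengths, compared between MODWT and
  DWT by a paired t-test (df = n−1 subjects);
- *filter-type effects*: sign tests between same-length filters with
  Bonferroni correction;
- *length effects*: one-way repeated-measures ANOVA with length as the
  within-subject factor, F on df (k−1, (k−1)(n−1));
- *group sensitivity*: −log10 p surfaces of two-sample t-tests and a
  C4.5-style boosted decision-tree classifier (gain-ratio splits,
  pessimistic pruning, AdaBoost.M1 with 10 trials, stratified 6-fold
  cross-validation, patient = positive class).

Because clinical fMRI data cannot be redistributed, the package ships a
first-class synthetic cohort generator: two groups of subjects whose
regional signals are mixtures of global, module and idiosyncratic
fractional Gaussian noise factors (exact circulant-embedding synthesis),
with a block-structured target correlation matrix and a tunable group
connectivity effect, broadband or confined to one wavelet band.

## Worked example

```python
from waveconn import CohortSpec, CohortStudy, RunConfig

spec = CohortSpec(n_per_group=6, n_regions=30, seed=11)
cfg = RunConfig(methods=("MODWT", "DWT"),
                sweep=tuple(("D", L) for L in (2, 4, 8, 16)),
                scales=(2,), graph_metrics=False, seed=11)
results = CohortStudy.from_spec(spec, cfg).fit()
print(results.method_variation_tests("mean_corr"))
print(results.method_variance_tests())
```

prints

```
   scale family     metric         t  df         p
0      2      D  mean_corr -4.971967   5  0.004205

   scale          t  df         p
0      2  27.046995   5  0.000001
```

The first table pairs each subject's length-variation statistic under
MODWT against DWT: t = −4.97 (df = 5, p = 0.004) means estimates move
significantly *less* over filter lengths with the MODWT.  The second
pairs the per-subject variance of the correlation coefficients averaged
over lengths: t = +27.0 means DWT estimates are substantially noisier —
both reproducing, on synthetic long-memory data, the reasons MODWT is
the preferred method in practice.

The same stages are available from a shell:

```sh
waveconn simulate --out cohort/ --seed 1
waveconn connect --manifest cohort/manifest.tsv --subject ctrl001 \
    --family LA --length 8 --scale 2 --out cm.tsv
waveconn metrics --matrix cm.tsv --density 0.3
waveconn run-all --manifest cohort/manifest.tsv --out results/ --seed 1
```

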