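# t2texture

Objective, high-throughput texture metrics for T2-weighted brain MRI of
lower-grade (WHO grade 2/3) glioma. Given a NIfTI image and a co-registered
binary lesion mask (voxels of interest, VOI), the package computes two
first-order metrics that quantify what a radiologist reads qualitatively:

* **T2WI Shannon entropy** — lesion heterogeneity. The whole image is
  rescaled to 256 gray levels using its global minimum and maximum (on
  T2WI these are anchored by air/bone and cerebrospinal fluid), a histogram
  of the levels inside the VOI is formed, and

  $$S = -\sum_{i=0}^{255} p_i \log_2 p_i$$

  where $p_i$ is the frequency of level $i$. $S \in [0, 8]$ bits; visually
  homogeneous lesions score low, heterogeneous ones high.

* **Edge mean / Edge median** — lesion border sharpness. Each axial slice
  of the 256-level image is filtered with the 3×3 Prewitt kernels
  ($G_x$, $G_y$), giving the gradient magnitude
  $G = \sqrt{G_x^2 + G_y^2}$; the mean and median of $G$ over the
  one-voxel-thick rim of the VOI (mask minus its in-plane 8-connected
  erosion) score how crisply the lesion is marginated.

The package also ships the published 50-case cohort (per-case metrics,
blinded radiologist readings of heterogeneity and border definition, and
IDH1 mutation status) together with the validation statistics: classic
pooled-variance Student t-tests between reading classes, and empirical ROC
curves with midrank (Mann–Whitney) AUC, DeLong standard errors, normal 95%
CIs and a test against AUC = 0.5. A deterministic phantom generator
produces ellipsoidal synthetic lesions with tunable heterogeneity
(number of intra-lesion intensity components) and border sharpness
(Gaussian boundary blur) so the whole image pipeline can be exercised and
tested without clinical data.

Intended users: neuro-imaging researchers extracting simple, reproducible
radiomic features from segmented lesions, and anyone needing a compact
reference implementation of VOI entropy / rim gradient scoring.

## Worked example

```sh
python examples/cohort_reproduction.py
```

prints every published comparison recomputed from the packaged table:

```
analysis                 kind   estimate             95% CI         p
entropy~heterogeneity    ttest    0.4731       (0.14, 0.81)    0.0062
edge_mean~border         ttest   14.4810      (7.06, 21.90)   0.00028
edge_median~border       ttest   11.9862      (5.58, 18.40)   0.00046
entropy~idh              ttest    0.4159       (0.12, 0.71)    0.0065
edge_mean~idh            ttest    5.6348     (-2.79, 14.06)      0.18
edge_median~idh          ttest    3.2676     (-4.01, 10.55)      0.37
entropy~heterogeneity    roc      0.7245       (0.57, 0.88)    0.0057
edge_mean~border         roc      0.8101       (0.69, 0.93)   6.4e-07
edge_median~border       roc      0.8269       (0.71, 0.94)   4.4e-08
entropy~idh              roc      0.7224       (0.58, 0.87)    0.0025
```

Reading the rows: lesions the blinded radiologist called heterogeneous have
0.47 bits higher entropy on average than homogeneous ones; well-defined
borders score about 14.5 (mean) / 12.0 (median) gradient units higher than
vague ones, and both edge statistics discriminate the border reading well
(AUC 0.81 / 0.83). Entropy also separates IDH1-mutant from wild-type tumors
(difference 0.42 bits, AUC 0.72), while border sharpness does not (the two
`edge*~idh` t-tests stay above p = 0.05).

The other examples show the per-case image pipeline on a synthetic lesion
(`examples/per_case_metrics.py`) and the phantom dose-response — entropy
climbing with component count at about log2 k bits, edge statistics falling
monotonically with boundary blur (`examples/phantom_dose_response.py`).

The same functionality is available from a shell:

```sh
t2texture phantom --seed 7 --out-prefix /tmp/case
t2texture metrics --image /tmp/case_image.nii.gz --mask /tmp/case_mask.nii.gz --out /tmp/metrics.tsv
t2texture reproduce --out /tmp/report.json
```

## Layout

- `src/t2texture/` — library: `image_io`, `quantize`, `texture_entropy`,
  `prewitt_edge`, `stats`, `cohort`, `phantom`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, parameter and design notes
- `tests/` — pytest suite, including end-to-end acceptance checks
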