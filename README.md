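# l1kpeaks

Peak calling for LINCS L1000 bead-level data.

The L1000 assay measures ~1000 landmark genes in ~500 Luminex bead color
channels, so every color carries beads for **two** genes, mixed at a roughly
2:1 bead ratio. Recovering each gene's expression value therefore requires
deconvolving every color's bead-intensity distribution into two peaks, and
any error here (especially assigning the peaks to the wrong genes — a
*flip*) propagates into every downstream signature. `l1kpeaks` implements:

* **Density-gap outlier removal** — a Gaussian-kernel density estimate of a
  sample's bead intensities (rule-of-thumb bandwidth
  `h = 0.9·min(sd, IQR/1.34)·n^(−1/5)`, 512-point grid); grid regions with
  density below `dy_thr` (default 1e-4) are data-free gaps that partition
  the beads into clusters, and clusters smaller than `clustersize_thr`
  (default 3) beads are discarded as outliers.
* **The aggregate Gaussian mixture model (AGMM)** — for the m replicate
  samples of a color, the joint log-likelihood

  ```
  L(δ, μ, σ, λ) = Σᵢ Σⱼ log[ λ f(xᵢⱼ; μᵢ + δᵢ/2, σ) + (1−λ) f(xᵢⱼ; μᵢ − δᵢ/2, σ) ]
  ```

  with f the Gaussian density, a single within-peak SD σ and mixing
  proportion λ shared across samples, and per-sample peak midpoints μᵢ and
  separations δᵢ. The (μ, δ) reparametrization of the component means
  (μ₁ᵢ, μ₂ᵢ) = (μᵢ ± δᵢ/2) turns the peak-order constraint μ₁ᵢ ≥ μ₂ᵢ into
  the box constraint δᵢ ≥ 0, so the likelihood is maximized with L-BFGS-B
  and the higher-expressed gene can never swap sides between replicates.
* **Baselines** — per-sample 1-D two-cluster k-medians (the default LINCS
  route) and a per-sample naïve two-component shared-variance GMM fitted by
  EM.
* **A hierarchical simulator** — per color, peak separation ~ Gamma(4, 4)
  and peak midpoint ~ N(7, 1); 40 + 20 beads ~ N(peak, 0.2) per sample; a
  Poisson(2) number of uniform stray beads per color; everything derived
  reproducibly from one seed. `fit_hyperparams_from_peaks` re-derives the
  Gamma/Gaussian hyperparameters from any real peak table by method of
  moments.
* **Benchmark metrics** — pooled Pearson correlation between true and
  predicted peaks, true-prediction counts (|error| < 0.05), mean absolute
  error, per-color flip counts, and Williams's t-test for the difference of
  two dependent correlations sharing the truth variable (df = n − 3).

## Worked example

```python
from l1kpeaks import SimHyperParams, simulate_dataset, agmm_fit

ds = simulate_dataset(SimHyperParams(n_colors=5, n_samples=4, seed=42))
res = agmm_fit(ds.beads[0])     # joint fit of color "c0" across 4 samples
print(res.summary())
```

```
Aggregate Gaussian mixture fit — color c0
  samples fitted: 4
  log-likelihood: -137.0680   converged: True
  sigma  = 0.22790  (SE 0.01068)
  lambda = 0.66606  (SE 0.03053)
        sample    mu_high     mu_low    delta    n removed
            s0     7.6114     6.4845   1.1270   60       0
            s1     7.6009     6.5006   1.1002   60       0
            s2     7.6300     6.4942   1.1358   60       0
            s3     7.5423     6.4230   1.1193   62       0
```

The two fitted peaks of this color sit near 7.60 and 6.49 in every
replicate — the generating truth was 7.59 and 6.46 — with λ ≈ 0.67
matching the 2:1 bead ratio (the majority gene is the higher peak) and a
shared within-peak SD of 0.23. Standard errors come from the observed
information at the optimum. `res.peak_calls` yields one `PeakCall` per
sample for writing with `write_peaks`.

The same pipeline runs from the shell:

```
l1kpeaks simulate --out-beads beads.tsv --out-truth truth.tsv --seed 1
l1kpeaks deconv   --in beads.tsv --method agmm --out peaks.tsv
l1kpeaks evaluate --truth truth.tsv --peaks peaks.tsv --out metrics.json
l1kpeaks benchmark --seed 1 --out report.json --table report.tsv
```

Bead tables are long-format TSV/CSV with columns
`sample_id  color_id  intensity` (intensities already on the analysis
scale; the package never transforms them). Every output file gets a
`.config.json` sidecar so a run can be replayed exactly.

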