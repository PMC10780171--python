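# ramanabund

Non-invasive estimation of biomolecular abundance in single microbial cells
from confocal Raman microspectra. The package implements the full analysis
chain used to follow protein and nucleic-acid levels across the lag, log and
stationary phases of microbial growth (*E. coli*-style batch cultures sampled
at 0–24 h):

1. **Preprocessing** — Savitzky–Golay smoothing (window 7, order 3), airPLS
   baseline removal (adaptive iteratively reweighted penalized least squares,
   λ = 100, ≤ 15 iterations), min–max normalization, and per-spectrum SNR
   estimation (max corrected peak / silent-region noise SD around 1800 cm⁻¹)
   with KS normality testing of the SNR distributions.
2. **Target extraction** — a gradient-boosted decision-tree classifier
   (grid search over trees ∈ {50, 90, 150}, depth ∈ {3, 5, 7},
   η ∈ {0.1, 0.3}; 3-fold stratified CV on an 80/20 split) recognizes the
   culture time or growth phase of each cell from the preprocessed per-channel
   intensities. The total split gain per wavenumber channel ranks candidate
   characteristic peaks; near-duplicates are collapsed and channels without a
   protein / nucleic-acid assignment (e.g. the 810/940 cm⁻¹ carbohydrate
   bands) are dropped. PCA (95 % variance) + 2-D LDA embeddings with phase
   silhouettes and one-vs-rest ROC/AUC serve as diagnostics.
3. **Quantification** — peak *areas*, not heights. Isolated peaks use the
   total-peak-area rule

   A = Σᵢ₌L..R xᵢ − (x̄_L + x̄_R)(R − L + 1)/2,

   with the background ordinates x̄ averaged over n = 3 channels at each
   boundary. Mixed/shoulder peaks (e.g. the 1096.8 cm⁻¹ band with its
   1102.2 cm⁻¹ shoulder) are deconvolved by bounded two-stage least-squares
   fitting of area-parameterized Gaussians

   f(x) = Σᵢ Aᵢ/(σᵢ√(π/2)) · exp(−2(x−μᵢ)²/σᵢ²),

   where each component integrates exactly to Aᵢ and σ is twice the Gaussian
   SD (FWHM = σ√(2 ln 2)).
4. **Abundance statistics** — per-peak one-way ANOVA across the three growth
   phases with significance stars (\* p<0.05, \*\* p<0.01, \*\*\* p<0.001)
   and row-normalized phase-mean heat-map matrices.

Because no public single-cell Raman growth series is available, the package
ships a first-class synthetic-spectrum generator (`ramanabund.synthetic`)
that emulates the assumed data structure — fluorescence baseline, narrow
biomolecular bands with growth-phase kinetics, per-cell SNR targets in
[3, 7], three replicate acquisitions per cell — and emits ground truth for
every stage, so every pipeline step is testable against known answers.

## Worked example

A scaled-down end-to-end run (11 culture times × 8 cells; the full study
design uses 40 cells per time):

```python
import numpy as np
import ramanabund as ra

design = ra.GeneratorDesign(cells_per_time=8)
sset, truth = ra.generate_dataset(design, seed=42)
cells = ra.average_replicates(sset, "cell_id")
cfg = ra.PipelineConfig(seed=42)
proc, snr = ra.preprocess_set(cells, cfg)
print(f"{len(sset)} replicate spectra -> {len(proc)} cell spectra; "
      f"median estimated SNR {np.median(snr.values):.1f}")

model, report = ra.train_growth_classifier(proc, "phase", seed=42, config=cfg)
print(f"phase test accuracy {report.accuracy:.3f}; "
      f"min one-vs-rest AUC {min(report.auc.values()):.3f}")

_, sil = ra.embed_pca_lda(proc)
print(f"PCA+LDA phase silhouette {sil:.2f}")

ranking = ra.rank_gain(model, proc.wavenumbers)
print(ra.ranking_frame(ranking, top_k=30).head(5).to_string(index=False))

peaks = [(w, c) for w, c in ra.DEFAULT_ASSIGNMENTS.items() if c != "excluded"]
stats = ra.anova_by_phase(ra.quantify(proc, peaks[:4], config=cfg))
print(stats.table[["peak", "mean_lag", "mean_log", "mean_stationary", "stars"]]
      .round(2).to_string(index=False))
```

prints

```
264 replicate spectra -> 88 cell spectra; median estimated SNR 6.9
phase test accuracy 0.944; min one-vs-rest AUC 0.861
PCA+LDA phase silhouette 0.85
 rank  wavenumber_cm1       gain assignment  kept drop_reason
    1          1482.0 127.440453            False  unassigned
    2          1484.0  91.684479            False  unassigned
    3           854.0  76.989601            False  unassigned
    4          1124.0  70.214798            False  unassigned
    5          1122.0  50.729465            False  unassigned
peak  mean_lag  mean_log  mean_stationary stars
 726      3.05      7.22             4.12    **
 782      1.94      3.20             1.47   ***
1096      2.76      5.87             2.05   ***
```

(786 cm⁻¹, not shown, is `ns` at this reduced cell count.) The classifier's
top-gain channels sit on the strongly induced marker bands near 1483, 853 and
1124 cm⁻¹; the nucleic-acid peaks at 726/782/1096 cm⁻¹ peak in the log phase,
as nucleic-acid replication concentrates there, while protein peaks rise
monotonically into stationary phase.

## Command line

```
ramanabund simulate  --seed 42 --out data/
ramanabund preprocess --in data/matrix.csv --labels data/labels.csv --out data/matrix.proc.csv
ramanabund extract   --in data/matrix.proc.csv --labels data/cells.csv --label-mode phase --out ranking.csv
ramanabund fit       --in data/matrix.proc.csv --peaks 726,1096 --out fits.json
ramanabund abundance --fits fits.json --labels data/cells.csv --out abundance.tsv --stats stats.tsv --heatmap heatmap.tsv
ramanabund run       --simulate --out artifacts/      # whole chain + report.json
```

All stage parameters (JSON config + flag overrides) default to the processing
values listed above; every artifact embeds a hash of the fully resolved
configuration.

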