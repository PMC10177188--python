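# cpoct

Quantitative attenuation-coefficient analysis for cross-polarization optical
coherence tomography (CP OCT) volumes, aimed at intraoperative assessment of
breast-cancer resection margins.

CP OCT records backscattered light in the incident (co-) and orthogonal
(cross-) polarization channels simultaneously.  Tissue types differ in how
fast the signal decays with depth, so the attenuation coefficient µ (mm⁻¹) is
a tissue-specific optical biomarker: adipose tissue and dense tumor-cell
clusters attenuate weakly in the cross channel, while fibrous connective
tissue and hyalinized tumor stroma attenuate strongly.  This package
implements, end to end:

* **Depth-resolved µ estimation** per voxel,
  `µ_est[i] = M[i] / (2Δ Σ_{j>i} M[j])`, with additive-noise compensation
  `µ_est = H·µ_att + N_µ` inverted by SNR weighting
  `µ_att = H·SNRµ / (H²·SNRµ + 1) · µ_est`, after local 3×3×3 averaging of
  the measured signal (see `docs/methods.md` for the full chain, including
  the µ-domain SNR definition and the discrete-sum de-bias).
* **En face mapping**: per-A-scan averaging of valid µ_att voxels over a
  fixed window 105–630 µm below the automatically detected tissue surface,
  rendered on a fixed 0–7 mm⁻¹ blue→cyan→yellow→red scale, with offset-grid
  stitching of neighbouring scans.
* **ROI statistics** for five breast-tissue classes — adipose (AT),
  non-tumorous fibrous connective tissue (NCT), hyalinized tumor stroma
  (HTS), low-/high-density tumor cells (LDTC/HDTC) — as Me [Q1; Q3] of
  300 × 300 µm window medians, with pairwise Mann–Whitney U tests under
  Bonferroni correction.
* **ROC diagnostics**: AUC, Youden-optimal cutoff Pth, sensitivity,
  specificity and accuracy with 95% CIs for the three standard class-pair
  comparisons (pooled tumor cells vs AT, pooled tumor cells vs NCT, HTS vs
  NCT) in both channels.
* A **calibrated phantom generator**: two-channel volumes with class-specific
  exponential decay, fully developed speckle, an additive noise floor, and
  between-sample µ variability drawn from truncated normals matched to the
  published class medians and quartiles — so the entire pipeline is testable
  without instrument data.

## Worked example

Recover the five class medians through the full volume pipeline on the
default (2, 800, 128, 128) phantom (~25 s on one CPU):

```python
from cpoct import (PhantomSpec, synthesize_volume, default_fixture_rois,
                   detect_surface, estimate_noise_floor, attenuation_volume)
from cpoct.enface import enface_maps
from cpoct.roistats import extract_roi_medians, class_stats_table

spec = PhantomSpec(heterogeneity="uniform", seed=42)
vol, truth, _ = synthesize_volume(spec)
surf = detect_surface(vol)
att = attenuation_volume(vol, noise=estimate_noise_floor(vol, surface=surf),
                         surface=surf)
medians = extract_roi_medians(enface_maps(att), default_fixture_rois(spec))
print(class_stats_table(medians).to_string(index=False))
```

```
class channel  n  median    q1    q3  mean
   AT      co 33   3.958 3.951 3.967 3.958
   AT   cross 33   0.902 0.902 0.903 0.903
  NCT      co 36   5.388 5.360 5.435 5.395
  NCT   cross 36   3.756 3.751 3.760 3.756
  HTS      co 27   5.147 5.134 5.156 5.144
  HTS   cross 27   4.751 4.745 4.759 4.752
 LDTC      co 34   5.053 5.048 5.062 5.052
 LDTC   cross 34   2.220 2.219 2.223 2.220
 HDTC      co 35   4.395 4.354 4.425 4.391
 HDTC   cross 35   1.005 1.004 1.006 1.005
```

Every estimated class median lands within ~2% of the µ value the phantom was
built with (e.g. NCT co 5.388 vs 5.3 ground truth, HDTC cross 1.005 vs 1.0):
the noise-compensated estimator, surface detection, depth-window averaging
and ROI extraction together introduce only percent-level bias.  The same
pipeline is available from the shell:

```bash
cpoct all --seed 42 --out runs/demo          # simulate → estimate → map → stats → roc
cpoct estimate --out runs/real               # enter with your own volume in runs/real/volume/
```

`cpoct all` writes the volume (per-channel multi-page TIFF + JSON geometry
sidecar), en face CSV/PNG maps, class statistics, pairwise p-values, six ROC
results and a `summary.json` with the six AUCs and ten class medians; the
configuration YAML and seed are archived next to the outputs, and identical
seeds reproduce every file bit for bit.

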