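# vasconn

Quantifying how much of resting-state fMRI "functional connectivity" is
carried by the macrovasculature — large cerebral arteries and veins — rather
than by neural activity.

Systemic low-frequency oscillations (sLFOs) are non-neuronal BOLD
fluctuations in the 0.01–0.1 Hz band that travel with the blood. Because
they are strong inside and around large vessels, seed-based connectivity
analyses can report high "connectivity" at and near the macrovasculature.
`vasconn` implements the full analysis needed to measure that contribution:

* **Vessel-mask engineering** — fuse multi-orientation TOF segmentations
  (sum-and-binarize), downsample to the fMRI grid, split artery/vein by a
  label map, restrict to gray matter, and build perivascular shells at voxel
  distances 1..K by morphological dilate-and-subtract.
* **Minimal preprocessing** — WM/CSF mean-signal regression, 0.01–0.1 Hz
  ideal bandpass, 6 mm FWHM Gaussian smoothing, in that order.
* **Connectivity metrics** — for the four vascular seed/target categories
  (venous–venous, arterial–arterial, arterial–venous, venous–arterial) and
  gray-matter references, per-seed:
  - degree `D` = #{targets with correlation above 0.15 (|r| by default)},
  - strength `S` = spatial mean of correlations, split by sign (`S±`),
  - variance `σ²` = spatial (population) variance of correlations, split by
    sign,
  and the macrovascular-to-GM ratio maps `D_V,V : D_V,GM`,
  `D_A,A : D_A,GM`, etc., with `σ²` counterparts.
* **Perivascular profiles** — the same ratio metrics with perivascular
  shells as seeds, resolved by distance d = 0..3 voxels from the vessel.
* **RSN occupancy** — percentage of each resting-state network (z > 3)
  occupied by macrovasculature (frequency map ≥ its 90th percentile).
* **Synthetic phantoms** — seeded, ground-truthed 4D volumes carrying a
  band-limited sLFO with opposite sign in arteries (−) and veins (+),
  distance-decaying extravascular coupling `c(d) = c₀·exp(−d/λ)`, a lagged
  global GM background, tissue noise, and measurement noise, so the whole
  pipeline is testable without any data download.

## Worked example

```python
from vasconn import PhantomSpec, make_phantom, category_metrics, ratio_maps
from vasconn.preprocess import preprocess_bold

ph = make_phantom(PhantomSpec(rng_seed=0))          # 24x24x16, TR 2.2 s, 200 vols
clean, _ = preprocess_bold(ph.bold, ph.wm, ph.csf)  # regress -> bandpass -> smooth

cats = category_metrics(clean, ph.labels.artery_mask(),
                        ph.labels.vein_mask(), ph.gm, threshold=0.15)
for name in ("VV", "AA", "AV", "VA"):
    m = cats[name]
    print(f"{name}: mu(D)={m.spatial_mean('D'):6.2f}  "
          f"S={m.spatial_mean('S_all'):+.3f}")

rm = ratio_maps(cats["VV"], cats["V_GM"])
print(f"mu(D_VV:D_V,GM) = {rm.spatial_mean('D_ratio'):.4f}")
```

prints

```
VV: mu(D)= 17.00  S=+0.632
AA: mu(D)= 11.44  S=+0.237
AV: mu(D)= 15.39  S=-0.273
VA: mu(D)= 15.39  S=-0.273
mu(D_VV:D_V,GM) = 0.0083
```

Read: every vein voxel is suprathreshold-correlated with all 17 other vein
voxels (strength +0.63); artery–vein pairs are *anti*-correlated
(S = −0.27) because arteries carry the sLFO with opposite sign — exactly the
planted structure. Arterial–arterial connectivity is weaker (the arterial
gain is half the venous one), and the transposed categories AV/VA agree
exactly as they must. The ratio line says vein-to-vein suprathreshold
connections amount to ~0.8% of each vein voxel's whole-GM degree in this
small phantom (17 vein voxels vs ~4000 GM voxels).

The same stages run from the shell:

```bash
vasconn run --out results/run0 --seed 0         # full phantom pipeline
vasconn phantom --preset msc-like --out data/   # study-scale phantom
vasconn masks shells vessels.nii --K 3 --out-prefix shells/peri
vasconn occupancy --rsn-dir rsns/ --freq freq.nii --out occupancy.tsv
```

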