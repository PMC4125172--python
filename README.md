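# ggnquant

Quantitative CT analysis of pulmonary ground-glass opacity nodules (GGNs).

Persistent GGNs resected at surgery span three pathologic classes —
adenocarcinoma in situ (AIS), minimally invasive adenocarcinoma (MIA, ≤ 5 mm
invasive component) and frankly invasive adenocarcinoma — yet all three can
look like the same hazy nodule on CT. Telling them apart before resection
matters because AIS/MIA have essentially 100% disease-free survival with
limited resection. `ggnquant` implements the first-order radiomics approach
to this problem for radiology/imaging researchers: it extracts the full
histogram/texture feature vector from a segmented nodule, runs the
classical selection-and-classification chain, and ships a synthetic phantom
generator so the whole pipeline is testable end to end without patient
data.

## What it computes

From the HU multiset `x` of the masked voxels (histogram frequencies `p_i`
over 1-HU bins):

- percentiles `P2.5, P25, P50, P75, P97.5` (linear interpolation),
- skewness and (non-excess) kurtosis,
- entropy `H = −Σ p_i log₂ p_i` (bits) and uniformity `U = Σ p_i²`
  — higher `H` / lower `U` mean a more heterogeneous lesion,
- volume `V` (voxel counting, cm³), density `ρ = (mean HU + 1000)/1000`,
  mass `m = ρ·V`,
- nodule size as the largest in-plane Feret diameter (lung window) and the
  same for the ≥ −160 HU solid component (mediastinal window).

The statistics stage reproduces the published chain: one-way ANOVA with
Bonferroni family correction and post hoc tests, Spearman correlation with
invasion extent, two-observer ICC(2,1) with F-based CI, VIF screening
(iteratively dropping VIF > 10), backward-stepwise logistic regression for
invasive vs AIS/MIA (entry: ANOVA P < 0.10; removal: likelihood-ratio
P > 0.10), ROC with stratified-bootstrap CI, and the fixed decision rule

```
predict invasive  ⇔  P75 ≥ −470 HU  AND  H ≥ 7.90 bits
```

See `docs/methods.md` for definitions, conventions, and what the phantom
generator does and does not emulate.

## Worked example

```python
from ggnquant.phantom import PhantomSpec, generate_nodule
from ggnquant.features import extract_features
from ggnquant.stats import ThresholdRule, apply_rule

spec = PhantomSpec(class_label="INV", diameter_mm=18.0, ggo_mean_hu=-640.0,
                   ggo_sd_hu=90.0, right_tail_weight=0.2, solid_focus_mm=3.0,
                   invasion_extent_mm=9.8, seed=42)
volume, mask, record = generate_nodule(spec)
f = extract_features(volume, mask)
print(f"size (lung/mediastinal): {f.size_lung_mm:.1f} / {f.size_mediastinal_mm:.1f} mm")
print(f"volume {f.volume_cm3:.2f} cm3, density {f.density:.2f}, mass {f.mass_g:.2f} g")
print(f"p75 {f.p75_hu:.0f} HU, p97.5 {f.p97_5_hu:.0f} HU")
print(f"entropy {f.entropy_bits:.2f} bits, uniformity {f.uniformity:.4f}")
print("rule positive:", apply_rule(f.as_dict(), ThresholdRule()))
```

prints

```
size (lung/mediastinal): 18.7 / 3.5 mm
volume 3.07 cm3, density 0.41, mass 1.27 g
p75 -510 HU, p97.5 -255 HU
entropy 8.98 bits, uniformity 0.0024
rule positive: False
```

An 18-mm invasive-class phantom with a 3-mm solid focus: the mediastinal
size recovers the embedded focus (3.5 ≈ 3 mm + one pixel), the entropy of
8.98 bits reflects the heterogeneous voxel mixture, and the two-threshold
rule stays negative because the 75th percentile (−510 HU) misses the
−470 HU cutoff even though entropy clears 7.90.

The same flow from the shell, over a whole cohort:

```bash
ggnquant generate --out cohort/ --seed 7        # NIfTI volumes + masks + cohort.csv
ggnquant extract  --volumes cohort/ --out features.csv
ggnquant run      --out report/ --seed 7        # all-in-one, writes the report bundle
ggnquant report   --report-dir report/          # human-readable summary
```

`report/` then contains the feature table, ANOVA/Spearman/ICC tables, the
logistic model with its full selection trace, ROC points, the rule
evaluation and a manifest; identical config + seed reproduce the bundle
byte for byte.

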