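# strictureqmri

Quantitative MRI analysis of bowel-wall strictures in Crohn's disease.

Strictures (luminal narrowings) are a common complication of Crohn's
disease, and the treatment decision hinges on their composition:
predominantly *inflammatory* strictures may still respond to
anti-inflammatory therapy, while *noninflammatory* (chronic, fibrotic or
muscularised) strictures are candidates for surgery or dilatation.  Two
quantitative MR measurements probe this difference non-invasively:

- **T2\* relaxometry** — a multi-echo gradient-echo acquisition is fitted
  voxel-wise with the monoexponential decay `S(TE) = S0 · exp(−TE/T2*)`.
  Oedema in inflamed tissue lengthens T2\*.
- **IVIM diffusion** (intravoxel incoherent motion) — a multi-b-value
  diffusion acquisition is fitted voxel-wise with the biexponential model
  `S(b) = S0 · [f · exp(−b·D*) + (1−f) · exp(−b·D)]`, separating the tissue
  diffusion coefficient `D` from the capillary pseudodiffusion coefficient
  `D*` with perfusion signal fraction `f`.  Cellular inflammatory
  infiltrate lowers `D`.

The package implements the complete analysis pipeline for stricture
sections: a digital phantom with known ground truth (annular bowel wall
around a gas lumen, 16-echo and 18-b-value protocols, Rician noise,
per-frame motion, short-T2\* gas-transition rim), voxel-wise T2\* and
segmented IVIM fitting, artifact-aware per-section median/IQR aggregation,
and the statistical layer: Mann–Whitney U comparison of inflammatory
vs noninflammatory sections at a Bonferroni-adjusted α = 0.01, ROC curves
with Youden-index cutoffs, χ² and χ²-for-trend tests, quadratically
weighted Cohen's κ and ICC(2,1) observer agreement.

## Worked example

Simulate a two-section acquisition (one inflammatory, one chronic section
at the bowel-wall group medians), fit both parameter maps and aggregate
per-section medians, excluding the gas-transition rim from the T2\* ROI:

```python
from strictureqmri import (PhantomSpec, ROISet, aggregate_section,
                           fit_ivim_map, fit_t2star_map, make_phantom)

spec = PhantomSpec(snr=50.0, gas_rim_fraction=0.3, seed=42)
echo, dwi, truth = make_phantom(spec)

t2_map, s0_map, _ = fit_t2star_map(echo, truth.wall_mask & ~truth.artifact_mask)
ivim_maps, _ = fit_ivim_map(dwi, truth.wall_mask)

for sid, phenotype, params in spec.sections:
    sect = truth.section_id_map == sid
    roi = ROISet(truth.wall_mask & sect, truth.artifact_mask & sect)
    t2 = aggregate_section(t2_map, roi, sid)
    d = aggregate_section(ivim_maps["d"], ROISet(truth.wall_mask & sect), sid)
    print(f"section {sid} ({phenotype}): "
          f"T2* = {t2['median']:.1f} ms (true {params.t2star}), "
          f"D = {d['median']:.5f} mm^2/s (true {params.d}), "
          f"{t2['n_voxels']} voxels, {t2['volume_mm3']:.0f} mm^3")
```

which prints

```
section 1 (inflammatory): T2* = 25.6 ms (true 25.4), D = 0.00120 mm^2/s (true 0.0012), 114 voxels, 1049 mm^3
section 2 (chronic): T2* = 18.6 ms (true 18.6), D = 0.00139 mm^2/s (true 0.0014), 108 voxels, 994 mm^3
```

At SNR 50 the per-section medians recover the true tissue values to within
a percent or two; the gas rim (deliberately simulated with T2\* = 3 ms) is
subtracted from the T2\* region of interest, as it would be in a reading
session.

The same stages are available from the shell: `strictureqmri simulate`,
`fit-t2star`, `fit-ivim`, `aggregate`, `compare`, `agreement`, and
`strictureqmri run`, which executes the whole simulate → align → fit →
aggregate → compare pipeline from a YAML config and writes per-section
CSV tables, a JSON statistical report and a run manifest.

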