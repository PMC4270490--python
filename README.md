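# myonuc

Quantification of **myonuclear positioning**, **motor/adaptor protein
localization**, **nuclear translocation dynamics**, and **muscle function**
from multi-channel fluorescence images of *Drosophila* body-wall muscles —
together with a ground-truth synthetic data generator so that every stage of
the pipeline can be validated without raw microscopy.

## Who this is for

Muscle cell biologists measuring where myonuclei sit inside elongated,
syncytial muscle fibers and how motor proteins (Kinesin, Dynein) and their
adaptors distribute between the muscle ends and the nuclei. The package
implements the measurement conventions used in quantitative studies of
cortical-pulling-driven nuclear positioning in *Drosophila* embryonic LT
muscles and larval VL muscles, as reusable, tested code.

## What it computes

**Positioning metrics** (all normalized to muscle length *L*):

- *end-to-nucleus distance*: `min over nuclei of d(end contour, nucleus outline) / L`
  for the dorsal and ventral fiber ends — the readout of cortical pulling;
- *nearest-neighbor distance*: per nucleus, `min centroid-centroid distance / L`
  (clumping); *longest gap*: largest nucleus-free axial stretch `/ L`;
- nucleus count and muscle length (axial mask extent, µm).

**Localization profiles**: within a box of set width spanning the shortest
end-to-nearest-nucleus segment, the per-position ratio

```
r(x) = mean_width(target) / mean_width(reference) x 100
```

is resampled onto a normalized axis (0% = muscle end, 100% = nucleus,
101 points). The curve maximum is the **peak intensity** and the integral
over [0, 100] the **total fluorescence (AUC)**. Variants: a
fixed-size box anchored at the nucleus (raw-position profile) and the
distal-2 µm target/reference ratio. The reference channel (Tropomyosin-like
structural stain) is validated as an internal control by comparing its own
totals across genotypes.

**Nuclear dynamics** from 20–60 min tracks: aspect-ratio extremes of the
outline's inertia-equivalent ellipse, shape changes per hour via a
hysteresis two-state classifier (elongated at AR >= 1.4, spherical at
AR <= 1.2), the percentage of nuclei reversing direction per hour, and
kymograph montages.

**Locomotion & viability**: path-length crawl velocity (µm/s) from larval
centroid tracks; stage survival percentages from embryo/L1/pupa/adult counts.

**Statistics**: every experimental-vs-control comparison is run both as a
pooled-variance Student's t-test and as an omnibus one-way ANOVA across the
experiment's groups; a difference is significant only when **both** tests
pass (`*` p<0.05, `**` p<0.01). Descriptives are mean ± sample SD.

## Worked example

```python
from myonuc import synthetic as sy, positioning as po, profiles as pr

presets = sy.load_presets()                      # genotype presets (YAML)
fiber  = sy.make_fiber(40, 6, 0.05, 0, seed=1)   # 40x6 µm fiber, 0.05 µm/px
nuclei = sy.place_nuclei(fiber, presets["control"], seed=1)
image, truth = sy.render_channels(fiber, nuclei, presets["control"], seed=1)

d, nearest = po.end_to_nucleus_distance(fiber, nuclei, "dorsal")
roi  = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
prof = pr.normalize_profile(pr.compute_ratio_profile(image, roi))
print(f"end distance {d:.3f} of L (nucleus {nearest}); "
      f"peak {prof.peak:.1f}, AUC {prof.auc:.0f}")
```

prints

```
end distance 0.038 of L (nucleus 1); peak 189.1, AUC 9439
```

i.e. the nearest nucleus sits 3.8% of the muscle length from the dorsal end
(control nuclei cluster near the ends), and the end-enriched target peaks at
~189 (ratio x 100 units) with a total fluorescence of ~9.4x10<sup>3</sup>
over the normalized span — matching this preset's analytic truth curve
(peak 189.4 at the muscle end, integral 9436).

A full experiment (three genotypes at the published cohort design of
4 muscles x 3 hemisegments x 10 embryos) runs from the command line:

```bash
myonuc run-all --seed 1 --out run1
myonuc simulate --preset syd_like --seed 2 --out fiber.tif
```

`run1/` then contains tidy CSVs (`measurements.csv`, `profiles.csv`,
`descriptives.csv`, `comparisons.csv`, `reference_check.csv`) and a
`manifest.json`; identical config + seed reproduces every CSV byte.

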