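# Methods

## Scope and model

`myonuc` quantifies the spatial organization of myonuclei and motor/adaptor
proteins in elongated, multinucleated muscle fibers, as imaged in 2D
maximum-intensity projections of multi-channel confocal stacks. The fiber is
represented by a binary mask, a long-axis unit vector, two end contours
(dorsal = smaller axial coordinate by convention, flippable), and a physical
length (axial extent of mask pixel centers + 1 px, in µm). Nuclei are
polygonal outlines with centroids and areas. All coordinates are 0-based
pixel centers, row-major, y down; physical units enter only through the
µm-per-pixel calibration, so every normalized metric is invariant to
rescaling by construction.

## Measurement conventions and the choices behind them

- **End-to-nucleus distance** is boundary-to-boundary (end contour to
  nucleus outline), not centroid-based: the bracketed span drawn in
  published figures runs from the muscle tip to the nucleus edge. Divided by
  muscle length. Sub-pixel caveat: contours are pixel centers, so distances
  carry an inherent ±0.5 px discretization at each anchor.
- **Nearest-neighbor distance** uses centroids — the stable estimator of a
  nucleus's "position" when outlines are irregular.
- **Longest gap** projects outlines onto the long axis as covered intervals
  and takes the largest uncovered sub-interval of the full axial footprint;
  fiber ends bound the outer gaps, so a nucleus-free muscle end scores as a
  gap.
- **Normalization ambiguity**: muscle length is the axial extent of the
  mask; a midline-arclength definition would differ on curved fibers. All
  fibers here are straight; for user data the mask extent is the documented
  contract.
- **Ratio profiles**: the ROI is an oriented rectangle aligned to the
  shortest end-to-nearest-nucleus segment, of configurable width
  (default 2 µm — "set width" is not standardized in the field; exposed in
  config). At 1-px longitudinal steps the target and reference channels are
  averaged across the width (arithmetic mean) and divided, x 100. The same
  pixel set is sampled in every channel. Normalization resamples the raw
  curve by linear interpolation onto a fixed 101-point [0, 100] grid
  (1%-steps match the granularity of published curves); the far endpoint is
  always included as a sample so the nucleus anchor maps exactly to 100%.
- **Peak** is the maximum of the width-averaged curve. Reading "greatest
  pixel intensity" as the unaveraged per-pixel maximum is a documented
  alternative; the averaged reading is the default because it is what the
  plotted curves show.
- **AUC** is the integral over the normalized axis (flat curve c integrates
  to 100c), computed on the raw samples by composite Simpson's rule. Peak
  and AUC always come from the raw samples, which are denser than the fixed
  grid for long spans and carry no resampling loss for short ones. Simpson
  was chosen over the trapezoid after the generator's analytic truth showed
  the trapezoid's convexity bias on steep short-span decays to be detectable
  at cohort size (a ~0.03% systematic excess, but significant at n = 60);
  Simpson is equally exact for constant and linear profiles and removes the
  bias. Cohort peak/AUC statistics are means/SDs of *per-profile* values,
  never the peak of the mean curve.
- **Curves are means of normalized profiles** (mean-of-normalized), not
  normalized means — the alternative ordering is noted but not implemented.
- **Dynamics**: the aspect ratio is the axis ratio of the outline's
  second-moment (inertia-equivalent) ellipse, computed from closed-form
  polygon moments — exact for polygons and similarity-invariant. Shape
  changes are counted by a hysteresis classifier (enter elongated at
  AR >= 1.4, return spherical at AR <= 1.2; configurable). Hysteresis makes
  the count invariant to temporal oversampling; the thresholds bracket the
  spherical (~1.1) and elongated (~1.8) states seen in time-lapse data.
  "Percent changing direction per hour" is the fraction of nuclei with at
  least one sign reversal of windowed axial displacement (window 10 frames,
  minimum displacement 0.5 µm — translocation thresholds are not
  standardized; both are configurable), each track's indicator divided by
  its duration in hours. Counting reversals instead of reversers is the
  documented alternative.
- **Velocity** is path length / elapsed time (matching crawling-assay
  practice); a net-displacement variant is exposed by flag and is provably
  never larger.
- **Statistics**: pooled-variance Student's t (not Welch; Welch by flag),
  two-sided; omnibus one-way ANOVA across all groups of an experiment; a
  comparison is significant only if both p-values pass the threshold. For
  two groups F = t² exactly, so the dual rule reduces to the t-test there;
  with three or more groups it is strictly more conservative. No
  multiple-testing correction (reports state the comparison count). Each
  muscle measurement is one observation; embryo/hemisegment nesting is
  deliberately not modeled.

## The synthetic generator

The generator emulates the *structure* of the real imagery, calibrated to
reproduce the ordering of phenotypes, not absolute published intensities
(no distributional parameters for any genotype are available).

- **Fiber**: rotatable rectangular mask, default 40 x 6 µm — typical of
  embryonic LT muscles. Whole-muscle imagery at 0.2 µm/px; profile-grade
  imagery at 0.05 µm/px, emulating the separate high-magnification
  acquisitions used for intensity profiles. The finer pixel size also keeps
  profile resampling error well below the 2%-of-peak tolerance on the
  shortest control spans.
- **Nuclei**: ellipses (semi-axes 1.4 x 1.0 µm, long axis along the fiber)
  drawn from a Gaussian cluster mixture over fractional axial positions —
  control: clusters at 0.10/0.90 (SD 0.05), six nuclei, mirroring the two
  end groups; mutants: single mid-fiber cluster (clumping). Transverse
  positions are near the midline (SD 30% of the half-width). Placement is
  rejection sampling with whole-set restarts; nuclei keep an elliptic
  separation factor of 2.3 (a resolvable gap for segmentation) and a 1.5 µm
  standoff from the fiber ends (even end-clustered myonuclei leave a short
  cortical span; this also guarantees a measurable profile span).
- **Channels**: reference = constant level inside the mask (equal across
  genotypes — it is the internal control); nuclei = bright ellipses; target
  = per end-to-nearest-nucleus span, `baseline + A exp(-|s - p| / lambda)`
  on the normalized span coordinate s, blended with a uniform diffuse
  component of equal span mean by weight w. Presets: end-peaked (p = 0,
  control cortical accumulation), nucleus-peaked (p = 1, adaptor/motor
  mutants), diffuse (w = 0.7, constitutive signaling). Outside the span the
  field continues smoothly — constant behind the end cap, a plateau across
  the nucleus body, then the same exponential decay — so the rendered image
  has no intensity discontinuities for interpolation to smear. Noise is
  additive Gaussian (SD 5 a.u. against a reference of 100), optionally with
  a Poisson-like signal-dependent scale; no published noise model exists, so
  a generic CCD-like model is used. The noiseless analytic ratio curve is
  returned as ground truth.
- **Tracks**: nucleus tracks alternate spherical/elongated states (AR
  1.1/1.8 at constant area) as a Poisson process and advance along the axis
  at 0.3 µm/min with Poisson direction reversals; recordings must span at
  least 20 min and sample faster than the expected dwell time. Larval tracks
  are correlated random walks toward a fixed stimulus at constant step speed
  (AR(1) heading noise), so the path-length velocity estimator is exactly
  calibrated.

**What the generator does not emulate** — optics (PSF, depth attenuation),
sarcomere texture, nucleus shape irregularity, segmentation ambiguity from
touching structures, or biological covariance between positioning and
expression level. Passing tests therefore demonstrate that the measurement
code is correct and well-calibrated on data with known structure; they do
not certify performance on degraded real imagery, where the provided-mask
(manual outline) route is the reference path.

## Numerical choices

- Profile sampling uses bilinear interpolation with outside-mask pixels
  filled by their nearest inside value, so samples at the fiber boundary are
  not diluted by background zeros (the ratio is immune to such dilution, but
  single-channel reference profiles are not). ROI width shrinks (with a
  warning) to stay inside the mask, erroring below 3 px. A zero-mean
  reference at any position is an error, never a silent division.
- Segmentation (the automatic convenience route) is Otsu thresholding +
  connected components: fiber = largest reference-channel component; nuclei
  = nuclei-channel components of >= 12 px (4-connectivity, so near-touching
  nuclei stay separate). Nucleus labels protruding <= 5% beyond the fiber
  mask warn; more fails.
- Degenerate statistics are explicit: SD is absent at n = 1; zero pooled
  variance gives p = 1 (equal means) or p = 0 with a warning (unequal).
- Kymographs flip the position axis so net motion points toward lower
  column indices; out-of-frame samples are zero-padded and flagged.
- All generators take explicit integer seeds (numpy `default_rng`); an
  experiment's per-fiber seeds derive from the experiment seed via
  `SeedSequence`, making every output CSV byte-reproducible.

## Cohort design and problem sizes

Synthetic experiments default to the published design: per genotype,
4 muscles x 3 hemisegments x 10 embryos (120 fibers) for positioning and
2 x 3 x 10 (60 fibers) for profiles; dynamics cohorts use 100 tracks of
1 h at 30 s intervals; locomotion uses 30 tracks; viability uses 300
embryos. Statistical calibration uses 10^4 simulated null replicates and
10^4-permutation oracles. The replicated phenotype-ordering check runs 20
independent experiments (tests) or 10 (acceptance script).

## Known limitations

- Metrics assume one fiber per mask and straight fibers; curved or branched
  fibers would need a midline parameterization.
- The end contour is a discrete pixel set; distances inherit ±0.5 px
  anchoring uncertainty (≈0.25% of length at default resolution).
- The dual-significance rule's operating characteristics depend on the
  number of groups in the experiment; with two groups it is exactly the
  t-test.
- No background subtraction or bleed-through correction is applied — inputs
  are assumed pre-corrected or acquired cleanly, as in the source protocol.
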