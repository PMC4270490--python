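# Genotype presets for the synthetic fiber generator.
#
# Each preset describes where myonuclei sit along the fiber axis (a Gaussian
# cluster mixture over fractional positions), how the target motor/adaptor
# protein is distributed over the end-to-nearest-nucleus span (exponential
# peak model blended with a diffuse component), the reference-channel level
# (held equal across genotypes: the reference stain serves as the internal
# control), and the noise model.  Values are calibrated to reproduce the
# ordering of phenotypes (end-enriched vs nucleus-enriched localization,
# end-clustered vs center-clumped nuclei), not absolute published intensities.
# Users may add genotypes by appending entries of the same shape.

control:
  nucleus_placement: {cluster_centers: [0.1, 0.9], cluster_sd: 0.05, n_nuclei: 6}
  target_model:
    baseline: 60.0
    peak_amplitude: 140.0
    peak_position: 0.0      # end-enriched (cortical accumulation)
    decay_length: 0.25
    mixture_weight_diffuse: 0.1
  reference_level: 100.0
  noise: {gaussian_sd: 5.0, poisson_like: false}

syd_like:
  # adaptor loss: nuclei clump mid-fiber, target shifts to the nucleus
  nucleus_placement: {cluster_centers: [0.5], cluster_sd: 0.08, n_nuclei: 6}
  target_model:
    baseline: 60.0
    peak_amplitude: 140.0
    peak_position: 1.0      # nucleus-enriched
    decay_length: 0.25
    mixture_weight_diffuse: 0.1
  reference_level: 100.0
  noise: {gaussian_sd: 5.0, poisson_like: false}

khc_like:
  # kinesin loss: similar nucleus-retained target distribution
  nucleus_placement: {cluster_centers: [0.45], cluster_sd: 0.1, n_nuclei: 6}
  target_model:
    baseline: 60.0
    peak_amplitude: 140.0
    peak_position: 1.0
    decay_length: 0.25
    mixture_weight_diffuse: 0.1
  reference_level: 100.0
  noise: {gaussian_sd: 5.0, poisson_like: false}

bsk_dn_like:
  # dominant-negative JNK: nucleus-enriched target, clumped nuclei
  nucleus_placement: {cluster_centers: [0.5], cluster_sd: 0.1, n_nuclei: 6}
  target_model:
    baseline: 60.0
    peak_amplitude: 140.0
    peak_position: 1.0
    decay_length: 0.25
    mixture_weight_diffuse: 0.1
  reference_level: 100.0
  noise: {gaussian_sd: 5.0, poisson_like: false}

hep_act_like:
  # constitutive JNK activation: mixed/diffuse target distribution
  nucleus_placement: {cluster_centers: [0.3, 0.7], cluster_sd: 0.1, n_nuclei: 6}
  target_model:
    baseline: 60.0
    peak_amplitude: 140.0
    peak_position: 0.0
    decay_length: 0.25
    mixture_weight_diffuse: 0.7
  reference_level: 100.0
  noise: {gaussian_sd: 5.0, poisson_like: false}
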