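# End-to-end demo: simulate a vesicle field, a rod profile and an assembly,
# then run every analysis stage on the generated data.
stages: [simulate, morphometrics, rods, plasticity, biochem]
out_dir: out/demo
seed: 7
simulate:
  n_vesicles: 40
  nested_fraction: 0.3
  image_shape: [1024, 1024]
  pixel_size: 7.0
  noise_sigma: 0.0
  profile_outer_radius: 107.5
rods:
  cutoff: 0.3
  increment: 5.0
  rod_length_um: 2.6
plasticity:
  hinge2_angles_deg: [-40.0, -20.0, 0.0, 10.0, 20.0]
  contact_pairs: [[44, 1, 126], [71, 1, 196]]
biochem:
  reference: WT
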