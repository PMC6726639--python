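# Sample mvmech pipeline configuration.
#
#   mvmech generate -c examples/pipeline_config.yaml -o out/gen
#   mvmech fit      -c examples/pipeline_config.yaml -o out/fit
#   mvmech simulate -c examples/pipeline_config.yaml -o out/sim

generate:
  tissue: chordae            # leaflet_anterior | leaflet_posterior | chordae
  truth_law: chordae_exp
  seed: 42
  n_replicates: 1
  noise:
    kind: proportional_gaussian   # none | additive_gaussian | proportional_gaussian
    cv: 0.05
  protocol:
    lam_max: 1.10
    n_points: 50

fit:
  tissue: leaflet_anterior   # pseudo-biaxial data generated from M1
  laws: [M1, M2, M3]
  protocol:
    lam_max: 1.40
    n_points: 30
  optimizer:
    n_starts: 20
    seed: 1

simulate:
  nx: 64                     # reduced size; the full demonstrator uses 128 x 64
  ny: 32
  law: M1
  tissue: anterior
  stiffness_scale: 1.0
  t_end: 0.08
  waveform:                  # (time s, pressure mmHg) anchors
    - [0.0, 0.0]
    - [0.008, 10.0]
    - [0.025, 10.0]
    - [0.04, -80.0]
    - [0.065, -150.0]
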