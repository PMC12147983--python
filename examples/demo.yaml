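# Small demonstration screen: vehicle control plus one morphotoxic compound
# at three doses, three replicate wells each, 24 structures per well.
seed: 1
scene:
  microwell_diameter: 300.0
  microwell_grid: [5, 5]
  structures_per_well: 24
  pixel_size: 0.8
scenario:
  control_name: control
  replicates_per_condition: 3
  conditions:
    - name: control
      doses:
        - dose: 0.0
          class_mixture: [0.72, 0.18, 0.04, 0.04, 0.02]
          delaminated_fraction: 0.16
    - name: compoundX
      doses:
        - dose: 0.5
          class_mixture: [0.60, 0.24, 0.08, 0.05, 0.03]
          delaminated_fraction: 0.22
        - dose: 1.0
          class_mixture: [0.50, 0.26, 0.14, 0.06, 0.04]
          delaminated_fraction: 0.30
        - dose: 2.0
          class_mixture: [0.40, 0.28, 0.20, 0.07, 0.05]
          delaminated_fraction: 0.40
classifier:
  train_per_class: 20
  n_rounds: 40
analysis:
  control: control
  n_mc: 100000
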