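# Demo pipeline: 800-patient synthetic cohort with the default planted
# risk profile, small model, 3 evaluation repeats.
seed: 0
sim:
  n_patients: 800
  seed: 0
  planted_effects:
    E11: 0.9162907318741551      # ln 2.5, hazardous diagnosis
    DB00316: -0.916290731874155  # ln 0.4, protective drug
    I48: 0.6931471805599453
    F32: 0.5877866649021191
    N17: 0.7884573603642703
    DB00945: -0.6931471805599453
    DB01234: -0.5108256237659907
    L050: 0.5306282510621704
    L051: -0.5978370007556204
cohort:
  seed: 1
model:
  embed_dim: 32
  hidden_size: 32
  n_layers: 1
  dropout: 0.2
  learning_rate: 0.005
  batch_size: 64
  max_epochs: 20
  patience: 4
  n_repeats: 3
  seed: 2
attribution:
  multiple_testing: benjamini_hochberg
  anchor_code: "DX:G30"
  prevalence_threshold: 0.10
  q_threshold: 0.05
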