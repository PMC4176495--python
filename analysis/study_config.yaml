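# Shared study conditions for the numbered analysis drivers.
# One seed governs every stage; identical config + seed reproduce every
# table byte for byte.
seed: 42
reference_arm: 3L
expression_threshold: 6.0
length_threshold: 10000
simulation:
  seed: 42
  arms:
    - [X, 6500000]
    - [3L, 6500000]
  genes_per_arm: 850
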