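# Severity-1.0 colour-vision-deficiency simulation matrices (linear RGB),
# from the physiologically-based two-stage model of Machado, Oliveira &
# Fernandes (2009).  Stored as data so researchers can substitute their own
# matrices (e.g. intermediate severities) without touching code.
schema_version: 1
none:
  - [1.0, 0.0, 0.0]
  - [0.0, 1.0, 0.0]
  - [0.0, 0.0, 1.0]
protan:
  - [0.152286, 1.052583, -0.204868]
  - [0.114503, 0.786281, 0.099216]
  - [-0.003882, -0.048116, 1.051998]
deutan:
  - [0.367322, 0.860646, -0.227968]
  - [0.280085, 0.672501, 0.047413]
  - [-0.011820, 0.042940, 0.968881]
tritan:
  - [1.255528, -0.076749, -0.178779]
  - [-0.078411, 0.930809, 0.147602]
  - [0.004733, 0.691367, 0.303900]
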