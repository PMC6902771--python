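format_version: 1
model_kind: linear_index
metadata:
  name: glioma_index
  source: published 3-miRNA serum index
payload:
  mirna_ids:
  - miR-4763-3p
  - miR-1915-3p
  - miR-3679-5p
  coefficients:
  - 2.09406
  - 1.35369
  - -0.378659
  intercept: -32.11268
  cutoff: 0.0
  positive_label: diffuse_glioma
  negative_label: noncancer
  scale: log2
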