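# The published 12-assay core KASP panel selected from the 54 polymorphic
# assays on the basis of FPR, FNR, background utility and allelic effects.
# Pinned by id: the published selection does not print numeric thresholds,
# so it is shipped as a named panel rather than re-derived from a rule.
panel_id: core12
marker_ids:
  - K_16856978
  - K_19041692
  - K_33072076
  - K_33079643
  - K_33107252
  - K_20771274
  - K_13314239
  - K_13430534
  - K_14713452
  - K_19899233
  - K_19914183
  - K_19914306
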