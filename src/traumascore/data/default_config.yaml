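# Default coding tables, score weights and cutoffs.
#
# Each band is [low, high, code] with closed integer-delimited bounds;
# high: null means unbounded above. Codes are ordinal 0 (worst) to 4
# (best / normal physiology).
#
# gcs_bands, sbp_rts_bands and rr_bands follow the canonical published
# RTS coding. sbp_nts_bands defaults to the same bands as the RTS SBP
# coding, and spo2_bands is a package default with the same five-band
# structure; both NTS tables are configuration, not established fact,
# and can be overridden here.
gcs_bands:
  - [13, 15, 4]
  - [9, 12, 3]
  - [6, 8, 2]
  - [4, 5, 1]
  - [3, 3, 0]
sbp_rts_bands:
  - [90, null, 4]
  - [76, 89, 3]
  - [50, 75, 2]
  - [1, 49, 1]
  - [0, 0, 0]
rr_bands:
  - [10, 29, 4]
  - [30, null, 3]
  - [6, 9, 2]
  - [1, 5, 1]
  - [0, 0, 0]
sbp_nts_bands:
  - [90, null, 4]
  - [76, 89, 3]
  - [50, 75, 2]
  - [1, 49, 1]
  - [0, 0, 0]
spo2_bands:
  - [94, 100, 4]
  - [86, 93, 3]
  - [76, 85, 2]
  - [51, 75, 1]
  - [0, 50, 0]
weights:
  rts_gcs_w: 0.9368
  rts_sbp_w: 0.7326
  rts_rr_w: 0.2908
  nts_sbp_w: 0.2983
  nts_spo2_w: 0.8709
cutoffs:
  rts_cutoff: 7.0
  nts_cutoff: 18.0
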