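# General-population scenario: 24 h/day potential exposure, activity assumed
# comparable to the animals (volume ratio 1), assessment factors
# 2.5 x 6 x 10 x 3 = 450.  Exposure estimate is the EU ambient-air limit
# value of 5 ug/m3 (1.5 ppb).  The AF values are illustrative.
pod_override: [9.6, 14.2]
adjustment: general
afs: general
exposure_lower: 1.5
exposure_upper: 1.5
exposure_units: ppb
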