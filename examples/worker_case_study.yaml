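# Occupational scenario: animal PoD supplied directly (BMCL50/BMCU50 in ppm
# from a micronucleus benchmark-dose analysis), worker exposure-regimen
# adjustment (6 h animal vs 8 h worker day; 6.7 -> 10 m3 inhaled volume) and
# worker assessment factors (2.5 x 6 x 5 x 3 = 225).
# The AF values are illustrative and set no precedent.
pod_override: [9.6, 14.2]
adjustment: worker
afs: worker
exposure_lower: 50.0    # long-term average workplace exposure, ppb
exposure_upper: 100.0
exposure_units: ppb
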