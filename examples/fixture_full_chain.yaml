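# Full chain on the synthetic two-study fixture: generate DO-like and
# B6C3F1-like micronucleus studies, run the combined covariate BMD analysis
# (both model families, CES 50%, 90% profile intervals), take the DO strain's
# BMCL/BMCU as the PoD, and characterize worker risk.
fixture_seed: 7
families: [exponential, hill]
ces: 0.5
ci_level: 0.90
pod_level: DO
adjustment: worker
afs: worker
exposure_lower: 50.0
exposure_upper: 100.0
seed: 0
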