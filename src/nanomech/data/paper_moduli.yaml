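# Reported median stiffness values by biological condition, in kPa.
# These seed the synthetic acceptance scenes; the IC8/T1C3 2D pair is
# constrained only by its reported two-fold contrast, so the absolute
# scale of those two entries is arbitrary (documented in docs/methods.md).
units: kPa
nhm_2d: 4.0
ic8_hsr_section: 16000.0
t1c3_hsr_section: 12000.0
ic8_to_t1c3_2d_ratio: 2.0
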