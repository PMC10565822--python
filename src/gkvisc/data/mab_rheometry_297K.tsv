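# Cone-plate rotational rheometry of mAb solutions at 297 K, shear rate 1000 1/s.
# filtered = 1: sample sterile-filtered before measurement.
concentration_mg_per_mL	viscosity_mPa_s	filtered
98	2.7	1
126	5.5	1
132	5.7	1
216	36.5	1
50	2.1	0
192	19.1	0
199	19.3	0
213	23.2	0
216	32.5	0
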