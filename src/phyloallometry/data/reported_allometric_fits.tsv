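response	predictor	slope	intercept	lambda	r_squared
olfactory_bulb	telencephalon_minus_olfactory_bulb	0.8463	-1.8087	0.948	0.4637
olfactory_bulb	whole_brain_minus_olfactory_bulb	0.8999	-2.2001	0.919	0.4607
mitral_cells	olfactory_bulb	0.6756	3.3910	0.268	0.6249
mitral_cells	telencephalon	0.4117	2.6818	0.759	0.1122
mitral_cells	whole_brain	0.4916	2.2599	0.604	0.1883
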