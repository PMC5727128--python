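measure	species	mean	sd	n
whole_brain	turkey_vulture	9211.97	203.56	3
whole_brain	black_vulture	11579.22	753.16	3
telencephalon	turkey_vulture	6154.25	81.16	3
telencephalon	black_vulture	8113.36	626.07	3
optic_tectum	turkey_vulture	222.96	20.17	3
optic_tectum	black_vulture	219.09	12.63	3
nucleus_rotundus	turkey_vulture	13.98	1.92	3
nucleus_rotundus	black_vulture	15.79	0.31	3
entopallium	turkey_vulture	100.25	9.90	3
entopallium	black_vulture	129.11	7.10	3
olfactory_bulb	turkey_vulture	224.87	34.92	3
olfactory_bulb	black_vulture	54.28	7.04	3
mitral_cells	turkey_vulture	162565	16094	3
mitral_cells	black_vulture	86550	10154	3
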