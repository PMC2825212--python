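ancestor	descendant_body_kg	ratio	delta_log_brain	delta_rel	within_ratio_range	within_brain_range	within_rel_range
H_erectus	16	0.720232	-0.39794	-0.020019	True	False	False
H_erectus	32	1.58235	-0.39794	-0.225923	False	False	False
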