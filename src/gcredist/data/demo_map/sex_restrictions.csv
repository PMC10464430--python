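cause_l4,sex
breast_cancer,female
cervical_cancer,female
uterine_cancer,female
prostate_cancer,male
maternal,female
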