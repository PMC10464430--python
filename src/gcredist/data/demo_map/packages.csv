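package_id,name,icd_prefix
heart_failure,Heart failure,I50
cardiac_arrest,Cardiac arrest,I46
acute_kidney_failure,Acute kidney failure,N19
acute_kidney_failure,Acute kidney failure,N170
acute_kidney_failure,Acute kidney failure,N179
respiratory_failure,Respiratory failure,J96
sepsis,Sepsis,A40
sepsis,Sepsis,A41
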