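uc_codes,mcod_codes,override
X41;X44;X61;X64;Y11,T436,F19
X42;X62;Y12,T40,F19
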