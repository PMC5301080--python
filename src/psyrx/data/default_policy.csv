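atc_prefix,allowed_categories,note
N05A,schizophrenia_psychosis,psychotic disorders (F20-F29) license any antipsychotic; edit to add drug-specific indications
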