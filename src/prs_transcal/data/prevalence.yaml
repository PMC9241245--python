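# Population-specific prevalence of diagnosed type 2 diabetes used for
# prevalence-adjusted PPV/NPV. Override with a file of the same shape.
european: 0.100
african: 0.125
hispanic: 0.131
asian: 0.137
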