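experiment: fig3-adaptation
outdir: results
scale: full
seed: 1
settings: {}
variant: control
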