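{
  "germline_variants.tsv": "8956098e874f0d823fb29224f7718f9df4ac6eeafab333956262b22a39c132a6",
  "somatic_variants.tsv": "dac9da4657003f87c3b8a3407286cdba21bb4bb8fffc76e41f7880f5018b5c34"
}
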