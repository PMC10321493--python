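{
  "single_copy_homologs": 2321,
  "disrupted_homologs": 123,
  "xprime_coding_mb": 4.2,
  "xprime_span_mb": 54.7,
  "x_coding_mb": 4.9,
  "x_span_mb": 58.8
}
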