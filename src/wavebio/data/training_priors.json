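{
  "n_non": 406,
  "n_slight": 728,
  "n_impaired": 287,
  "n_total": 1421
}
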