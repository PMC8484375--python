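{
  "comment": "Case-insensitive substrings classifying section titles for text-scope selection (mode 2: method+results, mode 3: results only).",
  "method_like": ["method", "material", "procedure", "analys", "statistic"],
  "result_like": ["result", "finding"]
}
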