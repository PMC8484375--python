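{
  "comment": "Words at which a candidate sentence is split into snippets before trimming. Any other prose word immediately followed by a comma also acts as a split point.",
  "split_words": [
    "and", "or", "were", "was", "of", "for", "with", "respectively",
    "but", "while", "whereas", "all", "both", "than", "that", "which",
    "although", "however", "indicating", "showing", "revealed", "yielded"
  ],
  "keep_words": [
    "ns", "df", "se", "bf", "or", "rr", "ps", "ts", "rs", "fs", "zs", "beta", "eta"
  ]
}
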