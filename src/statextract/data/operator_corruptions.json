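{
  "comment": "Curated map of PDF-conversion artifacts that stand where a comparison operator was printed. Applied by textnorm.repair_operators only between a recognized statistic/p token and a number, never in ordinary prose. '¼' is the classic Times-encoding corruption of '='.",
  "map": {
    "¼": "=",
    "˂": "<",
    "˃": ">",
    "‹": "<",
    "›": ">",
    "¸": "=",
    "¯": "="
  }
}
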