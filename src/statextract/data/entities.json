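{
  "comment": "Unicode character -> canonical ASCII token map applied by textnorm.normalize_characters. Greek letters map to their spelled-out names; relational operators to ASCII digraphs.",
  "map": {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ζ": "zeta",
    "η": "eta",
    "θ": "theta",
    "ι": "iota",
    "κ": "kappa",
    "λ": "lambda",
    "μ": "mu",
    "ν": "nu",
    "ξ": "xi",
    "π": "pi",
    "ρ": "rho",
    "σ": "sigma",
    "τ": "tau",
    "υ": "upsilon",
    "φ": "phi",
    "χ": "chi",
    "ψ": "psi",
    "ω": "omega",
    "Γ": "Gamma",
    "Δ": "Delta",
    "Θ": "Theta",
    "Λ": "Lambda",
    "Σ": "Sigma",
    "Φ": "Phi",
    "Ψ": "Psi",
    "Ω": "Omega",
    "ϕ": "phi",
    "ß": "beta",
    "²": "2",
    "³": "3",
    "¹": "1",
    "⁰": "0",
    "⁴": "4",
    "≤": "<=",
    "≥": ">=",
    "≪": "<",
    "≫": ">",
    "−": "-",
    "–": "-",
    "—": "-",
    "±": "+/-",
    "×": "*",
    "⋅": "*",
    "∙": "*",
    " ": " ",
    " ": " ",
    " ": " ",
    " ": " ",
    " ": " ",
    "​": "",
    "‘": "'",
    "’": "'",
    "“": "\"",
    "”": "\"",
    "�": " "
  }
}
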