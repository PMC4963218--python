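{
  "entries": [
    {
      "residue": "LYS", "state": "acetyl", "nucleus": "CE", "effect": 1.5,
      "rotamer_offsets": {"0": 1.3, "180": -1.3},
      "anchor": "PUBLISHED",
      "citation": "mean Delta for acetylated Lys 13Ce, validation test on lysine derivatives"
    },
    {
      "residue": "LYS", "state": "monomethyl", "nucleus": "CE", "effect": -10.1,
      "rotamer_offsets": {"+60": 1.95, "-60": -1.95, "180": 0.0},
      "anchor": "PUBLISHED",
      "citation": "mean Delta for mono-methylated Lys 13Ce, validation test on lysine derivatives"
    },
    {
      "residue": "LYS", "state": "dimethyl", "nucleus": "CE", "effect": -19.1,
      "rotamer_offsets": {"+60": 1.95, "-60": -1.95, "180": 0.0},
      "anchor": "PUBLISHED",
      "citation": "mean Delta for di-methylated Lys 13Ce, validation test on lysine derivatives"
    },
    {
      "residue": "LYS", "state": "trimethyl", "nucleus": "CE", "effect": -25.8,
      "rotamer_offsets": {"fixed": 0.0},
      "anchor": "PUBLISHED",
      "citation": "mean Delta for tri-methylated Lys 13Ce, validation test on lysine derivatives"
    },
    {
      "residue": "ARG", "state": "monomethyl-NE", "nucleus": "CZ", "effect": -2.5,
      "rotamer_offsets": {"NE": 0.0},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only; mono- and di-methyl Arg 13Cz distributions are not printed as numbers"
    },
    {
      "residue": "ARG", "state": "monomethyl-NH", "nucleus": "CZ", "effect": -2.5,
      "rotamer_offsets": {"NH1:0": 0.6, "NH1:180": -0.6, "NH2:0": 0.6, "NH2:180": -0.6},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only"
    },
    {
      "residue": "ARG", "state": "dimethyl-sym", "nucleus": "CZ", "effect": -5.5,
      "rotamer_offsets": {"syn": 0.5, "anti": -0.5},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only"
    },
    {
      "residue": "ARG", "state": "dimethyl-asym", "nucleus": "CZ", "effect": -5.5,
      "rotamer_offsets": {"NH1:a": 0.4, "NH1:b": -0.4, "NH2:a": 0.4, "NH2:b": -0.4},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only"
    },
    {
      "residue": "SER", "state": "alpha-GalNAc", "nucleus": "CB", "effect": -2.0,
      "rotamer_offsets": {},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only; alpha-GalNAc Ser overlaps the unmodified distribution"
    },
    {
      "residue": "SER", "state": "beta-GlcNAc", "nucleus": "CB", "effect": -5.0,
      "rotamer_offsets": {},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only"
    },
    {
      "residue": "THR", "state": "alpha-GalNAc", "nucleus": "CB", "effect": 5.0,
      "rotamer_offsets": {},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only; GalNAc-Thr separates from unmodified Thr above ~+3 ppm"
    },
    {
      "residue": "THR", "state": "beta-GlcNAc", "nucleus": "CB", "effect": 0.5,
      "rotamer_offsets": {},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only; GlcNAc-Thr strongly overlaps unmodified Thr"
    },
    {
      "residue": "ASN", "state": "beta-GlcNAc", "nucleus": "CG", "effect": 3.0,
      "rotamer_offsets": {},
      "anchor": "ILLUSTRATIVE",
      "citation": "figure-only; glycosylated Asn separates above ~+2 ppm"
    }
  ]
}
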