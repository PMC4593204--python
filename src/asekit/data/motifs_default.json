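[
  {
    "motif_id": "NFKB_core",
    "kind": "iupac",
    "pattern": "GGGRNNY"
  },
  {
    "motif_id": "NFKB_consensus10",
    "kind": "iupac",
    "pattern": "GGGRNNYYCC"
  },
  {
    "motif_id": "SP1_GC_box",
    "kind": "iupac",
    "pattern": "KRGGCKRRK"
  },
  {
    "motif_id": "SP1_GT_box",
    "kind": "iupac",
    "pattern": "GGTGTSS"
  },
  {
    "motif_id": "NFKB_p50_halfsite",
    "kind": "pwm",
    "matrix": {
      "A": [
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555,
        0.7222222222222222,
        0.6111111111111112,
        0.2777777777777778,
        0.05555555555555555
      ],
      "C": [
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555,
        0.16666666666666666,
        0.05555555555555555,
        0.16666666666666666
      ],
      "G": [
        0.8333333333333334,
        0.8333333333333334,
        0.8333333333333334,
        0.16666666666666666,
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555
      ],
      "T": [
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555,
        0.05555555555555555,
        0.16666666666666666,
        0.6111111111111112,
        0.7222222222222222
      ]
    },
    "background": [
      0.25,
      0.25,
      0.25,
      0.25
    ],
    "threshold": 4.0
  }
]
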