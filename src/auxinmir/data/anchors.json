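{
  "tir1": {
    "ref_id": "SYN_TIR1_REF",
    "fbox_span": [
      10,
      55
    ],
    "lrr_span": [
      100,
      580
    ],
    "pocket_orientation": [
      [
        410,
        "K"
      ],
      [
        440,
        "S"
      ],
      [
        441,
        "G"
      ],
      [
        464,
        "A"
      ],
      [
        465,
        "F"
      ]
    ],
    "pocket_selectivity": [
      [
        405,
        "C"
      ],
      [
        438,
        "S"
      ],
      [
        439,
        "L"
      ],
      [
        440,
        "S"
      ],
      [
        462,
        "S"
      ],
      [
        489,
        "R"
      ]
    ],
    "ac_positions": [
      [
        520,
        "N"
      ],
      [
        544,
        "S"
      ],
      [
        568,
        "R"
      ]
    ]
  },
  "arf": {
    "ref_id": "SYN_ARF_REF",
    "dbd_span": [
      1,
      350
    ],
    "dd_span": [
      230,
      330
    ],
    "b3_motif_start": 120,
    "md_span": [
      351,
      550
    ],
    "pb1_span": [
      551,
      640
    ]
  },
  "pb1": {
    "ref_id": "SYN_PB1_REF",
    "canonical_k_pos": 20,
    "opca_span": [
      50,
      54
    ]
  }
}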