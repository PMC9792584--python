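{
  "source_label": "synthetic fit-population baseline",
  "segments": [
    {
      "id": 1,
      "mass_fraction": 0.142,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        1.0
      ]
    },
    {
      "id": 2,
      "mass_fraction": 0.1,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_dir": [
        0.0,
        -0.8741572761215377,
        -0.4856429311786321
      ],
      "attach_ratio": 1.0295630140987
    },
    {
      "id": 3,
      "mass_fraction": 0.0465,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_dir": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_ratio": 1.1388888888888888
    },
    {
      "id": 4,
      "mass_fraction": 0.0145,
      "com_ratio": 0.5,
      "axis": [
        0.9191450300180579,
        0.0,
        -0.3939192985791677
      ],
      "attach_dir": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_ratio": 1.1764705882352942
    },
    {
      "id": 5,
      "mass_fraction": 0.1,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_dir": [
        0.0,
        0.8741572761215377,
        -0.4856429311786321
      ],
      "attach_ratio": 1.0295630140987
    },
    {
      "id": 6,
      "mass_fraction": 0.0465,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_dir": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_ratio": 1.1388888888888888
    },
    {
      "id": 7,
      "mass_fraction": 0.0145,
      "com_ratio": 0.5,
      "axis": [
        0.9191450300180579,
        0.0,
        -0.3939192985791677
      ],
      "attach_dir": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_ratio": 1.1764705882352942
    },
    {
      "id": 8,
      "mass_fraction": 0.437,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        1.0
      ],
      "attach_dir": [
        0.0,
        0.0,
        1.0
      ],
      "attach_ratio": 1.0
    },
    {
      "id": 9,
      "mass_fraction": 0.099,
      "com_ratio": 0.5,
      "axis": [
        0.0,
        0.0,
        -1.0
      ],
      "attach_dir": [
        0.0,
        0.0,
        1.0
      ],
      "attach_ratio": 4.499999999999999
    }
  ]
}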