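{
  "bodies": [
    {
      "id": 1,
      "joint": "root"
    },
    {
      "id": 2,
      "joint": "spherical",
      "parent": 1
    },
    {
      "id": 3,
      "joint": "hinge",
      "parent": 2,
      "axis": [
        0.0,
        1.0,
        0.0
      ]
    },
    {
      "id": 4,
      "joint": "hinge",
      "parent": 3,
      "axis": [
        0.0,
        1.0,
        0.0
      ]
    },
    {
      "id": 5,
      "joint": "spherical",
      "parent": 1
    },
    {
      "id": 6,
      "joint": "hinge",
      "parent": 5,
      "axis": [
        0.0,
        1.0,
        0.0
      ]
    },
    {
      "id": 7,
      "joint": "hinge",
      "parent": 6,
      "axis": [
        0.0,
        1.0,
        0.0
      ]
    },
    {
      "id": 8,
      "joint": "spherical",
      "parent": 1
    },
    {
      "id": 9,
      "joint": "spherical",
      "parent": 1
    }
  ]
}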