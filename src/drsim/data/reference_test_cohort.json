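{
  "continuous": {
    "age": [
      150,
      67.3,
      8.9
    ],
    "bmi": [
      150,
      32.3,
      6.8
    ],
    "dm_duration": [
      150,
      20.5,
      8.6
    ],
    "hba1c": [
      150,
      8.0,
      1.5
    ]
  },
  "dichotomous": {
    "dyslipidemia": [
      150,
      137
    ],
    "hypertension": [
      150,
      149
    ],
    "male": [
      150,
      148
    ],
    "nephropathy": [
      150,
      51
    ],
    "tobacco": [
      150,
      25
    ]
  },
  "stages": {
    "NPDR": 121,
    "PDR": 29
  }
}
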