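{
  "LARC": [
    "IUD",
    "intrauterine device",
    "IUI",
    "intrauterine implant",
    "contraceptive implant",
    "contraceptive shot",
    "contraceptive injection",
    "Depo Provera",
    "Depo-provera"
  ],
  "COVID": [
    "Corona",
    "coronavirus",
    "COVID"
  ]
}
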