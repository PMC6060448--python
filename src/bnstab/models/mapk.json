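{
  "inputs": ["DNA_damage", "EGFR_stimulus", "FGFR3_stimulus", "TGFBR_stimulus"],
  "outputs": ["Proliferation", "Apoptosis", "Growth_Arrest"]
}
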