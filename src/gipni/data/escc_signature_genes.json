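{
 "gene_ids": [
  "SPRR2A",
  "SPRR2B",
  "SPRR2E",
  "SEC11A",
  "PPFIA1",
  "CROT",
  "RAP1B",
  "HPRT1",
  "MRPL41",
  "S100A7",
  "SNRPD2"
 ],
 "training_cohort": "training"
}
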