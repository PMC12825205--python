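{
  "_comment": "Pre-stimulus species concentrations (nM). Basal phospho-STAT3 is held as nuclear monomer and basal JAG1 as pre-made membrane protein so that an unstimulated run never rises above baseline.",
  "PRLR": 0.0,
  "JAK2": 0.0,
  "RJ": 12.0,
  "PRL": 0.0,
  "PRL_RJ": 0.0,
  "PRL_RJ2": 0.0,
  "PRL_RJ2a": 0.0,
  "S3c": 1000.0,
  "PRL_RJ2a_S3c": 0.0,
  "pS3c": 0.0,
  "PRL_RJ2a_pS3c": 0.0,
  "pS3c_dim": 0.0,
  "pS3n_dim": 0.0,
  "pS3n": 10.0,
  "S3n": 60.0,
  "PPX": 50.0,
  "PPX_pS3c": 0.0,
  "PPN": 60.0,
  "PPN_pS3n": 0.0,
  "SOCS": 0.0,
  "PRL_RJ2a_SOCS": 0.0,
  "SHP2": 100.0,
  "PRL_RJ2a_SHP2": 0.0,
  "DNAdim": 0.0,
  "mRNAn": 0.0,
  "mRNAc": 0.0,
  "JAG1c": 0.0,
  "JAG1": 10.0
}
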