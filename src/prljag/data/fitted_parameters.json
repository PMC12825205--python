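{
 "_provenance": {
  "method": "two-stage Monte Carlo fit (C_max 1.0 then 0.3) against the packaged phenomenological observation table (design seed 0, noise sd 0.1, n=3)",
  "seed": 20260927,
  "stage_iterations": [
   3000,
   9000
  ],
  "rmse_pstat3": 0.3727062384724287,
  "rmse_jag1": 0.5973543518264905,
  "stage1_rmse_pstat3": 0.3668468890712956,
  "stage1_rmse_jag1": 0.6850218807073616
 },
 "values": {
  "k1f": 0.1,
  "k1r": 0.0,
  "k2f": 0.05018376134482855,
  "k2r": 0.01627218024001951,
  "k3f": 0.2,
  "k3r": 0.2,
  "k4": 0.03327801961063087,
  "k4r": 0.001,
  "k5f": 0.00020847804230440147,
  "k5r": 0.4,
  "k6": 0.554069367865899,
  "k7f": 0.001,
  "k7r": 0.2,
  "k8f": 0.0010668239986557687,
  "k8r": 0.1,
  "k9f": 0.002,
  "k9r": 0.2,
  "k10": 0.01,
  "k11f": 0.005367756876293279,
  "k11r": 0.1,
  "k12": 0.00552322103176861,
  "k13": 0.002,
  "k14": 0.005,
  "k15f": 1e-05,
  "k15r": 0.01,
  "k16": 0.0005,
  "k17": 3e-05,
  "k19f": 0.05,
  "k19r": 0.1,
  "k20": 0.0005,
  "k21": 0.0005,
  "k22": 0.001,
  "k23": 0.0010878600021773494,
  "k24f": 0.01,
  "k24r": 0.0002,
  "k25_1": 0.01692959826214646,
  "k25_2": 0.4,
  "k26": 2e-05,
  "k27": 5e-06,
  "k28": 4.515175924433727e-05,
  "k29": 0.0005,
  "k30_1": 0.0003856862809143192,
  "k30_2": 0.5,
  "k31": 0.0009837206444669143,
  "k32": 0.0001,
  "k33": 0.00024506283205320183,
  "k34": 0.00089108168981562,
  "k34r": 1e-05,
  "deg_ratio": 1.360644915569716,
  "RJ": 1.9544026819879083,
  "PPX": 32.91846110214183,
  "S3c": 1971.494356510323,
  "S3n": 35.69249505382856
 }
}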