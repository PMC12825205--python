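{
 "_comment": "Initial-guess rate constants for the unfitted model. Units: nM^-1 s^-1 for bimolecular steps, s^-1 for unimolecular steps; k25_1/k30_1 are Vmax in nM/s with Michaelis constants k25_2/k30_2 in nM; deg_ratio is dimensionless. Chosen once so the unfitted response has the right qualitative shape (early pSTAT3 peak, delayed dose-dependent JAG1 rise) at in-vitro-scale fold-changes; the Monte Carlo fit refines them.",
 "k1f": 0.1,
 "k1r": 0.0,
 "k2f": 0.05,
 "k2r": 0.02,
 "k3f": 0.2,
 "k3r": 0.2,
 "k4": 0.05,
 "k4r": 0.001,
 "k5f": 0.0002,
 "k5r": 0.4,
 "k6": 1.0,
 "k7f": 0.001,
 "k7r": 0.2,
 "k8f": 0.001,
 "k8r": 0.1,
 "k9f": 0.002,
 "k9r": 0.2,
 "k10": 0.01,
 "k11f": 0.005,
 "k11r": 0.1,
 "k12": 0.01,
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
 "k23": 0.001,
 "k24f": 0.01,
 "k24r": 0.0002,
 "k25_1": 0.01,
 "k25_2": 0.4,
 "k26": 2e-05,
 "k27": 5e-06,
 "k28": 0.0001,
 "k29": 0.0005,
 "k30_1": 0.0003,
 "k30_2": 0.5,
 "k31": 0.001,
 "k32": 0.0001,
 "k33": 0.0002,
 "k34": 0.001,
 "k34r": 1e-05,
 "deg_ratio": 1.0
}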