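"""Unit conversions shared across the package.

The pathway model works in nM and seconds; serum prolactin doses arrive in
ng/mL. Conversion uses the molar mass of human prolactin (~23 kDa), so
1 ng/mL corresponds to roughly 0.0435 nM.
"""

PRL_MOLAR_MASS_KDA = 23.0

#: nM of prolactin per ng/mL of serum concentration:
#: 1 ng/mL = 1e-6 g/L; / 23_000 g/mol -> 4.348e-11 mol/L = 0.04348 nM
NG_PER_ML_TO_NM = 1.0e-6 / (PRL_MOLAR_MASS_KDA * 1.0e3) * 1.0e9

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0


def prl_dose_to_nm(dose_ng_per_ml: float) -> float:
    """Convert a prolactin dose in ng/mL to nM."""
    if dose_ng_per_ml < 0:
        raise ValueError(f"PRL dose must be nonnegative, got {dose_ng_per_ml}")
    return dose_ng_per_ml * NG_PER_ML_TO_NM
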